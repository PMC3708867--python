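"""Configuration bundle: defaults, TOML loading, validation, normalization.

All model inputs are literature-derived parameters with package-level
defaults; a run is fully specified by a (possibly empty) TOML file plus
a seed.  Unknown keys are rejected by name, and cross-field constraints
(e.g. shuttle fractions too large for the equilibrium composition) are
surfaced at load time.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, replace

from .analysis import Threshold
from .engine import DivisionParams, SimulationConfig
from .expression import LN2, ExpressionParams
from .markov import RateMatrices, TransitionSpec, build_rate_matrices


@dataclass(frozen=True)
class ModelConfig:
    """Validated parameter bundle for a simulation run."""

    spec: TransitionSpec
    expr: ExpressionParams
    div: DivisionParams
    sim: SimulationConfig
    threshold: Threshold

    def rates(self) -> RateMatrices:
        return build_rate_matrices(self.spec)

    def with_(self, **kwargs) -> "ModelConfig":
        """Return a copy with the given sections replaced."""
        return replace(self, **kwargs)


def default_config() -> ModelConfig:
    return ModelConfig(
        spec=TransitionSpec(),
        expr=ExpressionParams(),
        div=DivisionParams(),
        sim=SimulationConfig(),
        threshold=Threshold(),
    )


_SECTIONS = {
    "markov": {"z_star", "t_d_hours", "shuttle"},
    "expression": {
        "s_on",
        "s_off",
        "half_life_nanog_hours",
        "half_life_reporter_hours",
        "noise_eta",
        "sde_dt_hours",
        "noise_model",
    },
    "division": {"mu", "sigma", "q", "hazard_cap"},
    "simulation": {
        "n_initial",
        "n_cap",
        "t_end_hours",
        "seed",
        "division_mode",
        "snapshot_every_hours",
        "scenario",
    },
    "analysis": {"nanog_positive_cutoff"},
}


def _check_keys(data: dict) -> None:
    unknown = [k for k in data if k not in _SECTIONS]
    if unknown:
        raise ValueError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    for section, keys in data.items():
        bad = [k for k in keys if k not in _SECTIONS[section]]
        if bad:
            raise ValueError(
                f"unknown key(s) in [{section}]: {', '.join(sorted(bad))}"
            )


def _parse_shuttle(raw: dict) -> dict[tuple[int, int], float]:
    out = {}
    for key, value in raw.items():
        parts = key.replace(",", "-").split("-")
        if len(parts) != 2:
            raise ValueError(f"shuttle key {key!r} must name a state pair like '1-2'")
        out[(int(parts[0]), int(parts[1]))] = float(value)
    return out


def config_from_dict(data: dict) -> ModelConfig:
    """Build a validated :class:`ModelConfig` from nested plain dicts."""
    _check_keys(data)
    base = default_config()

    mk = data.get("markov", {})
    spec_kwargs = {}
    if "z_star" in mk:
        spec_kwargs["z_star"] = tuple(float(z) for z in mk["z_star"])
    if "t_d_hours" in mk:
        spec_kwargs["t_d"] = float(mk["t_d_hours"])
    if "shuttle" in mk:
        spec_kwargs["shuttle"] = _parse_shuttle(mk["shuttle"])
    spec = TransitionSpec(**spec_kwargs) if spec_kwargs else base.spec

    ex = data.get("expression", {})
    expr = ExpressionParams(
        s_on=float(ex.get("s_on", base.expr.s_on)),
        s_off=float(ex.get("s_off", base.expr.s_off)),
        gamma_n=LN2 / float(ex.get("half_life_nanog_hours", LN2 / base.expr.gamma_n)),
        gamma_r=LN2 / float(ex.get("half_life_reporter_hours", LN2 / base.expr.gamma_r)),
        eta=float(ex.get("noise_eta", base.expr.eta)),
        sde_dt=float(ex.get("sde_dt_hours", base.expr.sde_dt)),
        noise_model=str(ex.get("noise_model", base.expr.noise_model)),
    )

    dv = data.get("division", {})
    div = DivisionParams(
        mu=float(dv.get("mu", base.div.mu)),
        sigma=float(dv.get("sigma", base.div.sigma)),
        q=float(dv.get("q", base.div.q)),
        hazard_cap=float(dv.get("hazard_cap", base.div.hazard_cap)),
    )

    sm = data.get("simulation", {})
    sim = SimulationConfig(
        n_initial=int(sm.get("n_initial", base.sim.n_initial)),
        n_cap=int(sm.get("n_cap", base.sim.n_cap)),
        t_end=float(sm.get("t_end_hours", base.sim.t_end)),
        seed=int(sm.get("seed", base.sim.seed)),
        division_mode=str(sm.get("division_mode", base.sim.division_mode)),
        snapshot_every=float(sm.get("snapshot_every_hours", base.sim.snapshot_every)),
        scenario=str(sm.get("scenario", base.sim.scenario)),
    )

    an = data.get("analysis", {})
    threshold = Threshold(float(an.get("nanog_positive_cutoff", base.threshold.nanog_positive_cutoff)))

    cfg = ModelConfig(spec=spec, expr=expr, div=div, sim=sim, threshold=threshold)
    cfg.rates()  # surfaces negative-diagonal / degenerate-chain errors at load time
    return cfg


def load_config(path) -> ModelConfig:
    """Load and validate a TOML config; an empty file yields all defaults."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return config_from_dict(data)


def dump_config(config: ModelConfig) -> str:
    """Serialize a config to normalized TOML (load(dump(x)) == x)."""
    spec, expr, div, sim, thr = config.spec, config.expr, config.div, config.sim, config.threshold
    lines = ["[markov]"]
    lines.append(f"z_star = [{', '.join(repr(z) for z in spec.z_star)}]")
    lines.append(f"t_d_hours = {spec.t_d!r}")
    lines.append("")
    lines.append("[markov.shuttle]")
    for (i, j), f in sorted(spec.shuttle.items()):
        lines.append(f'"{i}-{j}" = {f!r}')
    lines.append("")
    lines.append("[expression]")
    lines.append(f"s_on = {expr.s_on!r}")
    lines.append(f"s_off = {expr.s_off!r}")
    lines.append(f"half_life_nanog_hours = {LN2 / expr.gamma_n!r}")
    lines.append(f"half_life_reporter_hours = {LN2 / expr.gamma_r!r}")
    lines.append(f"noise_eta = {expr.eta!r}")
    lines.append(f"sde_dt_hours = {expr.sde_dt!r}")
    lines.append(f'noise_model = "{expr.noise_model}"')
    lines.append("")
    lines.append("[division]")
    lines.append(f"mu = {div.mu!r}")
    lines.append(f"sigma = {div.sigma!r}")
    lines.append(f"q = {div.q!r}")
    lines.append(f"hazard_cap = {div.hazard_cap!r}")
    lines.append("")
    lines.append("[simulation]")
    lines.append(f"n_initial = {sim.n_initial}")
    lines.append(f"n_cap = {sim.n_cap}")
    lines.append(f"t_end_hours = {sim.t_end!r}")
    lines.append(f"seed = {sim.seed}")
    lines.append(f'division_mode = "{sim.division_mode}"')
    lines.append(f"snapshot_every_hours = {sim.snapshot_every!r}")
    lines.append(f'scenario = "{sim.scenario}"')
    lines.append("")
    lines.append("[analysis]")
    lines.append(f"nanog_positive_cutoff = {thr.nanog_positive_cutoff!r}")
    return "\n".join(lines) + "\n"


def config_hash(config: ModelConfig) -> str:
    """Stable hash of the normalized config, recorded in run manifests."""
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:16]
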