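"""Drivers for the in-silico experiments.

Each scenario builds the appropriate variant of the population model —
wild-type equilibrium, reconstitution from a uniform subtype,
reporter-fidelity configurations, transcriptional shutoff without
allelic regulation, and single-allele knockout — runs the kinetic Monte
Carlo engine, and reduces the snapshots to the reported summary
statistics (composition, NANOG-positive fractions, CVs, reporter/native
Pearson correlation, peak counts, switching lags).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import (
    coefficient_of_variation,
    composition_fractions,
    crossing_time,
    histogram_peaks,
    nanog_positive_fraction,
    pearson_correlation,
)
from .config import ModelConfig, default_config
from .engine import (
    LN2,
    PopulationSnapshot,
    Simulation,
    SimulationConfig,
    sample_partition_fraction,
)
from .expression import ExpressionParams, propagate_deterministic, steady_state
from .markov import N_STATES, RateMatrices, growth_rates, stationary_composition


@dataclass
class ScenarioResult:
    """Named scenario output: snapshot series plus derived scalar statistics."""

    label: str
    snapshots: list[PopulationSnapshot]
    stats: dict[str, float]
    extras: dict = field(default_factory=dict)


def composition_trace(snapshots: list[PopulationSnapshot]) -> pd.DataFrame:
    rows = [
        {"time_h": s.time_h, **{f"z{i + 1}": f for i, f in enumerate(composition_fractions(s))}}
        for s in snapshots
    ]
    return pd.DataFrame(rows)


def no_switching_rates(t_d: float) -> RateMatrices:
    """Rate matrices with all allelic switching disabled (no allelic regulation)."""
    lam = growth_rates(t_d)
    zero = np.zeros((N_STATES, N_STATES))
    return RateMatrices(p=np.eye(N_STATES), k=zero, lam=lam, a=np.diag(lam))


def knockout_rates(rates: RateMatrices) -> RateMatrices:
    """Restrict switching to allele 2 (states 3<->4) for the Nanog+/- genotype."""
    k = np.zeros_like(rates.k)
    k[2, 3] = rates.k[2, 3]
    k[3, 2] = rates.k[3, 2]
    k[2, 2] = -k[2, 3]
    k[3, 3] = -k[3, 2]
    return RateMatrices(p=rates.p, k=k, lam=rates.lam, a=k + np.diag(rates.lam))


def knockout_equilibrium_composition(rates: RateMatrices) -> np.ndarray:
    """Stationary composition of the allele-2-only chain (states 3 and 4)."""
    k34, k43 = rates.k[2, 3], rates.k[3, 2]
    z3 = k43 / (k34 + k43)
    return np.array([0.0, 0.0, z3, 1.0 - z3])


def _seeded(sim: SimulationConfig, seed: int | None) -> SimulationConfig:
    return sim if seed is None else replace(sim, seed=seed)


def _equilibrium_stats(snap: PopulationSnapshot, config: ModelConfig) -> dict[str, float]:
    comp = composition_fractions(snap)
    return {
        **{f"z{i + 1}": float(f) for i, f in enumerate(comp)},
        "frac_positive": nanog_positive_fraction(snap, config.threshold),
        "cv_nanog": coefficient_of_variation(snap.n_total),
        "mean_nanog": float(snap.n_total.mean()),
        "n_cells": float(len(snap)),
    }


def run_equilibrium(config: ModelConfig | None = None, seed: int | None = None) -> ScenarioResult:
    """Wild-type population at dynamic equilibrium.

    Seeds the population at the stationary composition and equilibrates
    the molecular-content structure; reports composition, positive
    fraction, CV and the peak count of the total-NANOG distribution.
    """
    config = config or default_config()
    sim = Simulation(
        config.rates(),
        config.expr,
        config.div,
        _seeded(config.sim, seed),
    )
    res = sim.run()
    stats = _equilibrium_stats(res.final, config)
    stats["peak_count"] = float(histogram_peaks(res.final.n_total))
    return ScenarioResult("equilibrium", res.snapshots, stats, {"result": res})


def run_reconstitution(
    initial_type: int, config: ModelConfig | None = None, seed: int | None = None,
    tolerance: float = 0.02, sustain_hours: float = 20.0,
) -> ScenarioResult:
    """Population reconstitution from 100% of a single subtype.

    Tracks the composition trajectory and reports the first time the
    maximum absolute deviation from the stationary composition drops
    below ``tolerance`` and stays there for ``sustain_hours``.
    """
    config = config or default_config()
    if initial_type not in (1, 2, 3, 4):
        raise ValueError("initial_type must be 1..4")
    comp0 = np.zeros(N_STATES)
    comp0[initial_type - 1] = 1.0
    rates = config.rates()
    sim_cfg = _seeded(config.sim, seed)
    sim = Simulation(rates, config.expr, config.div, sim_cfg, initial_composition=comp0)
    res = sim.run()
    z_star = stationary_composition(rates.k)
    trace = composition_trace(res.snapshots)
    dev = np.abs(trace[["z1", "z2", "z3", "z4"]].to_numpy() - z_star).max(axis=1)
    times = trace["time_h"].to_numpy()
    t_conv = math.inf
    for i in range(len(times)):
        window = dev[(times >= times[i]) & (times <= times[i] + sustain_hours)]
        if np.all(window < tolerance) and times[-1] >= times[i] + sustain_hours - 1e-9:
            t_conv = float(times[i])
            break
    stats = _equilibrium_stats(res.final, config)
    stats["t_converged"] = t_conv
    stats["max_dev_final"] = float(dev[-1])
    return ScenarioResult(
        f"reconstitute_type{initial_type}", res.snapshots, stats, {"trace": trace, "result": res}
    )


def run_reporter_study(
    insertion: str,
    reporter_half_life: float,
    config: ModelConfig | None = None,
    seed: int | None = None,
) -> ScenarioResult:
    """Reporter-fidelity study (knock-in on ``"one"`` or ``"both"`` alleles).

    The reporter is co-expressed from the designated allele(s) with the
    native production constants and its own half-life; the native gene
    keeps producing from both alleles (the knock-in does not abolish
    native expression).  Reports the per-cell Pearson correlation of
    total reporter vs total NANOG and the CV of each on the equilibrium
    snapshot.
    """
    config = config or default_config()
    alleles = {"one": (1,), "both": (1, 2)}.get(insertion)
    if alleles is None:
        raise ValueError("insertion must be 'one' or 'both'")
    expr = replace(config.expr, gamma_r=LN2 / reporter_half_life)
    sim = Simulation(
        config.rates(),
        expr,
        config.div,
        _seeded(config.sim, seed),
        reporter_alleles=alleles,
    )
    res = sim.run()
    snap = res.final
    stats = _equilibrium_stats(snap, config)
    stats.update(
        rho=pearson_correlation(snap.r_total, snap.n_total),
        cv_reporter=coefficient_of_variation(snap.r_total),
        mean_reporter=float(snap.r_total.mean()),
    )
    return ScenarioResult(
        f"reporter_{insertion}_t{reporter_half_life:g}h", res.snapshots, stats, {"result": res}
    )


def run_shutoff_study(
    config: ModelConfig | None = None,
    seed: int | None = None,
    equilibrate_hours: float = 120.0,
    follow_hours: float = 20.0,
    reporter_half_life: float = 20.0,
    shutoff_production: str = "zero",
) -> ScenarioResult:
    """Transcriptional shutoff of a gene X without allelic regulation.

    Phase 1 equilibrates a non-switching population (all cells type 1,
    single-allele reporter).  At t = 0 transcription of both the native
    and reporter genes stops; the mean +/- st.dev. trajectories and the
    reporter/native correlation are tracked.  ``shutoff_production``
    selects complete inhibition (``"zero"``, as under a transcriptional
    inhibitor; production drops to 0) or demotion to the off-state leak
    rate (``"leak"``).  Complete inhibition preserves the per-cell
    reporter/native correlation over the reporter half-life, whereas a
    leak floor erases the native protein's cross-cell structure within a
    few native half-lives.
    """
    config = config or default_config()
    rates = no_switching_rates(config.spec.t_d)
    expr = replace(config.expr, gamma_r=LN2 / reporter_half_life)
    seed = config.sim.seed if seed is None else seed
    eq_cfg = replace(config.sim, t_end=equilibrate_hours, seed=seed)
    sim1 = Simulation(
        rates, expr, config.div, eq_cfg,
        reporter_alleles=(1,),
        initial_composition=(1.0, 0.0, 0.0, 0.0),
    )
    res1 = sim1.run()
    snap0 = res1.final
    rho_t0 = pearson_correlation(snap0.r_total, snap0.n_total)

    # shut off transcription from both alleles
    if shutoff_production not in ("zero", "leak"):
        raise ValueError("shutoff_production must be 'zero' or 'leak'")
    expr2 = replace(expr, s_off=0.0) if shutoff_production == "zero" else expr
    pop = sim1.pop
    pop.state[: pop.count] = 4
    follow_cfg = replace(
        config.sim, t_end=follow_hours, seed=seed + 1, snapshot_every=min(2.0, follow_hours)
    )
    sim2 = Simulation(
        rates, expr2, config.div, follow_cfg,
        reporter_alleles=(1,),
        initial_population=pop,
    )
    res2 = sim2.run()
    snap20 = res2.final
    traj = pd.DataFrame(
        [
            {
                "time_h": s.time_h,
                "mean_native": float(s.n_total.mean()),
                "std_native": float(s.n_total.std(ddof=0)),
                "mean_reporter": float(s.r_total.mean()),
                "std_reporter": float(s.r_total.std(ddof=0)),
            }
            for s in res2.snapshots
        ]
    )
    stats = {
        "rho_t0": rho_t0,
        "rho_t_end": pearson_correlation(snap20.r_total, snap20.n_total),
        "native_decay_ratio": float(snap20.n_total.mean() / snap0.n_total.mean()),
        "reporter_decay_ratio": float(snap20.r_total.mean() / snap0.r_total.mean()),
        "n_cells": float(len(snap0)),
    }
    return ScenarioResult(
        "shutoff", res1.snapshots + res2.snapshots, stats,
        {"trajectories": traj, "snapshot_t0": snap0, "result_follow": res2},
    )


def run_knockout_study(
    config: ModelConfig | None = None,
    seed: int | None = None,
    reconstitution_cycles: float = 5.0,
    chain: str = "full",
) -> ScenarioResult:
    """Single Nanog-allele deletion (Nanog+/-) vs wild type.

    Gene expression from allele 1 is held in the "off" state for the
    whole simulation while allele 2 keeps its wild-type dynamics.  With
    ``chain="full"`` (default) cells still traverse all four regulatory
    subtypes — the deletion silences allele 1's output, not the
    regulatory switching — so NANOG is produced whenever the cell is in
    a type with allele 2 active (types 1 and 3).  ``chain="restricted"``
    instead confines switching to the functional allele (states 3<->4).
    Reports the NANOG-positive fraction, CV and mean at equilibrium for
    both genotypes, and the positive fraction ``reconstitution_cycles``
    doubling times after an all-off start.
    """
    config = config or default_config()
    rates = config.rates()
    seed = config.sim.seed if seed is None else seed

    wt = run_equilibrium(config, seed=seed)

    if chain == "full":
        ko_rates = rates
        ko_comp = stationary_composition(rates.k)
    elif chain == "restricted":
        ko_rates = knockout_rates(rates)
        ko_comp = knockout_equilibrium_composition(rates)
    else:
        raise ValueError("chain must be 'full' or 'restricted'")
    sim_ko = Simulation(
        ko_rates, config.expr, config.div, _seeded(config.sim, seed + 1),
        allele1_deleted=True,
        initial_composition=ko_comp,
    )
    res_ko = sim_ko.run()
    snap_ko = res_ko.final

    five_cfg = replace(config.sim, t_end=reconstitution_cycles * config.spec.t_d, seed=seed + 2)
    sim5 = Simulation(
        ko_rates, config.expr, config.div, five_cfg,
        allele1_deleted=True,
        initial_composition=(0.0, 0.0, 0.0, 1.0),
    )
    res5 = sim5.run()

    stats = {
        "frac_positive_wt": wt.stats["frac_positive"],
        "cv_wt": wt.stats["cv_nanog"],
        "mean_wt": wt.stats["mean_nanog"],
        "frac_positive_ko": nanog_positive_fraction(snap_ko, config.threshold),
        "cv_ko": coefficient_of_variation(snap_ko.n_total),
        "mean_ko": float(snap_ko.n_total.mean()),
        "frac_positive_after_cycles": nanog_positive_fraction(res5.final, config.threshold),
        "n_cells": float(len(snap_ko)),
    }
    stats["mean_ratio"] = stats["mean_ko"] / stats["mean_wt"]
    return ScenarioResult(
        "knockout", res_ko.snapshots, stats,
        {"wild_type": wt, "result_ko": res_ko, "result_5cycles": res5},
    )


# ---------------------------------------------------------------------------
# single-cell trajectories and switching-lag timing
# ---------------------------------------------------------------------------


@dataclass
class SwitchEvent:
    time_h: float
    kind: str  # "switch" | "divide"
    from_state: int
    to_state: int


def simulate_single_cell(
    config: ModelConfig | None = None,
    seed: int = 0,
    t_end: float = 1000.0,
    initial_type: int = 2,
    record_dt: float = 0.1,
) -> tuple[pd.DataFrame, list[SwitchEvent]]:
    """Follow one cell lineage (one daughter kept at each division).

    Allelic switching follows the transition rate matrix; divisions
    occur at the constant rate ln2/T_d and partition the protein content
    by a symmetric-beta fraction.  Protein dynamics between events are
    the exact deterministic solution.  Returns the sampled trajectory
    and the annotated event list.
    """
    config = config or default_config()
    rates = config.rates()
    expr = config.expr
    rng = np.random.Generator(np.random.PCG64(seed))
    lam = LN2 / config.spec.t_d

    state = initial_type
    s_of = {
        st: (
            expr.s_on if st in (1, 2) else expr.s_off,
            expr.s_on if st in (1, 3) else expr.s_off,
        )
        for st in (1, 2, 3, 4)
    }
    n1, n2 = (s / expr.gamma_n for s in s_of[state])
    t = 0.0
    rows, events = [], []
    next_rec = 0.0
    lut = {st: [(j + 1, rates.k[st - 1, j]) for j in range(4) if j != st - 1] for st in (1, 2, 3, 4)}
    while t < t_end:
        channels = [(target, r) for target, r in lut[state] if r > 0] + [(0, lam)]
        total = sum(r for _, r in channels)
        dt = rng.exponential(1.0 / total)
        t_next = min(t + dt, t_end)
        while next_rec <= t_next:
            h = next_rec - t
            s1, s2 = s_of[state]
            rows.append(
                {
                    "time_h": next_rec,
                    "type": state,
                    "n1": propagate_deterministic(n1, s1, expr.gamma_n, h),
                    "n2": propagate_deterministic(n2, s2, expr.gamma_n, h),
                }
            )
            next_rec += record_dt
        s1, s2 = s_of[state]
        n1 = propagate_deterministic(n1, s1, expr.gamma_n, t_next - t)
        n2 = propagate_deterministic(n2, s2, expr.gamma_n, t_next - t)
        t = t_next
        if t >= t_end:
            break
        u = rng.random() * total
        acc = 0.0
        for target, r in channels:
            acc += r
            if u < acc:
                break
        if target == 0:
            x = sample_partition_fraction(config.div.q, rng, size=2)
            n1, n2 = n1 * x[0], n2 * x[1]
            events.append(SwitchEvent(t, "divide", state, state))
        else:
            events.append(SwitchEvent(t, "switch", state, target))
            state = target
    df = pd.DataFrame(rows)
    df["n_total"] = df["n1"] + df["n2"]
    return df, events


def switching_timing(
    trajectory: pd.DataFrame,
    events: list[SwitchEvent],
    expr: ExpressionParams | None = None,
    depletion_multiple: float = 2.0,
    buildup_fraction: float = 0.8,
) -> dict[str, float]:
    """Lag statistics for NANOG depletion and build-up after switching.

    For every entry into the all-off state, measures the time until
    total NANOG first drops below ``depletion_multiple`` times the
    off/off steady state; for every exit from the all-off state into a
    monoallelic state, the time to reach ``buildup_fraction`` of the
    monoallelic steady state.  Reports medians and event counts.
    """
    expr = expr or ExpressionParams()
    ss_off = steady_state(2 * expr.s_off, expr.gamma_n)
    ss_mono = steady_state(expr.s_on + expr.s_off, expr.gamma_n)
    t = trajectory["time_h"].to_numpy()
    n = trajectory["n_total"].to_numpy()
    depletion, buildup = [], []
    for ev in events:
        if ev.kind != "switch":
            continue
        if ev.to_state == 4:
            mask = (t >= ev.time_h) & (n <= depletion_multiple * ss_off)
            if mask.any():
                depletion.append(t[mask][0] - ev.time_h)
        elif ev.from_state == 4 and ev.to_state in (2, 3):
            mask = (t >= ev.time_h) & (n >= buildup_fraction * ss_mono)
            if mask.any():
                buildup.append(t[mask][0] - ev.time_h)
    return {
        "median_depletion_lag_h": float(np.median(depletion)) if depletion else math.nan,
        "median_buildup_lag_h": float(np.median(buildup)) if buildup else math.nan,
        "n_depletion_events": float(len(depletion)),
        "n_buildup_events": float(len(buildup)),
    }


def deterministic_depletion_time(
    expr: ExpressionParams | None = None, start: str = "biallelic", multiple: float = 2.0
) -> float:
    """Closed-form time to fall below ``multiple`` x the off/off steady state."""
    expr = expr or ExpressionParams()
    n0 = steady_state(
        2 * expr.s_on if start == "biallelic" else expr.s_on + expr.s_off, expr.gamma_n
    )
    ss_off = steady_state(2 * expr.s_off, expr.gamma_n)
    return crossing_time(n0, 2 * expr.s_off, expr.gamma_n, multiple * ss_off)


def deterministic_buildup_time(
    expr: ExpressionParams | None = None, fraction: float = 0.8
) -> float:
    """Closed-form time from the off/off to ``fraction`` of the monoallelic steady state."""
    expr = expr or ExpressionParams()
    n0 = steady_state(2 * expr.s_off, expr.gamma_n)
    s_mono = expr.s_on + expr.s_off
    return crossing_time(n0, s_mono, expr.gamma_n, fraction * steady_state(s_mono, expr.gamma_n))
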