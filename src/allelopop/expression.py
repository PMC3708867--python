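"""Per-allele protein birth–death dynamics for NANOG and a knock-in reporter.

Each allele produces protein with zeroth-order kinetics at ``s_on`` when
active and at a leak rate ``s_off`` (1% of ``s_on`` by default) when
inactive; degradation is first order.  The linear ODE has an exact
closed-form solution used throughout the deterministic simulations.  A
stochastic variant adds multiplicative Gaussian white noise proportional
to the current protein level and is integrated with Euler–Maruyama.

A knock-in fluorescent reporter is driven by the same allele on/off
state and the same production constants but its own degradation rate
(GFP half-life ~20 h vs ~2 h for NANOG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LN2 = math.log(2.0)

DEFAULT_S_ON = 1000.0  # molecules/h per active allele
DEFAULT_S_OFF = 10.0  # leak production, 1% of s_on
DEFAULT_HALF_LIFE_NANOG_H = 2.0
DEFAULT_HALF_LIFE_REPORTER_H = 20.0
DEFAULT_SDE_DT_H = 0.01


@dataclass(frozen=True)
class ExpressionParams:
    """Production/degradation constants for the two protein species.

    ``gamma_n`` and ``gamma_r`` are the NANOG and reporter degradation
    rates (1/h); ``eta`` is the dimensionless noise fraction of the SDE
    model (0 recovers the deterministic ODE).  ``noise_model`` selects
    whether the noise amplitude multiplies the current protein level
    (``"state"``) or the production term (``"production"``).
    """

    s_on: float = DEFAULT_S_ON
    s_off: float = DEFAULT_S_OFF
    gamma_n: float = LN2 / DEFAULT_HALF_LIFE_NANOG_H
    gamma_r: float = LN2 / DEFAULT_HALF_LIFE_REPORTER_H
    eta: float = 0.0
    sde_dt: float = DEFAULT_SDE_DT_H
    noise_model: str = "state"

    def __post_init__(self) -> None:
        if not self.s_on > self.s_off:
            raise ValueError(f"s_on ({self.s_on}) must exceed s_off ({self.s_off})")
        if self.s_off < 0:
            raise ValueError("s_off must be non-negative")
        if not (self.gamma_n > 0 and self.gamma_r > 0):
            raise ValueError("degradation rates must be positive")
        if self.eta < 0:
            raise ValueError("noise fraction eta must be non-negative")
        if not self.sde_dt > 0:
            raise ValueError("SDE time step must be positive")
        if self.noise_model not in ("state", "production"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    @classmethod
    def from_half_lives(
        cls,
        half_life_nanog: float = DEFAULT_HALF_LIFE_NANOG_H,
        half_life_reporter: float = DEFAULT_HALF_LIFE_REPORTER_H,
        **kwargs,
    ) -> "ExpressionParams":
        return cls(
            gamma_n=LN2 / half_life_nanog, gamma_r=LN2 / half_life_reporter, **kwargs
        )


@dataclass(frozen=True)
class AllelePattern:
    """On/off state of the two Nanog alleles and the derived subtype id."""

    allele1: bool
    allele2: bool

    @property
    def type_id(self) -> int:
        # 1 = on/on, 2 = on/off, 3 = off/on, 4 = off/off
        return {(True, True): 1, (True, False): 2, (False, True): 3, (False, False): 4}[
            (self.allele1, self.allele2)
        ]

    @classmethod
    def from_type(cls, type_id: int) -> "AllelePattern":
        try:
            a1, a2 = {1: (True, True), 2: (True, False), 3: (False, True), 4: (False, False)}[
                int(type_id)
            ]
        except KeyError:
            raise ValueError(f"cell type must be 1..4, got {type_id}") from None
        return cls(a1, a2)


@dataclass
class CellState:
    """Single-cell state vector: per-allele protein contents and size.

    ``n1``/``n2`` are NANOG molecules attributed to alleles 1 and 2,
    ``r1``/``r2`` the reporter molecules (zero when no reporter is
    inserted) and ``v`` the dimensionless cell size.
    """

    n1: float
    n2: float
    v: float
    pattern: AllelePattern
    r1: float = 0.0
    r2: float = 0.0
    cell_id: int = 0

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "r1", "r2", "v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def allele_production(active: bool, params: ExpressionParams, species: str = "nanog") -> float:
    """Production rate of one allele: ``s_on`` if active, else the leak ``s_off``.

    The reporter shares the native production constants (same promoter),
    so ``species`` only documents intent.
    """
    if species not in ("nanog", "reporter"):
        raise ValueError(f"unknown species {species!r}")
    return params.s_on if active else params.s_off


def steady_state(s_total: float, gamma: float) -> float:
    """Equilibrium molecule count ``s_total / gamma`` of the birth–death ODE."""
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    return s_total / gamma


def propagate_deterministic(n0, s, gamma: float, t) -> np.ndarray | float:
    """Exact solution ``s/g + (n0 - s/g) e^{-g t}`` of dn/dt = s - g n.

    Accepts scalars or broadcastable arrays; no integration error, so
    composing over successive intervals is exact.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("elapsed time must be non-negative")
    ss = np.asarray(s, dtype=float) / gamma
    out = ss + (np.asarray(n0, dtype=float) - ss) * np.exp(-gamma * np.asarray(t, dtype=float))
    return float(out) if out.ndim == 0 else out


def propagate_sde(
    n0,
    s,
    gamma: float,
    eta: float,
    t: float,
    dt: float,
    rng: np.random.Generator,
    noise_model: str = "state",
):
    """Euler–Maruyama integration of dn = (s - g n) dt + eta·amp·dW.

    The noise amplitude ``amp`` is the current protein level for
    ``noise_model="state"`` (multiplicative noise linear in the protein)
    or the production rate ``s`` for ``"production"``.  Trajectories are
    clipped at zero (molecule counts cannot be negative).  Vectorized
    over ``n0``/``s`` arrays; one shortened final step covers any
    remainder ``t mod dt``.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    if eta < 0:
        raise ValueError("eta must be non-negative")
    n = np.asarray(n0, dtype=float).copy()
    scalar = n.ndim == 0
    n = np.atleast_1d(n)
    s = np.broadcast_to(np.asarray(s, dtype=float), n.shape)
    remaining = float(t)
    while remaining > 1e-15:
        h = min(dt, remaining)
        amp = n if noise_model == "state" else s
        xi = rng.standard_normal(n.shape)
        n = n + (s - gamma * n) * h + eta * amp * math.sqrt(h) * xi
        np.clip(n, 0.0, None, out=n)
        remaining -= h
    return float(n[0]) if scalar else n


def total_nanog(cell: CellState) -> float:
    """Total NANOG content ``n1 + n2`` of a cell."""
    return cell.n1 + cell.n2
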