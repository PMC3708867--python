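"""Four-state Markov chain of allelic Nanog on/off patterns.

Mouse embryonic stem cells are classified by which of the two *Nanog*
alleles is transcriptionally active: type 1 (both on), types 2 and 3
(exactly one on) and type 4 (both off).  Cells shuttle stochastically
between these patterns on the timescale of the cell cycle.  The chain is
constructed from *observed* quantities — the equilibrium subpopulation
fractions z* and the fraction of the population shuttling between each
linked pair of states per cell cycle — via detailed balance, so that z*
is stationary by construction.

Transition probabilities per cell cycle are converted to first-order
rates by ``k_ij = p_ij / T_d`` (the observation window is one doubling
time), and all four subtypes proliferate at the same rate ``ln 2 / T_d``.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, null_space

N_STATES = 4

#: Equilibrium composition under LIF/serum: 14% biallelic, 28% for each
#: monoallelic pattern, 30% with both alleles inactive.
DEFAULT_Z_STAR: tuple[float, float, float, float] = (0.14, 0.28, 0.28, 0.30)

#: Fraction of the total population shuttling between each linked pair of
#: states per cell cycle.  Pairs (1,4) and (2,3) are not linked: either
#: transition would require both alleles to switch simultaneously.
DEFAULT_SHUTTLE: dict[tuple[int, int], float] = {
    (1, 2): 0.12,
    (1, 3): 0.12,
    (2, 4): 0.12,
    (3, 4): 0.12,
}

DEFAULT_DOUBLING_TIME_H = 10.0

_ALL_PAIRS = [(i, j) for i in range(1, 5) for j in range(i + 1, 5)]


def _normalize_shuttle(shuttle: Mapping[tuple[int, int], float]) -> dict[tuple[int, int], float]:
    out = {pair: 0.0 for pair in _ALL_PAIRS}
    for key, value in shuttle.items():
        i, j = int(key[0]), int(key[1])
        if i == j or not (1 <= i <= 4 and 1 <= j <= 4):
            raise ValueError(f"invalid shuttle pair {key!r}: states must be distinct, in 1..4")
        out[(min(i, j), max(i, j))] = float(value)
    return out


@dataclass(frozen=True)
class TransitionSpec:
    """Raw ingredients of the allelic-switching chain.

    Parameters
    ----------
    z_star : length-4 sequence
        Equilibrium fractions of types 1–4 (non-negative, summing to 1).
    shuttle : mapping ``(i, j) -> fraction``
        Fraction of the total population shuttling between states ``i``
        and ``j`` per cell cycle (symmetric; unordered pairs).  States 1
        and 4 are not linked directly, so ``shuttle[(1, 4)]`` must be 0.
    t_d : float
        Population doubling time in hours; also the observation window
        over which the shuttle fractions were measured.
    """

    z_star: tuple[float, ...] = DEFAULT_Z_STAR
    shuttle: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_SHUTTLE)
    )
    t_d: float = DEFAULT_DOUBLING_TIME_H

    def __post_init__(self) -> None:
        z = np.asarray(self.z_star, dtype=float)
        if z.shape != (N_STATES,):
            raise ValueError(f"z_star must have 4 entries, got shape {z.shape}")
        if np.any(z < 0):
            raise ValueError("z_star entries must be non-negative")
        if abs(z.sum() - 1.0) > 1e-12:
            raise ValueError(f"z_star must sum to 1 (got {z.sum()!r})")
        object.__setattr__(self, "z_star", tuple(float(x) for x in z))
        sh = _normalize_shuttle(self.shuttle)
        for pair, f in sh.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"shuttle fraction for pair {pair} must lie in [0, 1], got {f}")
        if sh[(1, 4)] != 0.0:
            raise ValueError("states 1 and 4 are not linked directly; shuttle[(1, 4)] must be 0")
        object.__setattr__(self, "shuttle", sh)
        if not self.t_d > 0:
            raise ValueError(f"doubling time must be positive, got {self.t_d}")

    def shuttle_fraction(self, i: int, j: int) -> float:
        return self.shuttle[(min(i, j), max(i, j))]


@dataclass(frozen=True)
class RateMatrices:
    """Transition probability/rate matrices and proliferation rates.

    ``p`` is the per-cell-cycle transition probability matrix (rows sum
    to 1), ``k`` the transition rate matrix in 1/h (rows sum to 0),
    ``lam`` the per-type proliferation rates (all equal to ln2/T_d) and
    ``a = k + diag(lam)`` the combined generator of the cell-number
    dynamics.
    """

    p: np.ndarray
    k: np.ndarray
    lam: np.ndarray
    a: np.ndarray


def build_transition_probabilities(spec: TransitionSpec) -> np.ndarray:
    """Per-cell-cycle transition probability matrix via detailed balance.

    The fraction shuttling between ``i`` and ``j`` splits equally between
    the two directions, so ``p_ij = (shuttle(i, j)/2) / z*_i`` and the
    diagonal absorbs the remainder.  Detailed balance
    ``z*_i p_ij = z*_j p_ji`` then holds exactly by construction.

    Raises
    ------
    ValueError
        If a linked pair has a zero equilibrium fraction, or if the
        off-diagonal mass of some row exceeds 1 (shuttle fractions too
        large for the given ``z_star``).
    """
    z = np.asarray(spec.z_star)
    p = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        for j in range(N_STATES):
            if i == j:
                continue
            f = spec.shuttle_fraction(i + 1, j + 1)
            if f == 0.0:
                continue
            if z[i] <= 0.0:
                raise ValueError(
                    f"state {i + 1} has zero equilibrium fraction but a nonzero "
                    f"shuttle fraction with state {j + 1}"
                )
            p[i, j] = 0.5 * f / z[i]
    diag = 1.0 - p.sum(axis=1)
    bad = np.nonzero(diag < 0)[0]
    if bad.size:
        rows = ", ".join(str(i + 1) for i in bad)
        raise ValueError(
            f"shuttle fractions too large for z_star: row(s) {rows} would have a "
            "negative staying probability"
        )
    p[np.diag_indices(N_STATES)] = diag
    return p


def build_rate_matrix(p: np.ndarray, t_d: float) -> np.ndarray:
    """Transition rate matrix ``k_ij = p_ij / T_d`` (1/h), rows summing to 0.

    The shuttle data are measured over a single cell cycle, so the rates
    are the first-order approximation probability/observation-window
    rather than a matrix-logarithm embedding.
    """
    if not t_d > 0:
        raise ValueError(f"doubling time must be positive, got {t_d}")
    p = np.asarray(p, dtype=float)
    if p.shape != (N_STATES, N_STATES):
        raise ValueError(f"expected a 4x4 matrix, got shape {p.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition probability matrix must be row-stochastic")
    k = p / t_d
    np.fill_diagonal(k, 0.0)
    k[np.diag_indices(N_STATES)] = -k.sum(axis=1)
    return k


def growth_rates(t_d: float) -> np.ndarray:
    """Proliferation rate ln2/T_d (1/h), identical for all four subtypes."""
    if not t_d > 0:
        raise ValueError(f"doubling time must be positive, got {t_d}")
    return np.full(N_STATES, np.log(2.0) / t_d)


def build_rate_matrices(spec: TransitionSpec) -> RateMatrices:
    """Assemble P, K, the proliferation rates and A = K + diag(lam)."""
    p = build_transition_probabilities(spec)
    k = build_rate_matrix(p, spec.t_d)
    lam = growth_rates(spec.t_d)
    return RateMatrices(p=p, k=k, lam=lam, a=k + np.diag(lam))


def stationary_composition(k: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Stationary composition Z solving Z·K = 0 with unit sum.

    Computed from the null space of ``k.T``; inputs whose null space is
    not one-dimensional (disconnected chains) are rejected.
    """
    k = np.asarray(k, dtype=float)
    if k.shape != (N_STATES, N_STATES):
        raise ValueError(f"expected a 4x4 rate matrix, got shape {k.shape}")
    ns = null_space(k.T)
    if ns.shape[1] != 1:
        raise ValueError(
            f"rate matrix null space has dimension {ns.shape[1]}; the chain must "
            "have a single communicating class"
        )
    z = ns[:, 0]
    if z.sum() < 0:
        z = -z
    if np.any(z < -tol * max(1.0, np.abs(z).max())):
        raise ValueError("stationary vector has negative entries")
    z = np.clip(z, 0.0, None)
    return z / z.sum()


def evolve_fractions(z0, rates, t: float) -> np.ndarray:
    """Composition Z(t) from initial composition ``z0``.

    With equal proliferation rates across types, the composition obeys
    ``dZ/dt = Z·K``; the solution is the matrix exponential
    ``Z(t) = Z(0)·exp(K t)``.  ``rates`` may be a :class:`RateMatrices`
    or a bare 4x4 rate matrix.
    """
    k = rates.k if isinstance(rates, RateMatrices) else np.asarray(rates, dtype=float)
    z0 = np.asarray(z0, dtype=float)
    if abs(z0.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial composition must sum to 1, got {z0.sum()!r}")
    z = z0 @ expm(k * float(t))
    z = np.clip(z, 0.0, None)
    return z / z.sum()
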