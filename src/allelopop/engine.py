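"""Kinetic Monte Carlo solver of the coupled population balance equations.

The population of proliferating cells is represented by an explicit
sample of cell state vectors (per-allele NANOG and reporter contents,
size, allelic pattern).  Between discrete events every cell grows
deterministically: protein contents follow the closed-form birth–death
solution (or Euler–Maruyama steps when transcriptional noise is on) and
size grows exponentially at ln2/T_d.  Discrete events — allelic switches
and divisions — are scheduled by sampling an exponential interval of
quiescence from the total event rate and selecting the cell/event by
inverse-CDF lookup over the event rate matrix, with propensities frozen
over each interval and refreshed after every event.

Division draws the mother's division size from a Gaussian hazard
(``size_hazard`` mode) or occurs at the constant rate ln2/T_d
(``constant_rate`` mode); each element of the state vector is split
between the daughters by an independent symmetric-beta fraction, so
content is conserved exactly.  The sampler is a constant-volume Monte
Carlo while the population grows to a ceiling, then switches to a
constant-number scheme in which the daughters replace the mother and a
uniformly chosen other cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .expression import AllelePattern, CellState, ExpressionParams
from .markov import N_STATES, RateMatrices

LN2 = math.log(2.0)
SQRT2PI = math.sqrt(2.0 * math.pi)

#: Default Gaussian division-size parameters and symmetric-beta
#: partitioning shape, fitted previously for stem cells.
DEFAULT_MU = 0.465
DEFAULT_SIGMA = 0.104
DEFAULT_Q = 39.0


class ExtinctionError(RuntimeError):
    """Raised when the simulated population is empty."""


@dataclass(frozen=True)
class DivisionParams:
    """Division-size Gaussian (mu, sigma) and beta partition parameter q.

    ``hazard_cap`` bounds the division propensity when the Gaussian
    survival function underflows for abnormally large cells, keeping
    waiting times finite without affecting the bulk of the population.
    """

    mu: float = DEFAULT_MU
    sigma: float = DEFAULT_SIGMA
    q: float = DEFAULT_Q
    hazard_cap: float = 50.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.q > 0:
            raise ValueError("q must be positive")
        if not self.hazard_cap > 0:
            raise ValueError("hazard_cap must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level settings of the Monte Carlo solver."""

    n_initial: int = 1000
    n_cap: int = 10000
    t_end: float = 150.0
    seed: int = 0
    division_mode: str = "size_hazard"
    snapshot_every: float = 10.0
    scenario: str = "equilibrium"

    def __post_init__(self) -> None:
        if not self.n_initial >= 1:
            raise ValueError("n_initial must be at least 1")
        if not self.n_cap >= self.n_initial:
            raise ValueError("n_cap must be >= n_initial")
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")
        if self.division_mode not in ("size_hazard", "constant_rate"):
            raise ValueError(f"unknown division_mode {self.division_mode!r}")
        if not self.snapshot_every > 0:
            raise ValueError("snapshot_every must be positive")


def grow_size(v0, t, t_d: float):
    """Exponential size growth ``v0 * exp((ln2/T_d) t)``."""
    return np.asarray(v0, dtype=float) * np.exp((LN2 / t_d) * np.asarray(t, dtype=float))


def division_hazard(v, t_d: float, params: DivisionParams):
    """Size-dependent dividing rate Gamma(v) = r_v(v) * pdf / survival.

    With size growing at rate ``r_v(v) = (ln2/T_d) v`` and division sizes
    Gaussian(mu, sigma), the hazard per unit time is the Gaussian hazard
    per unit size times the growth speed.  Where the survival function
    underflows the value is capped at ``params.hazard_cap``.
    """
    v = np.asarray(v, dtype=float)
    x = (v - params.mu) / params.sigma
    pdf = np.exp(-0.5 * x * x) / (params.sigma * SQRT2PI)
    sf = 0.5 * erfc(x * (1.0 / math.sqrt(2.0)))
    rv = (LN2 / t_d) * v
    gamma = rv * pdf / np.maximum(sf, np.finfo(float).tiny)
    gamma = np.where(x >= 8.0, params.hazard_cap, np.minimum(gamma, params.hazard_cap))
    return gamma if gamma.ndim else float(gamma)


def sample_partition_fraction(q: float, rng: np.random.Generator, size=None):
    """Symmetric Beta(q, q) daughter fraction; q = inf forces an exact 0.5 split."""
    if math.isinf(q):
        return 0.5 if size is None else np.full(size, 0.5)
    if not q > 0:
        raise ValueError("q must be positive")
    return rng.beta(q, q, size=size)


def divide_cell(
    mother: CellState, params: DivisionParams, rng: np.random.Generator
) -> tuple[CellState, CellState]:
    """Split a mother cell into two daughters conserving every element.

    Independent beta fractions are drawn for n1, n2, r1, r2 and v;
    daughter A receives fraction x of each element and daughter B the
    complement, so sums are conserved to machine precision.  Both
    daughters inherit the mother's allelic pattern.
    """
    vals = np.array([mother.n1, mother.n2, mother.r1, mother.r2, mother.v])
    x = sample_partition_fraction(params.q, rng, size=5)
    a = x * vals
    b = vals - a
    da = CellState(n1=a[0], n2=a[1], r1=a[2], r2=a[3], v=a[4], pattern=mother.pattern)
    db = CellState(n1=b[0], n2=b[1], r1=b[2], r2=b[3], v=b[4], pattern=mother.pattern)
    return da, db


# ---------------------------------------------------------------------------
# population container and snapshots
# ---------------------------------------------------------------------------


class Population:
    """Vectorized cell population: parallel numpy arrays, one row per cell."""

    __slots__ = ("n1", "n2", "r1", "r2", "v", "state", "cell_id", "birth_time", "count", "_next_id")

    def __init__(self, capacity: int):
        self.n1 = np.zeros(capacity)
        self.n2 = np.zeros(capacity)
        self.r1 = np.zeros(capacity)
        self.r2 = np.zeros(capacity)
        self.v = np.zeros(capacity)
        self.state = np.zeros(capacity, dtype=np.int64)
        self.cell_id = np.zeros(capacity, dtype=np.int64)
        self.birth_time = np.zeros(capacity)
        self.count = 0
        self._next_id = 0

    def __len__(self) -> int:
        return self.count

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id

    def ensure_capacity(self, capacity: int) -> None:
        current = self.v.size
        if capacity <= current:
            return
        for name in ("n1", "n2", "r1", "r2", "v", "state", "cell_id", "birth_time"):
            arr = getattr(self, name)
            grown = np.zeros(capacity, dtype=arr.dtype)
            grown[:current] = arr
            setattr(self, name, grown)

    def cell(self, i: int) -> CellState:
        """Materialize one row as a :class:`CellState` (for inspection/tests)."""
        return CellState(
            n1=self.n1[i],
            n2=self.n2[i],
            r1=self.r1[i],
            r2=self.r2[i],
            v=self.v[i],
            pattern=AllelePattern.from_type(int(self.state[i])),
            cell_id=int(self.cell_id[i]),
        )


@dataclass
class PopulationSnapshot:
    """Timestamped copy of the population state."""

    time_h: float
    n1: np.ndarray
    n2: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    v: np.ndarray
    state: np.ndarray
    cell_id: np.ndarray

    def __len__(self) -> int:
        return self.state.size

    @property
    def n_total(self) -> np.ndarray:
        return self.n1 + self.n2

    @property
    def r_total(self) -> np.ndarray:
        return self.r1 + self.r2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": np.full(len(self), self.time_h),
                "cell_id": self.cell_id,
                "type": self.state,
                "n1": self.n1,
                "n2": self.n2,
                "n_total": self.n_total,
                "r_total": self.r_total,
                "v": self.v,
            }
        )

    @classmethod
    def of(cls, pop: Population, t: float) -> "PopulationSnapshot":
        m = pop.count
        return cls(
            time_h=float(t),
            n1=pop.n1[:m].copy(),
            n2=pop.n2[:m].copy(),
            r1=pop.r1[:m].copy(),
            r2=pop.r2[:m].copy(),
            v=pop.v[:m].copy(),
            state=pop.state[:m].copy(),
            cell_id=pop.cell_id[:m].copy(),
        )


def initialize_population(
    n_cells: int,
    composition: Sequence[float],
    expr: ExpressionParams,
    div: DivisionParams,
    t_d: float,
    rng: np.random.Generator,
    *,
    capacity: int | None = None,
    reporter_alleles: Sequence[int] = (),
    allele1_deleted: bool = False,
) -> Population:
    """Seed a population with the given type composition.

    Types are drawn from ``composition``; sizes emulate an asynchronous
    exponentially growing culture (a beta-split of a Gaussian division
    size, advanced by a uniform cell-cycle age); molecular contents start
    at the deterministic steady state of each cell's allelic pattern.
    """
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (N_STATES,) or np.any(comp < 0) or not math.isclose(comp.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("composition must be 4 non-negative fractions summing to 1")
    pop = Population(capacity or n_cells)
    pop.count = n_cells
    pop.state[:n_cells] = rng.choice(N_STATES, size=n_cells, p=comp) + 1
    pop.cell_id[:n_cells] = np.arange(1, n_cells + 1)
    pop._next_id = n_cells

    vd = np.clip(rng.normal(div.mu, div.sigma, size=n_cells), 1e-3, None)
    x = sample_partition_fraction(div.q, rng, size=n_cells)
    age = rng.random(n_cells)  # fraction of a cell cycle already elapsed
    pop.v[:n_cells] = x * vd * np.exp(LN2 * age)

    st = pop.state[:n_cells]
    a1 = ((st == 1) | (st == 2)) & (not allele1_deleted)
    a2 = (st == 1) | (st == 3)
    s1 = np.where(a1, expr.s_on, expr.s_off)
    s2 = np.where(a2, expr.s_on, expr.s_off)
    pop.n1[:n_cells] = s1 / expr.gamma_n
    pop.n2[:n_cells] = s2 / expr.gamma_n
    if 1 in reporter_alleles:
        pop.r1[:n_cells] = s1 / expr.gamma_r
    if 2 in reporter_alleles:
        pop.r2[:n_cells] = s2 / expr.gamma_r
    return pop


# ---------------------------------------------------------------------------
# event rates and selection
# ---------------------------------------------------------------------------


@dataclass
class EventRateMatrix:
    """Per-cell event propensities: three switch channels plus division.

    ``rates[n]`` holds the transition rates out of cell n's current state
    (columns 0–2, in ascending target-state order given by ``targets[n]``)
    and its division propensity (column 3).
    """

    rates: np.ndarray  # (n_cells, 4)
    targets: np.ndarray  # (n_cells, 3) target state ids for the switch columns
    total_rate: float


def _rate_lookup(k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-state switch rates/targets tables indexed by state id (row 0 unused)."""
    rates = np.zeros((N_STATES + 1, 3))
    targets = np.zeros((N_STATES + 1, 3), dtype=np.int64)
    for i in range(N_STATES):
        cols = [j for j in range(N_STATES) if j != i]
        rates[i + 1] = [max(k[i, j], 0.0) for j in cols]
        targets[i + 1] = [j + 1 for j in cols]
    return rates, targets


def build_event_rates(
    population: Population,
    rates: RateMatrices | np.ndarray,
    division_mode: str = "size_hazard",
    div_params: DivisionParams | None = None,
    t_d: float | None = None,
) -> EventRateMatrix:
    """Assemble the event rate matrix for the current population state."""
    m = population.count
    if m == 0:
        raise ExtinctionError("population is extinct")
    k = rates.k if isinstance(rates, RateMatrices) else np.asarray(rates, dtype=float)
    if t_d is None:
        if not isinstance(rates, RateMatrices):
            raise ValueError("t_d is required when passing a bare rate matrix")
        t_d = LN2 / rates.lam[0]
    lut_rates, lut_targets = _rate_lookup(k)
    st = population.state[:m]
    e = np.empty((m, 4))
    e[:, :3] = lut_rates[st]
    if division_mode == "size_hazard":
        e[:, 3] = division_hazard(population.v[:m], t_d, div_params or DivisionParams())
    elif division_mode == "constant_rate":
        e[:, 3] = LN2 / t_d
    else:
        raise ValueError(f"unknown division_mode {division_mode!r}")
    return EventRateMatrix(rates=e, targets=lut_targets[st], total_rate=float(e.sum()))


def sample_quiescence(total_rate: float, rng: np.random.Generator) -> float:
    """Exponential waiting time to the next division or switch event."""
    if not total_rate > 0:
        raise ValueError("total event rate must be positive")
    return rng.exponential(1.0 / total_rate)


class Event(NamedTuple):
    cell_index: int
    kind: str  # "divide" | "switch"
    target_state: int  # 0 for divisions


def select_event(e: EventRateMatrix, ran2: float) -> Event:
    """Inverse-CDF event selection over the flattened event rate matrix."""
    if not 0.0 <= ran2 < 1.0:
        raise ValueError("ran2 must lie in [0, 1)")
    cum = np.cumsum(e.rates.ravel())
    total = cum[-1]
    if not total > 0:
        raise ValueError("total event rate must be positive")
    idx = int(np.searchsorted(cum, ran2 * total, side="right"))
    idx = min(idx, cum.size - 1)
    row, col = divmod(idx, 4)
    if col == 3:
        return Event(row, "divide", 0)
    return Event(row, "switch", int(e.targets[row, col]))


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    snapshots: list[PopulationSnapshot]
    event_counts: dict[str, int]
    division_ages: np.ndarray
    population: Population = field(repr=False, default=None)

    @property
    def final(self) -> PopulationSnapshot:
        return self.snapshots[-1]


class Simulation:
    """Event-driven Monte Carlo simulation of the cell population.

    Parameters
    ----------
    rates : RateMatrices
        Allelic switching rate matrix and proliferation rates; the
        doubling time is recovered from ``rates.lam``.
    expr : ExpressionParams
        Single-cell production/degradation constants (``expr.eta > 0``
        switches the protein dynamics to the Euler–Maruyama SDE).
    div : DivisionParams
        Division-size Gaussian and partitioning parameters.
    config : SimulationConfig
        Population sizes, horizon, seed, division mode.
    reporter_alleles : sequence of {1, 2}
        Alleles carrying the knock-in reporter (empty for none).
    allele1_deleted : bool
        Heterozygous-knockout mode — allele 1 produces only the leak rate
        regardless of pattern (pair with a 3<->4-restricted rate matrix).
    initial_composition : length-4 sequence, optional
        Type fractions used to seed the population (defaults to the
        stationary composition of ``rates.k``).
    initial_population : Population, optional
        Continue from an existing population instead of seeding one.

    Five independent child random streams (initialization, quiescence,
    event selection, partitioning, SDE noise) are spawned from the master
    seed so that toggling one mode never perturbs the others.
    """

    def __init__(
        self,
        rates: RateMatrices,
        expr: ExpressionParams | None = None,
        div: DivisionParams | None = None,
        config: SimulationConfig | None = None,
        *,
        reporter_alleles: Sequence[int] = (),
        allele1_deleted: bool = False,
        initial_composition: Sequence[float] | None = None,
        initial_population: Population | None = None,
    ):
        from .markov import stationary_composition

        self.rates = rates
        self.expr = expr or ExpressionParams()
        self.div = div or DivisionParams()
        self.config = config or SimulationConfig()
        self.reporter_alleles = tuple(sorted(set(int(a) for a in reporter_alleles)))
        if any(a not in (1, 2) for a in self.reporter_alleles):
            raise ValueError("reporter_alleles must be a subset of {1, 2}")
        self.allele1_deleted = bool(allele1_deleted)
        self.t_d = LN2 / rates.lam[0]
        self._lut_rates, self._lut_targets = _rate_lookup(rates.k)

        ss = np.random.SeedSequence(self.config.seed)
        s_init, s_quiet, s_select, s_part, s_sde = ss.spawn(5)
        self._rng_init = np.random.Generator(np.random.PCG64(s_init))
        self._rng_quiet = np.random.Generator(np.random.PCG64(s_quiet))
        self._rng_select = np.random.Generator(np.random.PCG64(s_select))
        self._rng_part = np.random.Generator(np.random.PCG64(s_part))
        self._rng_sde = np.random.Generator(np.random.PCG64(s_sde))

        if initial_population is not None:
            self.pop = initial_population
            self.pop.ensure_capacity(self.config.n_cap)
        else:
            comp = (
                np.asarray(initial_composition, dtype=float)
                if initial_composition is not None
                else stationary_composition(rates.k)
            )
            self.pop = initialize_population(
                self.config.n_initial,
                comp,
                self.expr,
                self.div,
                self.t_d,
                self._rng_init,
                capacity=self.config.n_cap,
                reporter_alleles=self.reporter_alleles,
                allele1_deleted=self.allele1_deleted,
            )
        self.event_counts: dict[str, int] = {"division": 0}
        self._division_ages: list[float] = []
        self._init_caches()

    # -- per-cell caches (switch rates and production), updated incrementally

    def _init_caches(self) -> None:
        cap = self.pop.v.size
        self._sw = np.zeros((cap, 3))
        self._sw_sum = np.zeros(cap)
        self._tg = np.zeros((cap, 3), dtype=np.int64)
        self._s1 = np.zeros(cap)
        self._s2 = np.zeros(cap)
        m = self.pop.count
        st = self.pop.state[:m]
        self._sw[:m] = self._lut_rates[st]
        self._tg[:m] = self._lut_targets[st]
        self._sw_sum[:m] = self._sw[:m].sum(axis=1)
        a1 = ((st == 1) | (st == 2)) & (not self.allele1_deleted)
        a2 = (st == 1) | (st == 3)
        self._s1[:m] = np.where(a1, self.expr.s_on, self.expr.s_off)
        self._s2[:m] = np.where(a2, self.expr.s_on, self.expr.s_off)

    def _refresh_cell(self, i: int) -> None:
        st = int(self.pop.state[i])
        self._sw[i] = self._lut_rates[st]
        self._tg[i] = self._lut_targets[st]
        self._sw_sum[i] = self._sw[i].sum()
        on1 = st in (1, 2) and not self.allele1_deleted
        self._s1[i] = self.expr.s_on if on1 else self.expr.s_off
        self._s2[i] = self.expr.s_on if st in (1, 3) else self.expr.s_off

    # -- continuous dynamics -------------------------------------------------

    def _advance(self, dt: float) -> None:
        """Propagate every cell's proteins and size over a quiescent interval."""
        if dt <= 0:
            return
        m = self.pop.count
        ex = self.expr
        s1, s2 = self._s1[:m], self._s2[:m]
        if ex.eta == 0.0:
            decay_n = math.exp(-ex.gamma_n * dt)
            ss1 = s1 / ex.gamma_n
            ss2 = s2 / ex.gamma_n
            self.pop.n1[:m] = ss1 + (self.pop.n1[:m] - ss1) * decay_n
            self.pop.n2[:m] = ss2 + (self.pop.n2[:m] - ss2) * decay_n
            if self.reporter_alleles:
                decay_r = math.exp(-ex.gamma_r * dt)
                if 1 in self.reporter_alleles:
                    rr1 = s1 / ex.gamma_r
                    self.pop.r1[:m] = rr1 + (self.pop.r1[:m] - rr1) * decay_r
                if 2 in self.reporter_alleles:
                    rr2 = s2 / ex.gamma_r
                    self.pop.r2[:m] = rr2 + (self.pop.r2[:m] - rr2) * decay_r
        else:
            self._advance_sde(m, s1, s2, dt)
        self.pop.v[:m] *= math.exp((LN2 / self.t_d) * dt)

    def _advance_sde(self, m: int, s1: np.ndarray, s2: np.ndarray, dt: float) -> None:
        ex = self.expr
        remaining = dt
        while remaining > 1e-15:
            h = min(ex.sde_dt, remaining)
            sqh = math.sqrt(h)
            for arr, s, g, noisy in (
                (self.pop.n1, s1, ex.gamma_n, True),
                (self.pop.n2, s2, ex.gamma_n, True),
                (self.pop.r1, s1, ex.gamma_r, 1 in self.reporter_alleles),
                (self.pop.r2, s2, ex.gamma_r, 2 in self.reporter_alleles),
            ):
                if not noisy:
                    continue
                amp = arr[:m] if ex.noise_model == "state" else s
                xi = self._rng_sde.standard_normal(m)
                arr[:m] += (s - g * arr[:m]) * h + ex.eta * amp * sqh * xi
                np.clip(arr[:m], 0.0, None, out=arr[:m])
            remaining -= h

    # -- discrete events -----------------------------------------------------

    def _division_propensity(self, m: int) -> np.ndarray:
        if self.config.division_mode == "size_hazard":
            return division_hazard(self.pop.v[:m], self.t_d, self.div)
        return np.full(m, LN2 / self.t_d)

    def _apply_switch(self, i: int, target: int) -> None:
        key = f"switch_{self.pop.state[i]}_{target}"
        self.event_counts[key] = self.event_counts.get(key, 0) + 1
        self.pop.state[i] = target
        self._refresh_cell(i)

    def _divide(self, i: int, t: float) -> None:
        pop = self.pop
        self.event_counts["division"] += 1
        self._division_ages.append(t - pop.birth_time[i])
        x = sample_partition_fraction(self.div.q, self._rng_part, size=5)
        vals = np.array([pop.n1[i], pop.n2[i], pop.r1[i], pop.r2[i], pop.v[i]])
        a = x * vals
        b = vals - a
        if pop.count < self.config.n_cap:
            j = pop.count
            pop.count += 1
        else:
            j = int(self._rng_select.integers(pop.count - 1))
            if j >= i:
                j += 1
        for arr, va, vb in zip(
            (pop.n1, pop.n2, pop.r1, pop.r2, pop.v), a, b
        ):
            arr[i] = va
            arr[j] = vb
        pop.state[j] = pop.state[i]
        pop.cell_id[i] = pop.new_id()
        pop.cell_id[j] = pop.new_id()
        pop.birth_time[i] = t
        pop.birth_time[j] = t
        self._refresh_cell(j)

    # -- main loop -----------------------------------------------------------

    def run(self) -> SimulationResult:
        cfg = self.config
        snaps: list[PopulationSnapshot] = [PopulationSnapshot.of(self.pop, 0.0)]
        snap_times = list(np.arange(cfg.snapshot_every, cfg.t_end, cfg.snapshot_every))
        snap_times.append(cfg.t_end)
        t = 0.0
        si = 0
        while si < len(snap_times):
            boundary = snap_times[si]
            m = self.pop.count
            if m == 0:
                raise ExtinctionError("population is extinct")
            # per-cell total event rate: cached switch rates + division hazard
            row_tot = self._sw_sum[:m] + self._division_propensity(m)
            cum = np.cumsum(row_tot)
            total = float(cum[-1])
            if total <= 0:
                self._advance(boundary - t)
                t = boundary
                snaps.append(PopulationSnapshot.of(self.pop, t))
                si += 1
                continue
            dt = sample_quiescence(total, self._rng_quiet)
            if t + dt >= boundary:
                # no event before the checkpoint; the exponential clock is
                # memoryless, so re-drawing after the checkpoint is exact
                self._advance(boundary - t)
                t = boundary
                snaps.append(PopulationSnapshot.of(self.pop, t))
                si += 1
                continue
            self._advance(dt)
            t += dt
            # inverse-CDF selection: first the cell, then its event channel
            u = float(self._rng_select.random()) * total
            i = min(int(np.searchsorted(cum, u, side="right")), m - 1)
            rem = u - (cum[i - 1] if i else 0.0)
            sw = self._sw[i]
            if rem < sw[0]:
                self._apply_switch(i, int(self._tg[i, 0]))
            elif rem < sw[0] + sw[1]:
                self._apply_switch(i, int(self._tg[i, 1]))
            elif rem < self._sw_sum[i]:
                self._apply_switch(i, int(self._tg[i, 2]))
            else:
                self._divide(i, t)
        return SimulationResult(
            snapshots=snaps,
            event_counts=dict(self.event_counts),
            division_ages=np.asarray(self._division_ages),
            population=self.pop,
        )


def run(
    rates: RateMatrices,
    expr: ExpressionParams | None = None,
    div: DivisionParams | None = None,
    config: SimulationConfig | None = None,
    **kwargs,
) -> SimulationResult:
    """Convenience wrapper: build a :class:`Simulation` and run it."""
    return Simulation(rates, expr, div, config, **kwargs).run()
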