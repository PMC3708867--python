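# Methods

## Model structure

The model couples three layers:

1. **Allelic switching** — a four-state time-homogeneous Markov chain
   over the on/off patterns of the two *Nanog* alleles (1 = on/on,
   2 = on/off, 3 = off/on, 4 = off/off).
2. **Single-cell expression** — per-allele zeroth-order production and
   first-order degradation of the native protein and, optionally, a
   knock-in reporter sharing the allele's on/off state.
3. **Population balance** — a kinetic Monte Carlo ensemble of cells
   with asynchronous exponential size growth, size-dependent division,
   beta-partitioning of all state-vector elements at mitosis, and
   constant-number population control.

Differentiation, cell death, mRNA dynamics, promoter bursting within an
"on" allele, and regulatory-network coupling (Oct4/Sox2) are outside the
model's scope.

## Chain construction

The chain is built from observables rather than free rate constants:
the equilibrium composition Z\* and the fraction of the total population
shuttling between each linked pair of subtypes per cell cycle.
Assuming the two directions of each shuttle carry equal mass, detailed
balance z\*ᵢ pᵢⱼ = z\*ⱼ pⱼᵢ = shuttle(i,j)/2 determines all off-diagonal
transition probabilities; rows are completed to 1.  Z\* is then
stationary *by construction* — this is an exact algebraic property, and
the test suite verifies it for randomized specifications.

Because the shuttle data are measured over one cell cycle, rates use
the first-order approximation kᵢⱼ = pᵢⱼ/T_d rather than a
matrix-logarithm embedding.  Transitions 1↔4 and 2↔3 are excluded:
either would require both alleles to switch in the same instant.

Defaults (LIF/serum culture): Z\* = (0.14, 0.28, 0.28, 0.30),
shuttle(1,2) = shuttle(1,3) = shuttle(2,4) = shuttle(3,4) = 0.12,
T_d = 10 h.  Only the 1↔2 shuttle fraction is directly quoted in the
source data; the other linked pairs default to the same value by the
no-allele-bias symmetry between alleles and between types 2 and 3.  All
values are config-overridable (`[markov]` section), including an
alternative composition for 2i-like conditions.

## Single-cell expression

Parameters, with provenance and defaults:

| parameter | default | meaning |
|---|---|---|
| `s_on` | 1000 molecules/h | production per active allele |
| `s_off` | 10 molecules/h | leak production (1% of `s_on`) |
| t₁⁄₂ (NANOG) | 2 h | γ_n = ln2/2 ≈ 0.347/h |
| t₁⁄₂ (reporter) | 20 h | γ_r = ln2/20 ≈ 0.0347/h (GFP-like) |
| `noise_eta` | 0 (0.2 for the noise study) | SDE noise fraction |
| `sde_dt_hours` | 0.01 | Euler–Maruyama step |

The deterministic dynamics admit the exact solution
N(t) = s/γ + (N₀ − s/γ)e^(−γt), used everywhere η = 0 — there is no
integration error, and propagation composes exactly over consecutive
intervals.  Steady states: 5770.8 molecules (biallelic), 2914.2
(monoallelic), 57.7 (silent, leak only) — the on and off states differ
by two orders of magnitude, and the mean over expressing cells at the
observed 1:4 biallelic:monoallelic ratio is ≈ 3486 molecules.

The SDE variant adds η·N·√dt·ξ per step (noise amplitude linear in the
current protein level; an alternative amplitude proportional to the
production rate is selectable via `noise_model = "production"`).
Trajectories are clipped at zero — molecule counts cannot go negative,
and a reflecting floor is the simplest contract-preserving choice.  The
step dt = 0.01 h is two orders of magnitude below the protein half-life
and three below the cell cycle.  Protein contents are continuous
concentrations, not integer copy numbers: at 10³–10⁴ molecules the
birth–death shot noise is small compared to the modeled allelic and
partitioning noise, and the reference dynamics are ODE/SDE, not a
chemical master equation.

A knock-in reporter co-expresses from the designated allele(s) with the
same production constants and its own degradation rate.  The knock-in
does **not** abolish native production from that allele — this
co-expression model is required for the NANOG-high/reporter-low
subpopulation that single-allele reporter lines exhibit.

## Population Monte Carlo

Cell size grows exponentially, r_v(v) = (ln2/T_d)·v.  In the default
`size_hazard` division mode the dividing rate is
Γ(v) = r_v(v)·φ(v; μ, σ)/(1 − Φ(v; μ, σ)) — the hazard implied by a
Gaussian division-size distribution (μ = 0.465, σ = 0.104 size units)
traversed at speed r_v.  Where the survival function underflows
(abnormally large cells), Γ is capped at 50/h to keep waiting times
finite without affecting the bulk.  A `constant_rate` mode (division
propensity λ = ln2/T_d for every cell) is also provided; the emergent
mean inter-division time of the default mode equals T_d within the
tested 15%, so the two modes agree on population kinetics.

The event loop freezes all propensities over each interval of
quiescence (standard first-order kinetic MC) and refreshes them after
every event.  The interval is exponential with the total rate of the
event matrix E (one row per cell: the three switch rates out of the
cell's current subtype plus its division propensity); a single uniform
variate selects the cell and event by inverse CDF over the flattened
cumulative entries.  Snapshot checkpoints truncate an interval without
bias — the exponential clock is memoryless.

At division, each of n₁, n₂, r₁, r₂, v is split by an *independent*
symmetric Beta(q, q) fraction (q = 39; daughter/mother ratio
sd ≈ 0.056), so every element is conserved to machine precision.  Below
the population ceiling both daughters are kept (constant-volume MC); at
the ceiling (default 10,000 cells) the daughters replace the mother and
one uniformly chosen other cell (constant-number MC).

**Randomness**: one master seed spawns five independent child streams
(initialization, quiescence, event selection, partitioning, SDE noise),
so toggling one mechanism never perturbs the draws of another;
identical seeds give bit-identical runs.

**Initialization**: subtypes are drawn from the requested composition;
sizes emulate an asynchronous culture (Beta-split of a Gaussian
division size, advanced by a uniform cell-cycle age); molecular
contents start at the deterministic steady state of each cell's
pattern.  Since the source gives no initial condition beyond subtype
composition, equilibrium statistics are read from late snapshots —
every equilibrium scenario runs ≥ 120 h, more than twice the slowest
chain relaxation time (≈ 23 h) and several reporter half-lives, before
the analysis snapshot.

## Scenarios and statistics

- **Equilibrium / reconstitution** — composition fractions per
  snapshot; the reconstitution convergence time is the first time the
  maximum absolute deviation from Z\* drops below 0.02 and stays there
  for 20 h.
- **NANOG⁺ gating** — total NANOG > 500 molecules, mimicking an
  isotype-control gate; the tests include a 300–800 molecule
  sensitivity sweep (the fraction moves by < 5 points).
- **Peak counting** — the reported "number of peaks" is made
  reproducible as: histogram of log₁₀(N+1) with 60 bins, 3-bin moving
  average, local maxima with prominence ≥ 5% of the modal bin height.
  Protein levels span two decades, hence the log axis.  The
  two-dimensional analogue (for the four clusters at the vertices of a
  square in the N₁–N₂ plane) smooths a 40×40 log-log histogram, takes
  3×3-neighbourhood maxima at ≥ 10% of the modal bin, and merges maxima
  within 3 bins (single linkage) to absorb plateau ties and the ridges
  formed by cells in transit between subtypes.
- **Reporter fidelity** — Pearson ρ between per-cell totals r₁+r₂ and
  n₁+n₂ on one equilibrium snapshot of the full population, on raw
  (not log) scale; the near-unit ρ of the matched two-allele insertion
  supports the raw-scale choice.  CV is population sd/mean.
- **Shutoff** — a non-switching population (all cells type 1,
  single-allele reporter, mismatched half-lives) is equilibrated, then
  transcription of both genes stops.  By default the shutoff is
  complete (production 0, as under a transcriptional inhibitor, the
  experiment this scenario emulates).  With production demoted to the
  off-state leak instead (`shutoff_production="leak"`), the native
  protein settles at the 57.7-molecule leak floor within a few
  half-lives and its cross-cell structure — hence the reporter/native
  correlation — is erased by ~15 h; complete inhibition preserves the
  correlation over the reporter half-life.  Both variants are exposed.
- **Knockout** — allele 1's output is pinned to the off state for the
  whole run.  By default the cell still traverses all four regulatory
  subtypes (`chain="full"`): the deletion silences the allele's
  product, not the locus-level switching dynamics, so NANOG is made
  whenever allele 2 is active (types 1 and 3, 42% of cells at
  equilibrium).  A variant restricting switching to the functional
  allele (states 3↔4 only, `chain="restricted"`) is provided; it
  predicts a higher positive fraction (~48% before smearing) and is
  not the default.  The "five cell cycles" reconstitution statistic is
  measured 5·T_d = 50 h after an all-off start at the off-state steady
  state.
- **Switching lags** — closed-form crossing times of the deterministic
  dynamics plus an empirical single-cell lineage simulator.  Depletion
  (entry into type 4) to twice the silent steady state takes 13.3 h
  from the biallelic and 11.3 h from the monoallelic steady state
  (15–20 h to a 10% band), while build-up from silent to 80% of the
  monoallelic steady state takes 4.6 h — the asymmetry holds for every
  parameterization with s_on ≫ s_off.

## What the simulations do and do not emulate

Populations are synthetic: the generator reproduces the observed
subtype composition, shuttle fractions, doubling time, division-size
statistics and protein kinetics, but not measurement effects real flow
cytometry adds (instrument noise, autofluorescence, spectral spillover,
gating artifacts), extrinsic niche signalling, or cell-cycle-dependent
transcription.  Passing tests therefore demonstrate the *mechanistic
sufficiency* of allelic regulation plus division noise for the observed
heterogeneity patterns — not a calibrated fit to any particular
cytometry data set.

## Problem sizes

Library defaults target a 10,000-cell ceiling.  The test suite runs
populations of 1,500–8,000 cells for 50–150 simulated hours;
`scripts/acceptance.py` uses 5,000-cell populations, 150 h horizons and
three replicate seeds per stochastic quantity.  At these sizes the
Monte Carlo error on composition fractions is below one percentage
point per replicate (lineage drift dominates the multinomial term), and
correlations are stable to ±0.01 across seeds.

## Known limitations

- Composition fractions at a few thousand cells drift on the slow
  chain-relaxation timescale (a bounded branching process has larger
  fluctuations than an i.i.d. multinomial sample); composition
  assertions therefore use ≥ 5,000 cells or seed averaging.
- The division hazard and the event-matrix description of proliferation
  are reconciled by offering both modes; results are validated under
  `size_hazard`, and the constant-rate mode is the analytically
  transparent fallback.
- The shuttle fractions of three of the four linked pairs rest on a
  symmetry argument, not direct measurement; all are config-exposed.
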