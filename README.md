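# allelopop

Stochastic population-balance simulation of **allelically regulated Nanog
expression** in proliferating mouse embryonic stem cells (mESCs).

NANOG levels in self-renewing stem cell cultures are strikingly
heterogeneous.  This package implements a multiscale model in which that
heterogeneity arises from the independent on/off control of the two
*Nanog* gene copies: cells occupy one of four allelic subtypes —
biallelic (type 1), monoallelic (types 2 and 3) and silent (type 4) —
and shuttle stochastically between them on the timescale of the cell
cycle, while each allele produces protein with simple birth–death
kinetics and cells grow, divide and partition their contents noisily.
The simulator reproduces the trimodal/bimodal NANOG population profiles,
quantifies how faithfully knock-in fluorescent reporters track the
native protein, and predicts the NANOG signature of heterozygous
*Nanog*⁺/⁻ knockouts.

## Model

**Allelic switching chain.**  Cell types 1–4 form a time-homogeneous
Markov chain.  From the observed equilibrium composition
Z\* = (0.14, 0.28, 0.28, 0.30) and the fraction of the population
shuttling between linked subtypes per cell cycle (12% between types 1
and 2, for instance), detailed balance

&nbsp;&nbsp;&nbsp;&nbsp;z\*ᵢ pᵢⱼ = z\*ⱼ pⱼᵢ = shuttle(i, j) / 2

fixes the per-cycle transition probabilities P (p₁₄ = p₄₁ = 0: both
alleles never flip at once).  Transition rates are kᵢⱼ = pᵢⱼ/T_d with
doubling time T_d = 10 h, and every subtype proliferates at
λ = ln2/T_d.  The composition obeys dZ/dt = Z·K with stationary point
Z\*.

**Single-cell expression.**  Each allele j produces NANOG at
s_on = 1000 molecules/h when active and at a 1% leak s_off = 10 when
silent, and protein degrades with rate γ = ln2/t₁⁄₂ (t₁⁄₂ = 2 h for
NANOG, 20 h for a GFP reporter driven by the same promoter):

&nbsp;&nbsp;&nbsp;&nbsp;dNⱼ/dt = s(allele j) − γ Nⱼ,

solved in closed form between discrete events; an optional
Euler–Maruyama variant adds multiplicative white noise η·N·dW.

**Population balance.**  The number densities of the four subtypes over
the state vector (N₁, N₂, v) are evolved with a kinetic Monte Carlo
solver: exponential intervals of quiescence drawn from the total event
rate, inverse-CDF selection of the next event (allelic switch or
division) from a per-cell event rate matrix, size growth r_v = λv, a
Gaussian division-size hazard (μ = 0.465, σ = 0.104), symmetric
Beta(q, q) partitioning of every state-vector element at mitosis
(q = 39), and constant-volume → constant-number population control at a
configurable ceiling.

## Worked example

```python
import allelopop as ap
from dataclasses import replace
from allelopop.config import default_config

cfg = default_config()
cfg = cfg.with_(sim=replace(cfg.sim, n_initial=2000, n_cap=2000, t_end=150.0))
result = ap.run_equilibrium(cfg, seed=1)
for key in ("z1", "z2", "z3", "z4", "frac_positive", "cv_nanog", "peak_count"):
    print(f"{key:14s} {result.stats[key]:.4f}")
```

prints

```
z1             0.1380
z2             0.2570
z3             0.3125
z4             0.2925
frac_positive  0.7455
cv_nanog       0.7301
peak_count     3.0000
```

i.e. a 2,000-cell culture at dynamic equilibrium sits near the observed
subtype composition (14/28/28/30%, up to Monte Carlo drift), ~74% of
cells exceed the 500-molecule NANOG⁺ gate, the population CV is ~0.74,
and the total-NANOG distribution is trimodal (low/middle/high peaks for
silent/monoallelic/biallelic cells).  Adding 20% transcriptional noise
(`noise_eta = 0.2`) merges the middle and high peaks into the familiar
bimodal profile.

The same machinery drives the other in-silico experiments:
`run_reconstitution` (uniform subtype populations re-establish Z\*
within 50–100 h), `run_reporter_study` (reporter/native Pearson
correlation for one- or two-allele knock-ins and matched or mismatched
half-lives), `run_shutoff_study` (transcriptional shutoff without
allelic regulation) and `run_knockout_study` (single-allele deletion).

A CLI mirrors the scenarios:

```
allelopop run --scenario knockout --cells 3000 --cap 3000 --t-end 120 --seed 7 --out runs/ko
allelopop sweep --parameter s_on --factors 0.8,1.0,1.2 --cells 2000 --cap 2000
allelopop stats runs/ko/snapshots/snapshot_t00120.00.csv
```

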