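"""Summary statistics for simulated populations.

Implements the read-outs reported for the in-silico experiments:
subtype composition, NANOG-positive fractions against a flow-cytometry
style gate, coefficients of variation, reporter/native Pearson
correlation, and an explicit, reproducible operationalization of peak
counting in (log-scaled) protein histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter, uniform_filter
from scipy.signal import find_peaks

from .engine import PopulationSnapshot
from .markov import N_STATES

#: Gate separating NANOG- from NANOG+ cells, mimicking an isotype control.
DEFAULT_POSITIVE_CUTOFF = 500.0


@dataclass(frozen=True)
class Threshold:
    nanog_positive_cutoff: float = DEFAULT_POSITIVE_CUTOFF

    def __post_init__(self) -> None:
        if not self.nanog_positive_cutoff > 0:
            raise ValueError("positivity cutoff must be positive")


def composition_fractions(snapshot: PopulationSnapshot) -> np.ndarray:
    """Fraction of cells in each allelic subtype 1–4 (sums to 1)."""
    if len(snapshot) == 0:
        raise ValueError("empty snapshot")
    counts = np.bincount(snapshot.state, minlength=N_STATES + 1)[1:]
    return counts / counts.sum()


def nanog_positive_fraction(
    snapshot: PopulationSnapshot, threshold: Threshold | float = DEFAULT_POSITIVE_CUTOFF
) -> float:
    """Fraction of cells whose total NANOG exceeds the positivity gate."""
    cutoff = threshold.nanog_positive_cutoff if isinstance(threshold, Threshold) else float(threshold)
    if not cutoff > 0:
        raise ValueError("positivity cutoff must be positive")
    if len(snapshot) == 0:
        raise ValueError("empty snapshot")
    return float(np.mean(snapshot.n_total > cutoff))


def coefficient_of_variation(values) -> float:
    """Population standard deviation over mean (the heterogeneity metric)."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if not mean > 0:
        raise ValueError("CV requires a positive mean")
    return float(values.std(ddof=0) / mean)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def histogram_peaks(
    values,
    bins: int = 60,
    smooth: int = 3,
    prominence_frac: float = 0.05,
    log_scale: bool = True,
) -> int:
    """Count modes of the protein distribution.

    The histogram is taken on ``log10(x + 1)`` (protein levels span two
    orders of magnitude), smoothed with a ``smooth``-bin moving average,
    and local maxima with prominence of at least ``prominence_frac`` of
    the modal bin height are counted.  Zero-padding at both ends lets
    boundary modes register.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError("peak counting needs at least 100 values")
    data = np.log10(values + 1.0) if log_scale else values
    hist, _ = np.histogram(data, bins=bins)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        hist = np.convolve(hist, kernel, mode="same")
    padded = np.concatenate([[0.0], hist, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_frac * hist.max())
    return int(len(peaks))


def histogram_modes_2d(
    x,
    y,
    bins: int = 40,
    smooth: int = 3,
    floor_frac: float = 0.10,
    merge_distance: int = 3,
) -> int:
    """Count modes of the joint (log-scaled) distribution of two levels.

    Used to verify that the per-allele NANOG scatter clusters at the
    four vertices of a square.  The 2-D histogram of
    ``(log10(x+1), log10(y+1))`` is mean-smoothed; bins that are local
    maxima of their 3x3 neighbourhood and at least ``floor_frac`` of the
    modal bin are mode candidates, and candidates within Chebyshev
    distance ``merge_distance`` of each other (plateau ties, ridge
    shoulders from cells in transit between subtypes) are merged into a
    single mode by single linkage.
    """
    lx = np.log10(np.asarray(x, dtype=float) + 1.0)
    ly = np.log10(np.asarray(y, dtype=float) + 1.0)
    hist, _, _ = np.histogram2d(lx, ly, bins=bins)
    if smooth > 1:
        hist = uniform_filter(hist, size=smooth, mode="constant")
    local_max = (hist == maximum_filter(hist, size=3, mode="constant")) & (hist > 0)
    significant = hist >= floor_frac * hist.max()
    candidates = np.argwhere(local_max & significant)
    if candidates.shape[0] == 0:
        return 0
    # single-linkage clustering at Chebyshev distance <= merge_distance
    n = candidates.shape[0]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.max(np.abs(candidates[i] - candidates[j])) <= merge_distance:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def crossing_time(n0: float, s: float, gamma: float, target: float) -> float:
    """Time for the deterministic birth–death ODE to reach ``target``.

    Solves ``target = s/g + (n0 - s/g) e^{-g t}`` for t.  Returns 0 if
    the trajectory starts at (or past) the target, and raises if the
    target is unreachable (on the far side of the steady state).
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    ss = s / gamma
    if target == n0:
        return 0.0
    d0 = n0 - ss
    if d0 == 0:
        raise ValueError(f"target {target} is unreachable from steady state {ss}")
    ratio = (target - ss) / d0
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"target {target} is unreachable from {n0} (steady state {ss})")
    return float(-np.log(ratio) / gamma)
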