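"""Circular time-of-day conventions, binning, histograms, and the overlap coefficient.

The 24-h day is identified with the unit circle (2π rad = 24 h, 0 rad = 00:00),
divided into ``J`` equal bins. Activity patterns are represented as simplex
vectors of per-bin proportions; agreement between two patterns is measured by
the coefficient of overlapping Δ = Σ_j min(f1_j, f2_j) ∈ [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TimeGrid",
    "ActivityHistogram",
    "radians_to_hours",
    "assign_bin",
    "histogram_from_times",
    "bin_probabilities_from_shape",
    "overlap_delta",
]

_HOURS_PER_DAY = 24.0
_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class TimeGrid:
    """An equal-width partition of the 24-h day into ``n_bins`` time-of-day bins.

    Parameters
    ----------
    n_bins
        Number of bins J (default 24 → hourly bins). Must be ≥ 2.
    """

    n_bins: int = 24

    def __post_init__(self) -> None:
        if not isinstance(self.n_bins, (int, np.integer)) or self.n_bins < 2:
            raise ValueError(f"n_bins must be an integer >= 2, got {self.n_bins!r}")

    @property
    def bin_width(self) -> float:
        """Bin width in hours (Δt = 24 / J)."""
        return _HOURS_PER_DAY / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        """Bin edges in hours, length J + 1, from 0 to 24."""
        return np.linspace(0.0, _HOURS_PER_DAY, self.n_bins + 1)


@dataclass(frozen=True)
class ActivityHistogram:
    """A diel activity pattern: non-negative per-bin proportions summing to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size < 2:
            raise ValueError("probs must be a 1-D array with at least 2 entries")
        if not np.all(np.isfinite(probs)):
            raise ValueError("probs must be finite")
        if np.any(probs < 0):
            raise ValueError("probs must be non-negative")
        if abs(float(probs.sum()) - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"probs must sum to 1 (got {probs.sum()!r})")
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @property
    def n_bins(self) -> int:
        return self.probs.size

    def __len__(self) -> int:
        return self.probs.size


def radians_to_hours(angle: float | np.ndarray) -> float | np.ndarray:
    """Map an angle on the circle to hour-of-day in [0, 24).

    The convention is 0 rad = 00:00 and 2π rad = 24 h, so π → 12.0 (midday)
    and 3π/2 → 18.0. Angles outside [0, 2π) wrap modulo one day.
    """
    arr = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("angle must be finite")
    hours = np.mod(arr * (_HOURS_PER_DAY / (2.0 * math.pi)), _HOURS_PER_DAY)
    # mod can return 24.0 for tiny negative inputs due to rounding
    hours = np.where(hours >= _HOURS_PER_DAY, 0.0, hours)
    if np.isscalar(angle) or arr.ndim == 0:
        return float(hours)
    return hours


def assign_bin(hour: float | np.ndarray, grid: TimeGrid) -> int | np.ndarray:
    """Assign hour-of-day value(s) to half-open bins [j·Δt, (j+1)·Δt).

    Hour 24.0 wraps to bin 0. Negative or non-finite hours are rejected.
    """
    arr = np.asarray(hour, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("hour must be finite")
    if np.any(arr < 0):
        raise ValueError("hour must be non-negative")
    bins = np.floor(np.mod(arr, _HOURS_PER_DAY) / grid.bin_width).astype(np.int64)
    # guard against floor(x/width) == J from float round-up at the seam
    bins = np.minimum(bins, grid.n_bins - 1)
    if np.isscalar(hour) or arr.ndim == 0:
        return int(bins)
    return bins


def histogram_from_times(times, grid: TimeGrid) -> ActivityHistogram:
    """Empirical activity histogram from a collection of hour-of-day values."""
    arr = np.asarray(times, dtype=float)
    if arr.size == 0:
        raise ValueError("times must contain at least one value")
    bins = assign_bin(arr, grid)
    counts = np.bincount(np.atleast_1d(bins), minlength=grid.n_bins)
    return ActivityHistogram(counts / counts.sum())


def bin_probabilities_from_shape(shape, grid: TimeGrid) -> ActivityHistogram:
    """Exact per-bin mass of a circular mixture density.

    Integrates each von Mises mixture component over every bin using CDF
    differences on the circle, giving the noiseless "true histogram" that a
    simulated dataset converges to. Uniform components (κ = 0) contribute
    1/J per bin exactly.
    """
    from .simulate import ActivityShape  # local import: avoids a module cycle

    if not isinstance(shape, ActivityShape):
        raise TypeError("shape must be an ActivityShape")
    edges_rad = grid.edges * (2.0 * math.pi / _HOURS_PER_DAY)
    probs = np.zeros(grid.n_bins)
    for mu, kappa, weight in shape.components:
        if kappa == 0.0:
            probs += weight / grid.n_bins
        else:
            # von Mises CDF on [edge_j, edge_{j+1}]; scipy's vonmises is
            # periodic, so differences of its CDF give exact arc masses.
            cdf = stats.vonmises.cdf(edges_rad, kappa, loc=mu)
            probs += weight * np.diff(cdf)
    probs = np.clip(probs, 0.0, None)
    return ActivityHistogram(probs / probs.sum())


def overlap_delta(f1: ActivityHistogram, f2: ActivityHistogram) -> float:
    """Coefficient of overlapping Δ between two binned activity patterns.

    Δ = Σ_j min(f1_j, f2_j), the shared area of the two distributions. With
    per-bin proportions the bin width is already absorbed, so Δ ∈ [0, 1] with
    Δ = 1 exactly when the histograms coincide.
    """
    p1 = f1.probs if isinstance(f1, ActivityHistogram) else np.asarray(f1, dtype=float)
    p2 = f2.probs if isinstance(f2, ActivityHistogram) else np.asarray(f2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError(f"histogram lengths differ: {p1.size} vs {p2.size}")
    return float(np.minimum(p1, p2).sum())
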