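"""Synthetic detection datasets with known truth.

Generates AI-style detection tables in which a known fraction of records are
false positives: detection times for true records are drawn from a von Mises
mixture on the circle (the species' diel activity pattern), false-positive
times either uniformly over the day or from a night-centered von Mises, and a
randomly chosen subset of records is flagged as human-verified with its
ground-truth label exposed.

False-positive and verified counts are deterministic rounded products rather
than binomial draws, so replicate-to-replicate variation reflects only the
sampling of detection times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import TimeGrid, assign_bin, radians_to_hours

__all__ = [
    "DEFAULT_KAPPA",
    "ActivityShape",
    "ScenarioConfig",
    "SimulatedDataset",
    "preset_shape",
    "sample_times",
    "simulate_dataset",
    "apply_verification",
]

#: Default von Mises concentration for peaked components. The resulting peaks
#: span roughly 4-6 hourly bins (circular SD ≈ 1.4 h).
DEFAULT_KAPPA = 8.0

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class ActivityShape:
    """A mixture of von Mises components describing a circular density.

    Each component is a ``(mean_direction, concentration, weight)`` triple with
    the mean direction in radians (0 rad = midnight, π = midday) and κ ≥ 0
    (κ = 0 degenerates to the circular uniform). Weights must sum to 1.
    """

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        comps = tuple(
            (float(mu), float(kappa), float(w)) for mu, kappa, w in self.components
        )
        if len(comps) == 0:
            raise ValueError("shape needs at least one component")
        for mu, kappa, w in comps:
            if not (math.isfinite(mu) and math.isfinite(kappa) and math.isfinite(w)):
                raise ValueError("component parameters must be finite")
            if kappa < 0:
                raise ValueError("concentration kappa must be >= 0")
            if w < 0:
                raise ValueError("component weights must be >= 0")
        if abs(sum(w for _, _, w in comps) - 1.0) > _WEIGHT_TOL:
            raise ValueError("component weights must sum to 1")
        object.__setattr__(self, "components", comps)


def preset_shape(name: str, kappa: float = DEFAULT_KAPPA) -> ActivityShape:
    """Named activity/error shapes used throughout the simulation studies.

    ``unimodal``    one peak at π/2 (06:00)
    ``bimodal``     equal-weight peaks at π/2 and 3π/2 (06:00, 18:00)
    ``trimodal``    equal-weight peaks at π/2, π, 3π/2 (06:00, 12:00, 18:00)
    ``skewed_true`` one midday peak at π (12:00)
    ``night_fp``    night-centered false-positive peak at 3π/2 (18:00)
    ``uniform_fp``  flat over the day (κ = 0)
    """
    half_pi = math.pi / 2.0
    presets = {
        "unimodal": [(half_pi, kappa, 1.0)],
        "bimodal": [(half_pi, kappa, 0.5), (3 * half_pi, kappa, 0.5)],
        "trimodal": [
            (half_pi, kappa, 1 / 3),
            (math.pi, kappa, 1 / 3),
            (3 * half_pi, kappa, 1 / 3),
        ],
        "skewed_true": [(math.pi, kappa, 1.0)],
        "night_fp": [(3 * half_pi, kappa, 1.0)],
        "uniform_fp": [(0.0, 0.0, 1.0)],
    }
    try:
        comps = presets[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(presets)}"
        ) from None
    return ActivityShape(tuple(comps))


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative settings for one simulated detection dataset."""

    n_detections: int = 2000
    fp_rate: float = 0.05
    verification_fraction: float = 0.0
    true_shape: ActivityShape = field(
        default_factory=lambda: preset_shape("unimodal")
    )
    fp_structure: str = "uniform"  # "uniform" or "skewed"
    fp_shape: ActivityShape | None = None
    grid: TimeGrid = field(default_factory=TimeGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_detections < 1:
            raise ValueError("n_detections must be >= 1")
        if not 0.0 <= self.fp_rate <= 1.0:
            raise ValueError("fp_rate must be in [0, 1]")
        if not 0.0 <= self.verification_fraction <= 1.0:
            raise ValueError("verification_fraction must be in [0, 1]")
        if self.fp_structure not in ("uniform", "skewed"):
            raise ValueError("fp_structure must be 'uniform' or 'skewed'")
        if self.fp_shape is None:
            default_fp = (
                preset_shape("uniform_fp")
                if self.fp_structure == "uniform"
                else preset_shape("night_fp")
            )
            object.__setattr__(self, "fp_shape", default_fp)


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated detection table with ground truth attached.

    Arrays are aligned per record: detection time (hours), time bin, whether
    the record is genuinely the target species, and whether it was verified
    (for verified records the ground-truth flag doubles as the human label).
    """

    times: np.ndarray
    bins: np.ndarray
    is_true: np.ndarray
    verified: np.ndarray
    config: ScenarioConfig

    def __post_init__(self) -> None:
        n = self.config.n_detections
        for name in ("times", "bins", "is_true", "verified"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")

    @property
    def n_records(self) -> int:
        return self.times.size


def sample_times(shape: ActivityShape, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` detection times (hour-of-day) from a von Mises mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = np.array([w for _, _, w in shape.components])
    membership = rng.choice(len(weights), size=n, p=weights / weights.sum())
    angles = np.empty(n)
    for k, (mu, kappa, _) in enumerate(shape.components):
        mask = membership == k
        m = int(mask.sum())
        if m == 0:
            continue
        if kappa == 0.0:
            angles[mask] = rng.uniform(0.0, 2.0 * math.pi, size=m)
        else:
            angles[mask] = rng.vonmises(mu, kappa, size=m)
    return np.asarray(radians_to_hours(angles))


def simulate_dataset(config: ScenarioConfig) -> SimulatedDataset:
    """Simulate one detection dataset under ``config``.

    Exactly ``round(fp_rate · N)`` records are false positives drawn from the
    false-positive shape; the remainder are true detections drawn from the
    activity shape. Records are shuffled, then the verified subset is selected
    at random without replacement.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_detections
    n_false = int(round(config.fp_rate * n))
    n_true = n - n_false

    times = np.empty(n)
    is_true = np.zeros(n, dtype=bool)
    if n_true > 0:
        times[:n_true] = sample_times(config.true_shape, n_true, rng)
        is_true[:n_true] = True
    if n_false > 0:
        times[n_true:] = sample_times(config.fp_shape, n_false, rng)

    order = rng.permutation(n)
    times, is_true = times[order], is_true[order]
    bins = np.asarray(assign_bin(times, config.grid))

    dataset = SimulatedDataset(
        times=times,
        bins=bins,
        is_true=is_true,
        verified=np.zeros(n, dtype=bool),
        config=config,
    )
    return apply_verification(dataset, config.verification_fraction, rng)


def apply_verification(
    dataset: SimulatedDataset, fraction: float, rng: np.random.Generator
) -> SimulatedDataset:
    """Mark a random ``round(fraction · N)`` subset of records as human-verified.

    Verified records expose their ground-truth flag as the observed label; all
    other records become unverified. Returns a new dataset.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = dataset.n_records
    n_verified = int(round(fraction * n))
    verified = np.zeros(n, dtype=bool)
    if n_verified > 0:
        idx = rng.choice(n, size=n_verified, replace=False)
        verified[idx] = True
    return replace(dataset, verified=verified)
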