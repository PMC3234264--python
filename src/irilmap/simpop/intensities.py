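"""Simulate two-channel intensity clusters for each marker pattern type."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..clusterqc.patterns import IntensitySet, PatternType


@dataclass
class IntensityParams:
    """Cluster geometry knobs for :func:`simulate_intensities`."""

    theta_sd: float = 0.03
    intensity_mean: float = 1.0
    intensity_sd: float = 0.12
    intensity_floor: float = 0.25
    #: fraction of low-intensity (uncallable) samples for TYPE2
    low_fraction: float = 0.08
    #: how far TYPE3 extreme clusters sit away from 0 / 1
    shift: float = 0.2
    weights3: tuple[float, float, float] = (0.35, 0.30, 0.35)
    weights5: tuple[float, ...] = (0.22, 0.18, 0.20, 0.18, 0.22)

    means3: tuple[float, float, float] = (0.04, 0.50, 0.96)
    means5: tuple[float, ...] = (0.04, 0.27, 0.50, 0.73, 0.96)


def simulate_intensities(
    pattern: PatternType,
    n_samples: int,
    params: IntensityParams | None = None,
    seed: int | None = None,
) -> tuple[IntensitySet, np.ndarray]:
    """Draw (theta, intensity) points for one marker of the given pattern.

    Returns the point set and the true cluster label per point (index into
    the pattern's mean vector; label ``-1`` marks TYPE2 low-intensity
    dropouts).
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10 for a fittable marker")
    params = params or IntensityParams()
    rng = np.random.default_rng(seed)

    if pattern in (PatternType.TYPE1, PatternType.TYPE2):
        means = np.asarray(params.means3)
        weights = np.asarray(params.weights3)
    elif pattern is PatternType.TYPE3:
        s = params.shift
        means = np.asarray((s, 0.5 + s / 2.0, 1.0 - s / 2.5))
        weights = np.asarray(params.weights3)
    elif pattern is PatternType.TYPE4:
        means = np.asarray(params.means5)
        weights = np.asarray(params.weights5)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown pattern {pattern!r}")
    weights = weights / weights.sum()

    labels = rng.choice(means.size, size=n_samples, p=weights)
    theta = means[labels] + rng.normal(0.0, params.theta_sd, size=n_samples)
    intensity = np.abs(rng.normal(params.intensity_mean, params.intensity_sd,
                                  size=n_samples))
    intensity = np.maximum(intensity, params.intensity_floor * 1.2)

    if pattern is PatternType.TYPE2:
        n_low = max(int(round(params.low_fraction * n_samples)), 3)
        low = rng.choice(n_samples, size=n_low, replace=False)
        intensity[low] = rng.uniform(0.0, params.intensity_floor * 0.6, size=n_low)
        theta[low] = rng.uniform(0.0, 1.0, size=n_low)
        labels = labels.copy()
        labels[low] = -1

    theta = np.clip(theta, 0.0, 1.0)
    return IntensitySet(theta=theta, intensity=intensity), labels
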