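"""Intensity-cluster pattern classification and genotype calling.

Markers on a two-channel array produce clusters in normalized theta
(angle in [0, 1]) vs intensity space.  Four recurring patterns:

* TYPE1 - three compact clusters near theta 0 / 0.5 / 1; all samples callable.
* TYPE2 - like TYPE1 plus a fraction of low-intensity samples that must be
  failed.
* TYPE3 - three clusters whose extreme theta means are shifted away from
  0 / 1 (duplicated-locus signature); callable after shift correction
  unless the clusters are too close together.
* TYPE4 - five clusters (two loci scored at once); never callable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from ..core import FAILED


class PatternType(enum.Enum):
    TYPE1 = 1
    TYPE2 = 2
    TYPE3 = 3
    TYPE4 = 4


@dataclass
class IntensitySet:
    """Per-sample (theta, intensity) points for one marker."""

    theta: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.theta.shape != self.intensity.shape:
            raise ValueError("theta and intensity must have the same shape")
        if ((self.theta < 0) | (self.theta > 1)).any():
            raise ValueError("theta values must lie in [0, 1]")
        if (self.intensity < 0).any():
            raise ValueError("intensity must be non-negative")

    @property
    def n(self) -> int:
        return int(self.theta.size)


@dataclass
class ClusterModel:
    """Fitted 1-D theta mixture plus the intensity floor used for calling."""

    means: np.ndarray          # ascending
    sds: np.ndarray
    weights: np.ndarray        # sum to 1
    intensity_floor: float
    pattern: PatternType
    unscorable: bool = False   # TYPE3 with clusters too close to separate

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if (np.diff(self.means) < 0).any():
            raise ValueError("component means must be sorted ascending")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("component weights must sum to 1")

    @property
    def n_components(self) -> int:
        return int(self.means.size)


class UnclassifiablePatternError(ValueError):
    """Raised when the fitted component count matches none of the patterns."""

    def __init__(self, n_components: int, message: str):
        super().__init__(message)
        self.n_components = n_components


def _default_floor(intensity: np.ndarray) -> float:
    return 0.3 * float(np.median(intensity))


def classify_pattern(
    points: IntensitySet,
    *,
    intensity_floor: float | None = None,
    shift_tol: float = 0.12,
    low_threshold: float = 0.02,
    min_separation: float = 0.08,
    max_components: int = 6,
    random_state: int = 0,
) -> tuple[PatternType, ClusterModel]:
    """Classify a marker's cluster pattern and return the fitted model.

    A 1-D Gaussian mixture is fitted on theta (points below the intensity
    floor excluded) for k = 1..``max_components``; k is selected by BIC.
    Three components with extreme means within ``shift_tol`` of 0 and 1
    give TYPE1, or TYPE2 when more than ``low_threshold`` of the samples
    sit below the intensity floor; three shifted components give TYPE3;
    five components give TYPE4.  Any other component count raises
    :class:`UnclassifiablePatternError`.
    """
    if points.n < 30:
        raise ValueError(f"need >= 30 points to classify, got {points.n}")
    floor = _default_floor(points.intensity) if intensity_floor is None else intensity_floor

    ok = points.intensity >= floor
    theta = points.theta[ok]
    if theta.size < 30:
        raise ValueError("fewer than 30 points above the intensity floor")
    if float(np.std(theta)) < 1e-6:
        raise UnclassifiablePatternError(
            1, "degenerate theta variance: single compact cluster, "
               "not callable as a 3-cluster marker")

    x = theta[:, None]
    fits = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             random_state=random_state, n_init=2,
                             reg_covar=1e-5)
        gm.fit(x)
        fits[k] = (gm.bic(x), gm)
    # parsimony: smallest k within a BIC tolerance of the optimum, so a
    # spurious extra component does not flip the pattern call
    best_bic = min(b for b, _ in fits.values())
    best_k = min(k for k, (b, _) in fits.items() if b <= best_bic + 10.0)
    best_gm = fits[best_k][1]

    order = np.argsort(best_gm.means_[:, 0])
    means = best_gm.means_[order, 0]
    sds = np.sqrt(best_gm.covariances_[order, 0])
    weights = best_gm.weights_[order]

    low_fraction = float(np.mean(~ok))

    if best_k == 3:
        shifted = (means[0] > shift_tol) or (means[-1] < 1.0 - shift_tol)
        if shifted:
            pattern = PatternType.TYPE3
        elif low_fraction > low_threshold:
            pattern = PatternType.TYPE2
        else:
            pattern = PatternType.TYPE1
        unscorable = (pattern is PatternType.TYPE3
                      and bool((np.diff(means) < min_separation).any()))
    elif best_k == 5:
        pattern = PatternType.TYPE4
        unscorable = True
    else:
        raise UnclassifiablePatternError(
            best_k,
            f"{best_k} mixture component(s) match none of the four patterns; "
            "marker not callable")

    model = ClusterModel(means=means, sds=sds, weights=weights,
                         intensity_floor=floor, pattern=pattern,
                         unscorable=unscorable)
    return pattern, model


def call_genotypes(
    model: ClusterModel,
    points: IntensitySet,
    *,
    region_sd: float = 3.0,
) -> np.ndarray:
    """Call AA/AB/BB per point from a fitted 3-component model.

    Points below the intensity floor, or outside every component's calling
    region (``region_sd`` standard deviations around its mean), are FAILED.
    TYPE3 models are called against their fitted (shifted) means, which is
    equivalent to shifting the clusters back before calling.  TYPE4 models
    are rejected outright, and unscorable TYPE3 markers fail every sample.
    """
    if model.pattern is PatternType.TYPE4:
        raise ValueError("TYPE4 markers cannot be genotype-called; "
                         "they are deleted from the data set")
    if model.n_components != 3:
        raise ValueError("calling requires a 3-component model")
    calls = np.full(points.n, FAILED, dtype=np.int8)
    if model.unscorable:
        return calls

    z = np.abs(points.theta[:, None] - model.means[None, :]) / model.sds[None, :]
    comp = np.argmin(z, axis=1)
    in_region = z[np.arange(points.n), comp] <= region_sd
    ok = in_region & (points.intensity >= model.intensity_floor)
    calls[ok] = comp[ok].astype(np.int8)  # component 0/1/2 -> AA/AB/BB codes
    return calls
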