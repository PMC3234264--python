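"""Dataset-level quality-control statistics."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ..core import AA, AB, BB, FAILED, GenotypeMatrix


def marker_failure_rates(
    matrix: GenotypeMatrix, threshold: float = 0.05
) -> tuple[pd.Series, dict]:
    """Per-marker FAILED fraction plus a summary.

    The summary reports the mean rate and the number of markers whose rate
    strictly exceeds ``threshold``.
    """
    if matrix.n_markers == 0 or matrix.n_samples == 0:
        raise ValueError("empty genotype matrix")
    rates = (matrix.calls == FAILED).mean(axis=1)
    series = pd.Series(rates, index=matrix.markers, name="failure_rate")
    summary = {
        "mean_failure_rate": float(rates.mean()),
        "threshold": threshold,
        "n_above_threshold": int((rates > threshold).sum()),
        "n_markers": matrix.n_markers,
        "n_samples": matrix.n_samples,
    }
    return series, summary


def group_call_rates(
    matrix: GenotypeMatrix, groups: Mapping[str, str]
) -> pd.Series:
    """Mean call rate (1 - failure fraction over cells) per sample group."""
    unknown = set(groups) - set(matrix.samples)
    if unknown:
        raise ValueError(f"grouping references unknown samples: {sorted(unknown)[:5]}")
    missing = set(matrix.samples) - set(groups)
    if missing:
        raise ValueError(f"samples without a group: {sorted(missing)[:5]}")
    called = matrix.calls != FAILED
    labels = np.asarray([groups[s] for s in matrix.samples], dtype=object)
    out = {}
    for g in sorted(set(labels)):
        cols = labels == g
        out[g] = float(called[:, cols].mean())
    return pd.Series(out, name="call_rate")


def triplet_consistency(
    p1: np.ndarray, p2: np.ndarray, f1: np.ndarray
) -> tuple[int, float]:
    """Count Mendelian inconsistencies in a parent/parent/F1 triplet.

    Only markers where all three calls are non-FAILED and both parents are
    homozygous are informative; the F1 is consistent iff it equals the
    shared parental genotype (identical parents) or is heterozygous
    (different parents).  Returns (count, rate over informative markers).
    """
    p1 = np.asarray(p1, dtype=np.int8)
    p2 = np.asarray(p2, dtype=np.int8)
    f1 = np.asarray(f1, dtype=np.int8)
    if not (p1.shape == p2.shape == f1.shape):
        raise ValueError("triplet vectors differ in length")
    informative = (p1 != FAILED) & (p2 != FAILED) & (f1 != FAILED) \
        & (p1 != AB) & (p2 != AB)
    expected = np.where(p1 == p2, p1, AB)
    bad = informative & (f1 != expected)
    n_inf = int(informative.sum())
    return int(bad.sum()), (float(bad.sum() / n_inf) if n_inf else 0.0)


def duplicate_concordance(v1: np.ndarray, v2: np.ndarray) -> tuple[int, int, float]:
    """Discordance between duplicate samples over jointly called markers.

    Returns (n_discordant, n_joint_called, discordance_rate).
    """
    v1 = np.asarray(v1, dtype=np.int8)
    v2 = np.asarray(v2, dtype=np.int8)
    if v1.shape != v2.shape:
        raise ValueError("duplicate vectors differ in length")
    joint = (v1 != FAILED) & (v2 != FAILED)
    n_joint = int(joint.sum())
    n_bad = int((joint & (v1 != v2)).sum())
    return n_bad, n_joint, (n_bad / n_joint if n_joint else 0.0)


def distortion_scan(
    matrix: GenotypeMatrix,
    parent1: np.ndarray,
    parent2: np.ndarray,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Segregation-distortion scan against the Mendelian 0.5 expectation.

    For each marker with homozygous, polymorphic parents, the frequency of
    the parent-1 allele among non-FAILED homozygous progeny calls is
    computed and flagged when it falls outside the two-sided exact
    binomial acceptance interval (each tail ``alpha / 2``) around 0.5.
    Markers with zero informative calls get frequency NaN and no flag.
    """
    p1 = np.asarray(parent1, dtype=np.int8)
    p2 = np.asarray(parent2, dtype=np.int8)
    if p1.shape != (matrix.n_markers,) or p2.shape != (matrix.n_markers,):
        raise ValueError("parent vectors must have one call per marker")
    informative_marker = (p1 != FAILED) & (p2 != FAILED) \
        & (p1 != AB) & (p2 != AB) & (p1 != p2)

    hom1 = matrix.calls == p1[:, None]
    hom2 = matrix.calls == p2[:, None]
    n1 = hom1.sum(axis=1)
    n = (hom1 | hom2).sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, n1 / np.maximum(n, 1), np.nan)
    freq = np.where(informative_marker, freq, np.nan)

    flag = np.zeros(matrix.n_markers, dtype=bool)
    ok = informative_marker & (n > 0)
    if ok.any():
        x = n1[ok]
        nn = n[ok]
        lower = stats.binom.cdf(x, nn, 0.5)
        upper = stats.binom.sf(x - 1, nn, 0.5)
        flag[ok] = (lower < alpha / 2) | (upper < alpha / 2)

    return pd.DataFrame({
        "marker": matrix.markers,
        "n_informative": n,
        "freq_parent1": freq,
        "distorted": flag,
    })
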