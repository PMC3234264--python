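"""Two-point recombinant-fraction estimation and linkage grouping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

_MIN_INFORMATIVE = 10


@dataclass
class TwoPointEstimate:
    """Observed line-level recombinant fraction between two markers."""

    R_hat: float
    n_informative: int
    n_recombinant: int
    lod: float
    reliable: bool


def _lod(d: np.ndarray, n: np.ndarray) -> np.ndarray:
    """log10 binomial likelihood ratio of R_hat vs independence (0.5)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.clip(d / np.maximum(n, 1), 1e-12, 0.5)
        ll = d * np.log10(p) + (n - d) * np.log10(1.0 - p) - n * np.log10(0.5)
    return np.where(n > 0, np.maximum(ll, 0.0), 0.0)


def estimate_R(x1: np.ndarray, x2: np.ndarray) -> TwoPointEstimate:
    """Two-point estimate from two origin-coded vectors (0/1/-1)."""
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    if x1.shape != x2.shape:
        raise ValueError("genotype vectors differ in length")
    joint = (x1 != -1) & (x2 != -1)
    n = int(joint.sum())
    d = int((x1[joint] != x2[joint]).sum())
    r_hat = min(d / n, 0.5) if n else np.nan
    lod = float(_lod(np.asarray(d, float), np.asarray(n, float))) if n else 0.0
    return TwoPointEstimate(R_hat=r_hat, n_informative=n, n_recombinant=d,
                            lod=lod, reliable=n >= _MIN_INFORMATIVE)


def two_point_tables(origins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs informative counts N and discordant counts D.

    ``origins``: (n_markers, n_lines) in {0, 1, -1}.  Computed by matrix
    products, so it scales to thousands of markers.
    """
    A = (origins == 0).astype(np.float64)
    B = (origins == 1).astype(np.float64)
    V = A + B
    N = V @ V.T
    D = A @ B.T + B @ A.T
    return N, D


def pairwise_R(origins: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(R_hat, N, LOD) matrices for all marker pairs."""
    N, D = two_point_tables(origins)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(N > 0, np.minimum(D / np.maximum(N, 1), 0.5), np.nan)
    lod = _lod(D, N)
    return R, N, lod


def group_markers(
    origins: np.ndarray,
    marker_ids: np.ndarray,
    lod_threshold: float = 6.0,
    r_threshold: float = 0.4,
) -> list[np.ndarray]:
    """Single-linkage grouping under (LOD >= threshold AND R <= threshold).

    Returns marker-index arrays, numbered by decreasing size then by the
    lowest member marker id (deterministic).
    """
    R, N, lod = pairwise_R(origins)
    adj = (lod >= lod_threshold) & (R <= r_threshold) & (N >= _MIN_INFORMATIVE)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [np.flatnonzero(labels == c) for c in range(n_comp)]
    groups.sort(key=lambda idx: (-idx.size, str(min(marker_ids[idx], key=str))))
    return groups
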