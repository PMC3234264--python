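"""Recombination landscape: monotone smoothing of genetic-vs-physical
positions and its derivative (cM / Mbp) on a uniform physical grid."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from ..core import LinkageMap, PhysicalPlacement

MBP = 1_000_000.0


def _smooth_monotone(bp: np.ndarray, cm: np.ndarray, grid: np.ndarray,
                     bandwidth: float) -> np.ndarray:
    """Gaussian-kernel local *linear* regression (boundary-bias free for
    linear trends) followed by isotonic correction."""
    dx = grid[:, None] - bp[None, :]
    w = np.exp(-0.5 * (dx / bandwidth) ** 2)
    sw = w.sum(axis=1)
    sx = (w * dx).sum(axis=1)
    sxx = (w * dx * dx).sum(axis=1)
    sy = w @ cm
    sxy = (w * dx) @ cm
    denom = sw * sxx - sx * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(np.abs(denom) > 1e-12,
                       (sxx * sy - sx * sxy) / denom,
                       sy / np.maximum(sw, 1e-300))
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    return iso.fit_transform(grid, est)


def landscape(
    lmap: LinkageMap,
    placement: PhysicalPlacement,
    bandwidth_bp: float = 10_000_000.0,
    *,
    n_grid: int = 200,
    min_markers: int = 20,
    outlier_tol_cm: float = 10.0,
) -> dict[str, pd.DataFrame]:
    """Per-chromosome smoothed Marey curve and local recombination rate.

    Markers whose genetic chromosome matches their physical chromosome
    feed a monotone smooth of (bp, cM); the local rate is its derivative
    on a uniform bp grid.  Outliers further than ``outlier_tol_cm`` from
    an initial isotonic fit are excluded before smoothing.
    """
    chrom_of = placement.chrom_of()
    bp_of = placement.bp_of()
    out: dict[str, pd.DataFrame] = {}
    for chrom, df in lmap.chromosomes.items():
        sub = df.assign(
            phys_chrom=df["marker"].map(chrom_of),
            phys_bp=df["marker"].map(bp_of))
        sub = sub[sub["phys_chrom"].astype(str) == str(chrom)].dropna(subset=["phys_bp"])
        if len(sub) < min_markers:
            raise ValueError(
                f"chromosome {chrom}: only {len(sub)} concordant markers, "
                f"need >= {min_markers}")
        sub = sub.sort_values("phys_bp")
        bp = sub["phys_bp"].to_numpy(dtype=float)
        cm = sub["cm"].to_numpy(dtype=float)
        # orient the genetic axis along the physical one
        if np.corrcoef(bp, cm)[0, 1] < 0:
            cm = cm.max() - cm

        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        fit0 = iso.fit_transform(bp, cm)
        keep = np.abs(cm - fit0) <= outlier_tol_cm
        if keep.sum() >= min_markers:
            bp, cm = bp[keep], cm[keep]

        grid = np.linspace(bp.min(), bp.max(), n_grid)
        cm_smooth = _smooth_monotone(bp, cm, grid, bandwidth_bp)
        rate = np.gradient(cm_smooth, grid / MBP)
        rate = np.maximum(rate, 0.0)
        out[str(chrom)] = pd.DataFrame({
            "bp": grid,
            "cm_smoothed": cm_smooth,
            "rate_cm_per_mbp": rate,
        })
    return out
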