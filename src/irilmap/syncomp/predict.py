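"""Homothetic prediction of physical positions from genetic positions."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import LinkageMap, PhysicalPlacement


def _anchors(lmap: LinkageMap, placement: PhysicalPlacement,
             chrom: str) -> pd.DataFrame:
    """Concordant framework markers: the (cM, bp) interpolation anchors."""
    fw = lmap.framework(chrom)
    chrom_of = placement.chrom_of()
    bp_of = placement.bp_of()
    fw = fw.assign(
        phys_chrom=fw["marker"].map(chrom_of),
        phys_bp=fw["marker"].map(bp_of))
    fw = fw[fw["phys_chrom"].astype(str) == str(chrom)].dropna(subset=["phys_bp"])
    return fw.sort_values("cm").reset_index(drop=True)


def predict_physical(
    markers: list[str],
    lmap: LinkageMap,
    placement: PhysicalPlacement,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Predict (chromosome, bp) for genetically mapped markers.

    The chromosome is the genetic one; bp comes from linear interpolation
    of the marker's cM between the nearest flanking concordant framework
    anchors, with linear extrapolation (clamped to the chromosome span)
    beyond the terminal anchors.  Markers on chromosomes without anchors
    are reported unpredictable.
    """
    frame = lmap.to_frame().set_index("marker")
    rows = []
    anchor_cache: dict[str, pd.DataFrame] = {}
    for marker in markers:
        if marker not in frame.index:
            rows.append((marker, None, np.nan, "not genetically mapped"))
            continue
        chrom = str(frame.loc[marker, "chrom"])
        cm = float(frame.loc[marker, "cm"])
        if chrom not in anchor_cache:
            anchor_cache[chrom] = _anchors(lmap, placement, chrom)
        anch = anchor_cache[chrom]
        anch = anch[anch["marker"] != marker]
        if len(anch) < 2:
            rows.append((marker, None, np.nan, "no concordant anchors"))
            continue
        a_cm = anch["cm"].to_numpy(dtype=float)
        a_bp = anch["phys_bp"].to_numpy(dtype=float)
        # orientation: the genetic axis may run against the physical one
        if np.corrcoef(a_cm, a_bp)[0, 1] < 0:
            cmax = a_cm.max()
            a_cm = cmax - a_cm
            cm = cmax - cm
            order = np.argsort(a_cm)
            a_cm, a_bp = a_cm[order], a_bp[order]
        exact = np.flatnonzero(np.isclose(a_cm, cm))
        if exact.size:
            bp = float(a_bp[exact[0]])
        elif cm <= a_cm[0]:
            slope = (a_bp[1] - a_bp[0]) / max(a_cm[1] - a_cm[0], 1e-9)
            bp = a_bp[0] + slope * (cm - a_cm[0])
        elif cm >= a_cm[-1]:
            slope = (a_bp[-1] - a_bp[-2]) / max(a_cm[-1] - a_cm[-2], 1e-9)
            bp = a_bp[-1] + slope * (cm - a_cm[-1])
        else:
            bp = float(np.interp(cm, a_cm, a_bp))
        hi = (chrom_sizes or {}).get(chrom)
        if hi is None:
            sub = placement.for_chrom(chrom)
            hi = int(sub["bp"].max()) if len(sub) else None
        bp = max(bp, 1.0)
        if hi is not None:
            bp = min(bp, float(hi))
        rows.append((marker, chrom, float(bp), None))
    return pd.DataFrame(rows, columns=["marker", "pred_chrom", "pred_bp", "note"])
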