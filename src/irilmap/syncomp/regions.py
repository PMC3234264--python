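"""Calling of major non-colinear regions from framework maps.

Within a chromosome shared by the genetic map and the assembly, each
framework marker's physical rank is compared with its genetic rank
(after orienting the genetic map along the physical one).  A marker is
discrepant when the ranks differ by more than ``rank_tol`` positions or
its position differs by more than ``bp_tol`` from the marker that holds
its genetic rank in physical order.  A region is a maximal physical run
of at least two discrepant framework markers; a single discrepant marker
is promoted only when its span overlaps a region called in the other
population.  Names follow ``<chrom>.<index><suffix>`` with the index
assigned by ascending physical start.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ..core import LinkageMap, PhysicalPlacement

REGION_COLUMNS = ["name", "chrom", "start_bp", "end_bp", "n_markers",
                  "markers", "population", "supported_by_other"]


def _chromosome_frame(
    lmap: LinkageMap, placement: PhysicalPlacement, chrom: str
) -> pd.DataFrame:
    fw = lmap.framework(chrom)
    chrom_of = placement.chrom_of()
    bp_of = placement.bp_of()
    fw = fw.assign(
        phys_chrom=fw["marker"].map(chrom_of),
        phys_bp=fw["marker"].map(bp_of),
    )
    fw = fw[fw["phys_chrom"].astype(str) == str(chrom)]
    return fw.dropna(subset=["phys_bp"]).reset_index(drop=True)


def _discrepant_markers(fw: pd.DataFrame, rank_tol: int, bp_tol: float) -> pd.DataFrame:
    """Flag displaced framework markers; returns rows sorted by bp."""
    df = fw.sort_values("phys_bp").reset_index(drop=True)
    df["phys_rank"] = np.arange(len(df))
    gen_rank = df["cm"].rank(method="first").to_numpy() - 1
    rho = spearmanr(df["phys_rank"], gen_rank).statistic if len(df) > 2 else 1.0
    if rho is not None and rho < 0:
        gen_rank = (len(df) - 1) - gen_rank
    df["gen_rank"] = gen_rank.astype(int)
    bp_sorted = df["phys_bp"].to_numpy(dtype=float)
    expected_bp = bp_sorted[np.clip(df["gen_rank"].to_numpy(), 0, len(df) - 1)]
    rank_off = np.abs(df["phys_rank"] - df["gen_rank"])
    bp_off = np.abs(df["phys_bp"].to_numpy(dtype=float) - expected_bp)
    # the bp rule needs rank_off >= 2: a one-rank shift spans ordinary
    # inter-marker spacing, which can exceed bp_tol in sparse regions
    df["discrepant"] = (rank_off > rank_tol) | ((rank_off >= 2) & (bp_off > bp_tol))
    return df


def call_regions(
    lmap: LinkageMap,
    placement: PhysicalPlacement,
    other_regions: pd.DataFrame | None = None,
    *,
    population_suffix: str = "I",
    rank_tol: int = 2,
    bp_tol: float = 5_000_000.0,
    bridge: int = 2,
    complete_map: LinkageMap | None = None,
) -> pd.DataFrame:
    """Call named non-colinear regions for one population's framework map.

    Runs of discrepant markers separated by at most ``bridge`` colinear
    markers are merged: the centre of an inverted run is itself barely
    displaced, so without bridging an inversion would split in two.
    """
    rows = []
    for chrom in sorted(lmap.chromosomes, key=str):
        fw = _chromosome_frame(lmap, placement, chrom)
        if len(fw) < 3:
            continue
        df = _discrepant_markers(fw, rank_tol, bp_tol)
        flags = df["discrepant"].to_numpy()
        # maximal runs of discrepant markers in physical order
        runs = []
        start = None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            elif not f and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(flags) - 1))
        merged = []
        for a, b in runs:
            if merged and a - merged[-1][1] - 1 <= bridge:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        for a, b in merged:
            members = df.iloc[a:b + 1]
            span = (int(members["phys_bp"].min()), int(members["phys_bp"].max()))
            if len(members) == 1:
                if other_regions is None or other_regions.empty:
                    continue
                other = other_regions[other_regions["chrom"].astype(str) == str(chrom)]
                pad = bp_tol
                overlap = ((other["start_bp"] - pad <= span[1])
                           & (other["end_bp"] + pad >= span[0]))
                if not overlap.any():
                    continue
            rows.append({
                "chrom": str(chrom),
                "start_bp": span[0],
                "end_bp": span[1],
                "n_markers": len(members),
                "markers": list(members["marker"]),
                "population": population_suffix,
            })

    regions = pd.DataFrame(rows, columns=[c for c in REGION_COLUMNS
                                          if c not in ("name", "supported_by_other")])
    if regions.empty:
        return pd.DataFrame(columns=REGION_COLUMNS)
    regions = regions.sort_values(["chrom", "start_bp"]).reset_index(drop=True)
    names = []
    for chrom, sub in regions.groupby("chrom", sort=False):
        for i in range(len(sub)):
            names.append(f"{chrom}.{i + 1}{population_suffix}")
    regions.insert(0, "name", names)

    if other_regions is not None and not other_regions.empty:
        supported = []
        for row in regions.itertuples(index=False):
            other = other_regions[other_regions["chrom"].astype(str) == str(row.chrom)]
            supported.append(bool(((other["start_bp"] <= row.end_bp)
                                   & (other["end_bp"] >= row.start_bp)).any()))
        regions["supported_by_other"] = supported
    else:
        regions["supported_by_other"] = False

    if complete_map is not None:
        regions["n_markers_complete"] = [
            _complete_members(complete_map, placement, row)
            for row in regions.itertuples(index=False)
        ]
    return regions


def _complete_members(complete_map: LinkageMap, placement: PhysicalPlacement,
                      row) -> int:
    """Markers of the complete map falling inside a region's physical span."""
    if row.chrom not in complete_map.chromosomes:
        return 0
    df = complete_map.chromosomes[row.chrom]
    bp = df["marker"].map(placement.bp_of())
    inside = bp.between(row.start_bp, row.end_bp)
    return int(inside.sum())
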