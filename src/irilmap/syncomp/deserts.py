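"""Polymorphism deserts: physical spans empty of one population's
polymorphic markers but well covered by the other's."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import PhysicalPlacement

MBP = 1_000_000.0


def deserts(
    placement: PhysicalPlacement,
    polymorphic: dict[str, set[str]],
    min_span_mbp: float = 10.0,
    min_other: int = 5,
) -> pd.DataFrame:
    """Maximal spans >= ``min_span_mbp`` with zero polymorphic markers in
    one population and at least ``min_other`` in the other.

    ``polymorphic`` maps population name -> set of polymorphic marker ids.
    """
    pops = sorted(polymorphic)
    if len(pops) != 2:
        raise ValueError("deserts requires exactly two populations")
    min_span = min_span_mbp * MBP
    placed = placement.placed
    rows = []
    for empty_pop in pops:
        other_pop = pops[0] if empty_pop == pops[1] else pops[1]
        for chrom in sorted(placed["chrom"].unique(), key=str):
            sub = placed[placed["chrom"] == chrom]
            lo, hi = int(sub["bp"].min()), int(sub["bp"].max())
            own = np.sort(sub.loc[sub["marker"].isin(polymorphic[empty_pop]),
                                  "bp"].to_numpy(dtype=float))
            other = np.sort(sub.loc[sub["marker"].isin(polymorphic[other_pop]),
                                    "bp"].to_numpy(dtype=float))
            edges = np.concatenate([[lo], own, [hi]])
            for a, b in zip(edges, edges[1:]):
                if b - a < min_span:
                    continue
                n_other = int(((other > a) & (other < b)).sum())
                if n_other >= min_other:
                    rows.append({
                        "chrom": str(chrom),
                        "start_bp": int(a),
                        "end_bp": int(b),
                        "span_mbp": (b - a) / MBP,
                        "empty_population": empty_pop,
                        "n_markers_empty_pop": 0,
                        "n_markers_other_pop": n_other,
                    })
    return pd.DataFrame(rows, columns=[
        "chrom", "start_bp", "end_bp", "span_mbp", "empty_population",
        "n_markers_empty_pop", "n_markers_other_pop"])
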