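"""Plant known corruptions (inversions, translocations, deletions) into a
physical placement so downstream comparisons have a ground truth."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ..core import PhysicalPlacement
from .genome import AssemblyEdit, Deletion, Inversion, Translocation, TruthSet


def _span_edits(edits: Sequence[AssemblyEdit]):
    return [e for e in edits if isinstance(e, (Inversion, Translocation))]


def _check_overlaps(edits: Sequence[AssemblyEdit]) -> None:
    spans = [(e.chrom, e.start_bp, e.end_bp) for e in _span_edits(edits)]
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            ci, si, ei = spans[i]
            cj, sj, ej = spans[j]
            if ci == cj and si <= ej and sj <= ei:
                raise ValueError(f"overlapping edits on chromosome {ci}: "
                                 f"[{si}, {ei}] and [{sj}, {ej}]")


def plant_misassembly(
    placement: PhysicalPlacement,
    edits: Sequence[AssemblyEdit],
    seed: int | None = None,
) -> tuple[PhysicalPlacement, TruthSet]:
    """Apply edits to a copy of ``placement``; return it with an edit log.

    Inversions reverse the bp order of the markers inside the span;
    translocations move the span's markers to another chromosome keeping
    their internal order; deletions drop markers from the table entirely
    (emulating sequence absent from the assembly).  Overlapping span edits
    are rejected.  ``seed`` is accepted for interface symmetry; the
    operation itself is deterministic.
    """
    _check_overlaps(edits)
    df = placement.df.copy()
    truth = TruthSet()

    for edit in edits:
        if isinstance(edit, Inversion):
            in_span = (df["chrom"] == edit.chrom) & df["bp"].between(
                edit.start_bp, edit.end_bp)
            idx = df.index[in_span]
            if len(idx) == 0:
                raise ValueError(f"inversion span contains no markers: {edit}")
            bp = df.loc[idx, "bp"].to_numpy()
            df.loc[idx, "bp"] = edit.start_bp + edit.end_bp - bp
            truth.edits.append({
                "kind": "inversion", "chrom": edit.chrom,
                "start_bp": int(edit.start_bp), "end_bp": int(edit.end_bp),
                "markers": df.loc[idx, "marker"].tolist(),
            })
        elif isinstance(edit, Translocation):
            in_span = (df["chrom"] == edit.chrom) & df["bp"].between(
                edit.start_bp, edit.end_bp)
            idx = df.index[in_span]
            if len(idx) == 0:
                raise ValueError(f"translocation span contains no markers: {edit}")
            bp = df.loc[idx, "bp"].to_numpy()
            df.loc[idx, "chrom"] = edit.dest_chrom
            df.loc[idx, "bp"] = edit.dest_bp + (bp - edit.start_bp)
            truth.edits.append({
                "kind": "translocation", "chrom": edit.chrom,
                "start_bp": int(edit.start_bp), "end_bp": int(edit.end_bp),
                "dest_chrom": edit.dest_chrom, "dest_bp": int(edit.dest_bp),
                "markers": df.loc[idx, "marker"].tolist(),
            })
        elif isinstance(edit, Deletion):
            missing = set(edit.markers) - set(df["marker"])
            if missing:
                raise ValueError(f"deletion references unknown markers: {sorted(missing)}")
            df = df[~df["marker"].isin(edit.markers)].reset_index(drop=True)
            truth.deleted_markers.extend(edit.markers)
            truth.edits.append({"kind": "deletion", "markers": list(edit.markers)})
        else:
            raise TypeError(f"unknown edit type {type(edit).__name__}")

    # re-check the result is a valid placement (bp may collide after edits)
    dup = df.duplicated(subset=["chrom", "bp"]) & df["chrom"].notna()
    if dup.any():
        raise ValueError("edit produced colliding bp coordinates; adjust spans")
    return PhysicalPlacement(df), truth


def placement_from_truth(truth_bp: dict[str, np.ndarray],
                         truth_order: dict[str, list[str]]) -> PhysicalPlacement:
    """Build the uncorrupted placement table from simulator truth."""
    rows = []
    for chrom, ids in truth_order.items():
        for m, bp in zip(ids, truth_bp[chrom]):
            rows.append((m, chrom, int(bp)))
    df = pd.DataFrame(rows, columns=["marker", "chrom", "bp"])
    df["bp"] = df["bp"].astype("Int64")
    return PhysicalPlacement(df)
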