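"""Placement-table CSV dialect: ``marker,chrom,bp`` with an empty chrom
(or the token ``unplaced``) for markers absent from the assembly."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..core import UNPLACED, PhysicalPlacement


class PlacementTableError(ValueError):
    pass


def read_placement(path: str | Path) -> PhysicalPlacement:
    df = pd.read_csv(path, dtype={"marker": str, "chrom": str})
    missing = {"marker", "chrom", "bp"} - set(df.columns)
    if missing:
        raise PlacementTableError(f"{path}: missing columns {sorted(missing)}")
    chrom = df["chrom"].replace({UNPLACED: np.nan, "": np.nan})
    bp = pd.to_numeric(df["bp"], errors="coerce").astype("Int64")
    bad = chrom.notna() & bp.notna() & (bp < 1)
    if bad.any():
        row = df.index[bad][0] + 2
        raise PlacementTableError(f"{path}:{row}: bp must be >= 1")
    out = pd.DataFrame({"marker": df["marker"], "chrom": chrom, "bp": bp})
    try:
        return PhysicalPlacement(out)
    except ValueError as exc:
        raise PlacementTableError(f"{path}: {exc}") from exc


def write_placement(placement: PhysicalPlacement, path: str | Path) -> None:
    df = placement.df.copy()
    df["chrom"] = df["chrom"].fillna(UNPLACED)
    df["bp"] = df["bp"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False)
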