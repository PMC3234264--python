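"""Map-table CSV dialect.

One row per marker; for each population ``P`` the columns
``{P}_status`` (``frame`` / ``placed`` / ``-``), ``{P}_chrom``,
``{P}_cm`` and ``{P}_pseudo_cm``; then ``phys_chrom`` and ``phys_bp``
for the assembly placement (empty when unplaced).  Status ``-`` means
the marker is not on that population's map and must carry no genetic
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..core import (
    TIER_FRAMEWORK,
    TIER_PLACED,
    TIER_SCAFFOLD,
    LinkageMap,
    PhysicalPlacement,
)

STATUS_FRAME = "frame"
STATUS_PLACED = "placed"
STATUS_NONE = "-"
_STATUSES = {STATUS_FRAME, STATUS_PLACED, STATUS_NONE}
#: U+2212 minus, as printed in the source tables
_UNICODE_MINUS = "−"

_POP_FIELDS = ("status", "chrom", "cm", "pseudo_cm")


class MapTableError(ValueError):
    pass


@dataclass
class MapTable:
    """Validated map table: one row per marker, per-population columns."""

    df: pd.DataFrame
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if "marker" not in df.columns:
            raise MapTableError("map table needs a 'marker' column")
        if df["marker"].duplicated().any():
            dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
            raise MapTableError(f"duplicate marker {dup!r}")
        for pop in self.populations:
            for f in _POP_FIELDS:
                col = f"{pop}_{f}"
                if col not in df.columns:
                    raise MapTableError(f"missing column {col!r}")
            status = df[f"{pop}_status"].replace(_UNICODE_MINUS, STATUS_NONE)
            bad = ~status.isin(_STATUSES)
            if bad.any():
                raise MapTableError(
                    f"unknown status token {df.loc[bad, f'{pop}_status'].iloc[0]!r} "
                    f"for population {pop!r}")
            df[f"{pop}_status"] = status
            unmapped = status == STATUS_NONE
            for f in ("chrom", "cm", "pseudo_cm"):
                col = df[f"{pop}_{f}"]
                if col[unmapped].notna().any():
                    m = df.loc[unmapped & col.notna(), "marker"].iloc[0]
                    raise MapTableError(
                        f"marker {m!r}: status '-' but {pop}_{f} is set")
            for f in ("cm", "pseudo_cm"):
                vals = pd.to_numeric(df[f"{pop}_{f}"], errors="coerce")
                if ((vals < 0) & df[f"{pop}_{f}"].notna()).any():
                    raise MapTableError(f"negative {pop}_{f} coordinate")
                df[f"{pop}_{f}"] = vals
        self.df = df

    def mapped(self, pop: str) -> pd.DataFrame:
        """Rows on the population's complete map (frame or placed)."""
        sel = self.df[f"{pop}_status"].isin((STATUS_FRAME, STATUS_PLACED))
        return self.df[sel].reset_index(drop=True)

    def framework(self, pop: str) -> pd.DataFrame:
        sel = self.df[f"{pop}_status"] == STATUS_FRAME
        return self.df[sel].reset_index(drop=True)


def read_map_table(path: str | Path) -> MapTable:
    header = list(pd.read_csv(path, nrows=0).columns)
    pops = [c[: -len("_status")] for c in header if c.endswith("_status")]
    if not pops:
        raise MapTableError(f"{path}: no *_status columns found")
    dtypes = {"marker": str, "phys_chrom": str}
    for pop in pops:
        dtypes[f"{pop}_status"] = str
        dtypes[f"{pop}_chrom"] = str
    df = pd.read_csv(path, dtype={k: v for k, v in dtypes.items() if k in header})
    for pop in pops:
        df[f"{pop}_status"] = df[f"{pop}_status"].str.strip()
    if "phys_bp" in df.columns:
        df["phys_bp"] = pd.to_numeric(df["phys_bp"], errors="coerce").astype("Int64")
    return MapTable(df, tuple(pops))


def write_map_table(table: MapTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def table_to_map(table: MapTable, pop: str) -> LinkageMap:
    """Extract one population's linkage map from a map table."""
    if pop not in table.populations:
        raise MapTableError(f"population {pop!r} not in table {table.populations}")
    sub = table.mapped(pop)
    chroms: dict[str, pd.DataFrame] = {}
    for chrom, grp in sub.groupby(f"{pop}_chrom", sort=True):
        tier = np.where(grp[f"{pop}_status"] == STATUS_FRAME,
                        TIER_FRAMEWORK, TIER_PLACED)
        chroms[str(chrom)] = pd.DataFrame({
            "marker": grp["marker"].to_numpy(),
            "tier": tier,
            "cm": grp[f"{pop}_cm"].to_numpy(dtype=float),
            "pseudo_cm": grp[f"{pop}_pseudo_cm"].to_numpy(dtype=float),
            "score": np.nan,
        })
    return LinkageMap(chromosomes=chroms, population=pop)


def maps_to_table(
    maps: dict[str, LinkageMap],
    placement: PhysicalPlacement | None = None,
) -> MapTable:
    """Combine per-population linkage maps (and a placement) into one table."""
    pops = tuple(maps)
    markers: dict[str, dict] = {}
    for pop, lmap in maps.items():
        frame = lmap.to_frame()
        status = np.where(
            frame["tier"].isin((TIER_SCAFFOLD, TIER_FRAMEWORK)),
            STATUS_FRAME, STATUS_PLACED)
        for row, st in zip(frame.itertuples(index=False), status):
            rec = markers.setdefault(row.marker, {})
            rec[f"{pop}_status"] = st
            rec[f"{pop}_chrom"] = row.chrom
            rec[f"{pop}_cm"] = row.cm
            rec[f"{pop}_pseudo_cm"] = row.pseudo_cm
    if placement is not None:
        for row in placement.df.itertuples(index=False):
            rec = markers.setdefault(row.marker, {})
            rec["phys_chrom"] = row.chrom
            rec["phys_bp"] = row.bp

    rows = []
    for marker, rec in markers.items():
        row = {"marker": marker}
        for pop in pops:
            row[f"{pop}_status"] = rec.get(f"{pop}_status", STATUS_NONE)
            for f in ("chrom", "cm", "pseudo_cm"):
                row[f"{pop}_{f}"] = rec.get(f"{pop}_{f}", np.nan)
        row["phys_chrom"] = rec.get("phys_chrom", np.nan)
        row["phys_bp"] = rec.get("phys_bp", np.nan)
        rows.append(row)
    return MapTable(pd.DataFrame(rows), pops)
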