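"""Chromosome-assignment concordance between a genetic map and a
physical placement, and clustering of non-syntenic markers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import LinkageMap, PhysicalPlacement


def relabel_by_placement(lmap: LinkageMap, placement: PhysicalPlacement) -> LinkageMap:
    """Rename linkage groups to the majority physical chromosome of their
    markers (de-novo group numbers carry no assembly meaning)."""
    chrom_of = placement.chrom_of()
    renamed: dict[str, pd.DataFrame] = {}
    for group, df in lmap.chromosomes.items():
        phys = [chrom_of.get(m) for m in df["marker"]]
        phys = [c for c in phys if c is not None and not pd.isna(c)]
        if phys:
            label = pd.Series(phys).value_counts().idxmax()
        else:
            label = group
        if label in renamed:  # two groups claiming one chromosome: keep suffixes
            label = f"{label}b"
        renamed[label] = df
    return LinkageMap(chromosomes=renamed, population=lmap.population)


def concordance(
    lmap: LinkageMap, placement: PhysicalPlacement
) -> tuple[pd.DataFrame, dict]:
    """Per-marker synteny records and summary counts.

    A marker is concordant when its genetic chromosome equals its physical
    chromosome; markers absent from the assembly get no flag.
    """
    frame = lmap.to_frame()
    chrom_of = placement.chrom_of()
    bp_of = placement.bp_of()
    phys_chrom = frame["marker"].map(chrom_of)
    phys_bp = frame["marker"].map(bp_of)
    placed = phys_chrom.notna()
    concordant = pd.array(
        np.where(placed, frame["chrom"].astype(str) == phys_chrom.astype(str), None),
        dtype="boolean")
    records = pd.DataFrame({
        "marker": frame["marker"],
        "genetic_chrom": frame["chrom"].astype(str),
        "cm": frame["cm"],
        "tier": frame["tier"],
        "phys_chrom": phys_chrom,
        "phys_bp": phys_bp,
        "concordant": concordant,
    })
    counts = {
        "n_mapped": int(len(records)),
        "n_mapped_and_placed": int(placed.sum()),
        "n_unplaced": int((~placed).sum()),
        "n_discordant": int((concordant == False).sum()),  # noqa: E712
    }
    return records, counts


def cluster_nonsyntenic(
    records: pd.DataFrame, max_gap_bp: int = 5_000_000
) -> pd.DataFrame:
    """Group discordant markers into clusters and singletons.

    Markers join a cluster when they sit on the same physical chromosome
    within ``max_gap_bp`` of each other and are genetically assigned to
    the same chromosome.
    """
    disc = records[records["concordant"] == False].copy()  # noqa: E712
    if disc.empty:
        return pd.DataFrame(columns=[
            "cluster_id", "phys_chrom", "genetic_chrom", "start_bp",
            "end_bp", "n_markers", "markers", "kind"])
    disc = disc.sort_values(["phys_chrom", "genetic_chrom", "phys_bp"])
    rows = []
    cluster_id = 0
    for (pc, gc), sub in disc.groupby(["phys_chrom", "genetic_chrom"], sort=True):
        bp = sub["phys_bp"].to_numpy(dtype=float)
        breaks = np.flatnonzero(np.diff(bp) > max_gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(bp) - 1]])
        for a, b in zip(starts, ends):
            members = sub.iloc[a:b + 1]
            cluster_id += 1
            rows.append({
                "cluster_id": cluster_id,
                "phys_chrom": pc,
                "genetic_chrom": gc,
                "start_bp": int(members["phys_bp"].min()),
                "end_bp": int(members["phys_bp"].max()),
                "n_markers": len(members),
                "markers": list(members["marker"]),
                "kind": "singleton" if len(members) == 1 else "cluster",
            })
    return pd.DataFrame(rows)
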