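"""Dataset-level summary numbers recomputed from deposited tables.

Each function takes paths to machine-readable (CSV) versions of the
study's deposited tables and recomputes one printed count through the
package's own readers and QC/comparison operations.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import genio
from .clusterqc import marker_failure_rates
from .core import PhysicalPlacement
from .syncomp import concordance


def failure_rate_summary(genotype_csv: str | Path) -> dict:
    """Mean per-marker failure rate (%) and count of markers above 5%."""
    matrix = genio.read_genotypes(genotype_csv)
    _, summary = marker_failure_rates(matrix, threshold=0.05)
    return {
        "mean_failure_rate_pct": round(100.0 * summary["mean_failure_rate"], 1),
        "n_markers_above_5pct": summary["n_above_threshold"],
        "n_markers": summary["n_markers"],
        "n_samples": summary["n_samples"],
    }


def gene_coverage_summary(gene_table_csv: str | Path) -> dict:
    """Distinct genes hit by scorable SNPs and genes with 1-3 SNPs.

    Expects columns ``marker`` and ``gene`` with the literal token
    ``NULL`` (or an empty cell) for markers outside genes.
    """
    df = pd.read_csv(gene_table_csv, dtype=str)
    genes = df["gene"].replace({"NULL": None, "": None}).dropna()
    per_gene = genes.value_counts()
    return {
        "n_genes": int(per_gene.size),
        "n_genes_1_to_3_snps": int(per_gene.between(1, 3).sum()),
    }


def framework_marker_count(map_table_csv: str | Path, population: str) -> int:
    table = genio.read_map_table(map_table_csv)
    return int(len(table.framework(population)))


def complete_map_marker_count(map_table_csv: str | Path, population: str) -> int:
    table = genio.read_map_table(map_table_csv)
    return int(len(table.mapped(population)))


def _placement_from_table(table: genio.MapTable) -> PhysicalPlacement:
    df = table.df
    out = pd.DataFrame({
        "marker": df["marker"],
        "chrom": df.get("phys_chrom"),
        "bp": pd.to_numeric(df.get("phys_bp"), errors="coerce").astype("Int64"),
    })
    # keep bp only where a chromosome is present
    out.loc[out["chrom"].isna(), "bp"] = pd.NA
    return PhysicalPlacement(out)


def nonsyntenic_marker_count(map_table_csv: str | Path, population: str) -> int:
    """Mapped-and-placed markers whose genetic chromosome differs from the
    assembly chromosome, via the concordance operation."""
    table = genio.read_map_table(map_table_csv)
    lmap = genio.table_to_map(table, population)
    placement = _placement_from_table(table)
    _, counts = concordance(lmap, placement)
    return counts["n_discordant"]


def unplaced_mapped_count(map_table_csv: str | Path) -> int:
    """Markers carrying a genetic position on either map but absent from
    the assembly."""
    table = genio.read_map_table(map_table_csv)
    df = table.df
    mapped_any = False
    for pop in table.populations:
        mapped_any = mapped_any | df[f"{pop}_status"].isin(
            (genio.STATUS_FRAME, genio.STATUS_PLACED))
    unplaced = df["phys_chrom"].isna() if "phys_chrom" in df.columns \
        else pd.Series(True, index=df.index)
    return int((mapped_any & unplaced).sum())
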