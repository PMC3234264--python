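"""Prioritized SNP panel selection.

Pipeline: prefilter (duplicates, double-flanking-SNP contamination, low
assay design score) then a four-step staged selection:

1. non-Panzea candidates located in catalogued genes (one per gene);
2. non-Panzea candidates outside genes;
3. Panzea candidates in genes not yet covered (one per gene);
4. greedy even-spacing fill across the genome up to the target size.

Within a gene, ties prefer the one-bead assay class, then the higher
design score, then the lexicographically smaller id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

PANZEA = "panzea"
ONE_BEAD = "one_bead"   # preferred assay class
TWO_BEAD = "two_bead"


@dataclass(frozen=True)
class CandidateSNP:
    id: str
    source: str
    gene: str | None
    design_score: float
    assay_class: str = ONE_BEAD
    flank_left: bool = False
    flank_right: bool = False
    chrom: str | None = None
    bp: int | None = None

    def __post_init__(self) -> None:
        if self.assay_class not in (ONE_BEAD, TWO_BEAD):
            raise ValueError(f"unknown assay class {self.assay_class!r}")


@dataclass
class SelectionConfig:
    target_size: int
    min_design_score: float = 0.0
    even_spacing: bool = True


def _preference_key(c: CandidateSNP):
    return (0 if c.assay_class == ONE_BEAD else 1, -c.design_score, c.id)


def prefilter(
    candidates: Sequence[CandidateSNP],
    min_design_score: float = 0.0,
) -> list[CandidateSNP]:
    """Drop duplicates, double-flanked candidates and low-score assays.

    Duplicates are candidates with a repeated id or a repeated genomic
    position; the first occurrence survives.
    """
    seen_ids: set[str] = set()
    seen_pos: set[tuple[str, int]] = set()
    out = []
    for c in candidates:
        if c.id in seen_ids:
            continue
        pos = (c.chrom, c.bp) if c.chrom is not None and c.bp is not None else None
        if pos is not None and pos in seen_pos:
            continue
        if c.flank_left and c.flank_right:
            continue
        if c.design_score < min_design_score:
            continue
        seen_ids.add(c.id)
        if pos is not None:
            seen_pos.add(pos)
        out.append(c)
    return out


def _pick_per_gene(pool: Iterable[CandidateSNP]) -> list[CandidateSNP]:
    by_gene: dict[str, list[CandidateSNP]] = {}
    for c in pool:
        by_gene.setdefault(c.gene, []).append(c)
    picks = []
    for gene in sorted(by_gene):
        picks.append(min(by_gene[gene], key=_preference_key))
    return picks


def _spacing_fill(
    selected: list[CandidateSNP],
    pool: list[CandidateSNP],
    n_needed: int,
) -> list[CandidateSNP]:
    """Repeatedly place a candidate inside the largest physical gap,
    preferring the one nearest the gap midpoint."""
    placed_pool = [c for c in pool if c.chrom is not None]
    positions: dict[str, list[int]] = {}
    for c in selected:
        if c.chrom is not None:
            positions.setdefault(c.chrom, []).append(c.bp)
    bounds: dict[str, tuple[int, int]] = {}
    for c in placed_pool + [s for s in selected if s.chrom is not None]:
        lo, hi = bounds.get(c.chrom, (c.bp, c.bp))
        bounds[c.chrom] = (min(lo, c.bp), max(hi, c.bp))

    available = list(placed_pool)
    picks: list[CandidateSNP] = []
    while len(picks) < n_needed and available:
        # largest gap that actually contains an available candidate
        best = None  # (gap size, candidates in gap, gap midpoint)
        for chrom, (lo_b, hi_b) in bounds.items():
            pts = sorted(positions.get(chrom, []))
            edges = [lo_b - 1] + pts + [hi_b + 1]
            for a, b in zip(edges, edges[1:]):
                if best is not None and b - a <= best[0]:
                    continue
                in_gap = [c for c in available if c.chrom == chrom and a < c.bp < b]
                if in_gap:
                    best = (b - a, in_gap, (a + b) / 2.0)
        if best is None:
            break
        _, in_gap, mid = best
        pick = min(in_gap, key=lambda c: (abs(c.bp - mid),) + _preference_key(c))
        picks.append(pick)
        available.remove(pick)
        positions.setdefault(pick.chrom, []).append(pick.bp)
    return picks


def staged_select(
    candidates: Sequence[CandidateSNP],
    gene_catalogue: set[str],
    config: SelectionConfig,
) -> pd.DataFrame:
    """Run the four-step selection; returns columns (id, step, gene).

    ``gene_catalogue`` is the set of high-confidence gene ids; a candidate
    is "in a gene" when its gene annotation is in the catalogue.
    """
    if not candidates:
        raise ValueError("empty candidate set")

    pool = list(candidates)
    chosen: list[tuple[CandidateSNP, int]] = []
    chosen_ids: set[str] = set()
    covered_genes: set[str] = set()

    def take(picks: Iterable[CandidateSNP], step: int) -> None:
        for c in picks:
            if len(chosen) >= config.target_size:
                return
            if c.id in chosen_ids:
                continue
            chosen.append((c, step))
            chosen_ids.add(c.id)
            if c.gene is not None:
                covered_genes.add(c.gene)

    in_gene = [c for c in pool if c.gene is not None and c.gene in gene_catalogue]
    step1 = _pick_per_gene([c for c in in_gene if c.source != PANZEA])
    take(step1, 1)

    step2 = sorted(
        (c for c in pool
         if c.source != PANZEA and (c.gene is None or c.gene not in gene_catalogue)),
        key=_preference_key)
    take(step2, 2)

    step3 = _pick_per_gene(
        [c for c in in_gene if c.source == PANZEA and c.gene not in covered_genes])
    take(step3, 3)

    remaining = [c for c in pool if c.id not in chosen_ids]
    n_needed = config.target_size - len(chosen)
    if n_needed > 0 and remaining:
        if config.even_spacing:
            picks = _spacing_fill([c for c, _ in chosen], remaining, n_needed)
        else:
            picks = sorted(remaining, key=_preference_key)[:n_needed]
        take(picks, 4)

    return pd.DataFrame(
        [(c.id, step, c.gene) for c, step in chosen],
        columns=["id", "step", "gene"])
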