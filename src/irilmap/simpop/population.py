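"""Forward simulation of intermated recombinant inbred lines.

Meiosis uses a no-interference (Haldane) crossover process evaluated at
the marker loci only: between adjacent markers separated by ``d`` cM the
gamete switches parental haplotype with probability
``r = (1 - exp(-2 d / 100)) / 2``, independently per interval.

The intermating phase assumes an effectively infinite mating pool: every
line descends from its own pedigree of ``2**t`` independent F2
individuals, so lines are i.i.d. and match the infinite-population
two-locus algebra used by :mod:`irilmap.linkmap.mapfunc`.
"""

from __future__ import annotations

import numpy as np

from ..core import AA, AB, BB, GenotypeMatrix
from .genome import GenomeModel, PopulationDesign, TruthSet

#: cap on extra selfing generations when running to fixation
_FIXATION_CAP = 512


def haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Meiotic recombination fraction for a Haldane map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _meiosis(hap: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual. ``hap``: (n, K, 2) int8; returns (n, K)."""
    n, k, _ = hap.shape
    chooser = np.empty((n, k), dtype=np.intp)
    chooser[:, 0] = rng.integers(0, 2, size=n)
    if k > 1:
        switches = np.cumsum(rng.random((n, k - 1)) < r, axis=1)
        chooser[:, 1:] = (chooser[:, :1] + switches) & 1
    return np.take_along_axis(hap, chooser[:, :, None], axis=2)[:, :, 0]


def _simulate_chromosome(
    cm: np.ndarray, design: PopulationDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one chromosome; returns (haplotypes (n_lines, K, 2), junctions)."""
    k = cm.size
    r = haldane_r(np.diff(cm))
    t = design.t_intermating
    n_units = design.n_lines << t

    # F1 is fully heterozygous with haplotypes identically 0 and 1, so an
    # F1 gamete *is* the chooser sequence of its meiosis.
    f1 = np.zeros((n_units, k, 2), dtype=np.int8)
    f1[:, :, 1] = 1
    hap = np.stack([_meiosis(f1, r, rng), _meiosis(f1, r, rng)], axis=2)  # F2

    for _ in range(t):
        half = hap.shape[0] // 2
        mom, dad = hap[0::2], hap[1::2]
        hap = np.stack([_meiosis(mom, r, rng), _meiosis(dad, r, rng)], axis=2)
        assert hap.shape[0] == half

    for _ in range(design.n_selfing):
        hap = np.stack([_meiosis(hap, r, rng), _meiosis(hap, r, rng)], axis=2)

    if design.self_to_fixation:
        for _ in range(_FIXATION_CAP):
            het = hap[:, :, 0] != hap[:, :, 1]
            if not het.any():
                break
            rows = het.any(axis=1)
            sub = hap[rows]
            hap[rows] = np.stack([_meiosis(sub, r, rng), _meiosis(sub, r, rng)], axis=2)

    junctions = (np.abs(np.diff(hap, axis=1)).sum(axis=(1, 2))
                 if k > 1 else np.zeros(hap.shape[0], dtype=np.int64))
    return hap, np.asarray(junctions, dtype=np.int64)


def parental_calls(n_markers: int) -> tuple[np.ndarray, np.ndarray]:
    """Founder genotype vectors: parent 1 is all-AA, parent 2 all-BB."""
    return (np.full(n_markers, AA, dtype=np.int8),
            np.full(n_markers, BB, dtype=np.int8))


def simulate_iril_population(
    genome: GenomeModel,
    design: PopulationDesign,
    include_parents: bool = True,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate an IRIL population genotyped at the genome's markers.

    Returns the genotype matrix (parent-1 allele is the alphabetically
    first allele of each marker, encoded AA) and the :class:`TruthSet`
    with true order/positions and per-line junction counts.
    """
    if not genome.chromosomes or all(c.n_markers < 2 for c in genome.chromosomes):
        if genome.n_markers == 0:
            raise ValueError("genome has no markers")
    rng = np.random.default_rng(design.rng_seed)

    calls_parts: list[np.ndarray] = []
    truth = TruthSet(design=design)
    junctions = np.zeros(design.n_lines, dtype=np.int64)
    for chrom in genome.chromosomes:
        if chrom.n_markers == 0:
            continue
        hap, junc = _simulate_chromosome(chrom.cm, design, rng)
        calls_parts.append((hap[:, :, 0] + hap[:, :, 1]).T.astype(np.int8))
        junctions += junc
        truth.true_order[chrom.name] = list(chrom.marker_ids)
        truth.true_cm[chrom.name] = chrom.cm.copy()
        truth.true_bp[chrom.name] = chrom.bp.copy()
    truth.crossover_counts = junctions

    calls = np.vstack(calls_parts)  # codes: 0=AA, 1=AB, 2=BB by construction
    markers = np.asarray(genome.marker_ids(), dtype=object)
    samples = [f"L{i + 1:04d}" for i in range(design.n_lines)]

    allele_rng = np.random.default_rng(design.rng_seed + 1)
    pairs = np.asarray(
        [sorted(allele_rng.choice(list("ACGT"), size=2, replace=False))
         for _ in range(markers.size)], dtype=object)

    if include_parents:
        p1, p2 = parental_calls(markers.size)
        calls = np.hstack([p1[:, None], p2[:, None], calls])
        samples = ["P1", "P2"] + samples

    matrix = GenotypeMatrix(
        markers=markers,
        samples=np.asarray(samples, dtype=object),
        calls=calls,
        alleles=pairs,
    )
    return matrix, truth


def make_triplets(
    parent1: np.ndarray,
    parent2: np.ndarray,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Expected F1 genotype vector from two (homozygous-or-FAILED) parents.

    Mendelian expectation: same homozygote -> that genotype; different
    homozygotes -> AB; any FAILED parent -> FAILED.  With ``error_rate``
    each informative call is replaced by a random different call.
    """
    p1 = np.asarray(parent1, dtype=np.int8)
    p2 = np.asarray(parent2, dtype=np.int8)
    if p1.shape != p2.shape:
        raise ValueError("parent vectors differ in length")
    het = np.isin(p1, (AB,)) | np.isin(p2, (AB,))
    if het.any():
        raise ValueError("parents must be homozygous or FAILED at every marker")
    f1 = np.where((p1 < 0) | (p2 < 0), -1, np.where(p1 == p2, p1, AB)).astype(np.int8)
    if error_rate:
        rng = np.random.default_rng(seed)
        hit = (rng.random(f1.size) < error_rate) & (f1 >= 0)
        if hit.any():
            shift = rng.integers(1, 3, size=int(hit.sum()))
            f1[hit] = ((f1[hit] + shift) % 3).astype(np.int8)
    return f1
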