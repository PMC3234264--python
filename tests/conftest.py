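import numpy as np
import pytest

from irilmap import linkmap, simpop
from irilmap.core import GenotypeMatrix


@pytest.fixture(scope="session")
def two_chrom_sim():
    """Simulated 2-chromosome IRIL population with mild noise + truth."""
    genome = simpop.GenomeModel.uniform(
        n_chromosomes=2, markers_per_chrom=60, length_cm=120,
        length_bp=100_000_000, seed=5)
    design = simpop.PopulationDesign(
        n_lines=239, t_intermating=4, n_selfing=6, rng_seed=11)
    matrix, truth = simpop.simulate_iril_population(genome, design)
    noisy = simpop.corrupt_genotypes(
        matrix, simpop.NoiseModel(call_error_rate=0.005, missing_rate=0.04),
        seed=12)
    return genome, design, noisy, truth


@pytest.fixture(scope="session")
def two_chrom_build(two_chrom_sim):
    """Full de-novo map build on the 2-chromosome simulation."""
    _, _, noisy, _ = two_chrom_sim
    config = linkmap.MapConfig(t=4, n_replicates=4)
    return linkmap.build_map(noisy, "P1", "P2", config, population="sim")


@pytest.fixture
def tiny_matrix():
    """3 markers x 4 samples with one FAILED call and one heterozygote."""
    calls = np.array([
        [0, 2, 1, -1],
        [0, 0, 2, 2],
        [2, 2, 2, 0],
    ], dtype=np.int8)
    return GenotypeMatrix(
        markers=np.array(["m1", "m2", "m3"], dtype=object),
        samples=np.array(["s1", "s2", "s3", "s4"], dtype=object),
        calls=calls,
        alleles=np.array([["A", "G"], ["C", "T"], ["A", "C"]], dtype=object),
        sources=np.array(["src"] * 3, dtype=object),
        dbsnp=np.array(["ss1", "ss2", "ss3"], dtype=object),
    )


def true_cm_lookup(truth):
    return {m: truth.true_cm[c][i]
            for c, ms in truth.true_order.items() for i, m in enumerate(ms)}
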