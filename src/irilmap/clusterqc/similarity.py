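"""DICE similarity between samples and a UPGMA dendrogram.

Each genotype is treated as the multiset of its two alleles, so a pair of
samples shares 2 alleles at a marker where both are the same genotype,
1 where a homozygote meets a heterozygote, and 0 between opposite
homozygotes.  DICE similarity is (shared alleles) / (2 x joint markers).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ..core import FAILED, GenotypeMatrix

#: shared-allele count by genotype-code pair (AA/AB/BB)
_SHARED = np.array([
    [2, 1, 0],
    [1, 2, 1],
    [0, 1, 2],
], dtype=np.int64)


def dice_similarity(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise DICE similarity over jointly called markers."""
    calls = matrix.calls
    n = matrix.n_samples
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            joint = (calls[:, i] != FAILED) & (calls[:, j] != FAILED)
            m = int(joint.sum())
            if m == 0:
                raise ValueError(
                    f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} "
                    "share no jointly called markers; similarity undefined")
            shared = _SHARED[calls[joint, i], calls[joint, j]].sum()
            sim[i, j] = sim[j, i] = shared / (2.0 * m)
    return pd.DataFrame(sim, index=matrix.samples, columns=matrix.samples)


def dice_dendrogram(matrix: GenotypeMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """DICE similarity matrix plus a UPGMA tree on distance 1 - similarity.

    Returns (similarity DataFrame, scipy linkage matrix).
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples for a dendrogram")
    sim = dice_similarity(matrix)
    dist = 1.0 - sim.to_numpy()
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    return sim, tree
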