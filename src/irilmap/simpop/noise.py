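"""Genotyping-noise injection with per-call quality scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import FAILED, GenotypeMatrix


@dataclass
class NoiseModel:
    """Call flips, dropouts and a two-component quality-score model.

    Quality scores are Beta-distributed: a high mode for clean calls and a
    low mode for corrupted ones, chosen so the downstream 0.8 / 0.6
    thresholds separate the two populations well.
    """

    call_error_rate: float = 0.0
    missing_rate: float = 0.0
    gc_good: tuple[float, float] = (45.0, 3.0)
    gc_bad: tuple[float, float] = (3.0, 4.0)

    def __post_init__(self) -> None:
        for name in ("call_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def corrupt_genotypes(
    matrix: GenotypeMatrix, noise: NoiseModel, seed: int | None = None
) -> GenotypeMatrix:
    """Return a corrupted copy of ``matrix`` carrying GC scores.

    Each called cell is independently flipped to one of the two other
    genotypes with probability ``call_error_rate``, then set to FAILED
    with probability ``missing_rate``.  Clean calls get high-mode GC
    scores, flipped calls low-mode ones, FAILED cells ``NaN``.
    The input matrix is not modified.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    calls = out.calls
    called = calls != FAILED

    flip = called & (rng.random(calls.shape) < noise.call_error_rate)
    if flip.any():
        shift = rng.integers(1, 3, size=int(flip.sum()))
        calls[flip] = ((calls[flip] + shift) % 3).astype(np.int8)

    gc = np.full(calls.shape, np.nan)
    good = called & ~flip
    gc[good] = rng.beta(*noise.gc_good, size=int(good.sum()))
    gc[flip] = rng.beta(*noise.gc_bad, size=int(flip.sum()))

    drop = called & (rng.random(calls.shape) < noise.missing_rate)
    calls[drop] = FAILED
    gc[drop] = np.nan

    out.calls = calls
    out.gc = gc
    return out
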