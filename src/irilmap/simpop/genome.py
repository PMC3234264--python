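"""Genome and population-design models for the simulator."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class ChromosomeModel:
    """One chromosome: genetic length (cM), physical length (bp) and markers.

    Markers are ordered; cM positions are non-decreasing (co-segregating
    markers may share a position), bp positions strictly increasing.
    """

    name: str
    length_cm: float
    length_bp: int
    marker_ids: list[str]
    cm: np.ndarray
    bp: np.ndarray

    def __post_init__(self) -> None:
        self.cm = np.asarray(self.cm, dtype=float)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        n = len(self.marker_ids)
        if self.cm.shape != (n,) or self.bp.shape != (n,):
            raise ValueError(f"chromosome {self.name}: marker arrays disagree in length")
        if self.length_cm <= 0 or self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: zero-length chromosome")
        if n:
            if (np.diff(self.cm) < 0).any():
                raise ValueError(f"chromosome {self.name}: cM positions must be non-decreasing")
            if (np.diff(self.bp) <= 0).any():
                raise ValueError(f"chromosome {self.name}: bp positions must be strictly increasing")
            if self.cm[0] < 0 or self.cm[-1] > self.length_cm + 1e-9:
                raise ValueError(f"chromosome {self.name}: cM positions outside [0, length]")
            if self.bp[0] < 1 or self.bp[-1] > self.length_bp:
                raise ValueError(f"chromosome {self.name}: bp positions outside [1, length]")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class GenomeModel:
    """Ordered chromosomes with true marker positions (the simulation truth)."""

    chromosomes: list[ChromosomeModel]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chromosomes)

    def marker_ids(self) -> list[str]:
        out: list[str] = []
        for c in self.chromosomes:
            out.extend(c.marker_ids)
        return out

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int = 10,
        markers_per_chrom: int = 200,
        length_cm: float = 170.0,
        length_bp: int = 200_000_000,
        seed: int | None = None,
        cm_profile=None,
    ) -> "GenomeModel":
        """Build a genome with markers at random bp positions.

        ``cm_profile`` maps a bp fraction in [0, 1] to a genetic-position
        fraction in [0, 1] (monotone); default is linear.  Useful to plant
        recombination landscapes (e.g. centromeric suppression).
        """
        rng = np.random.default_rng(seed)
        chroms = []
        for ci in range(1, n_chromosomes + 1):
            bp = _sample_unique_positions(rng, length_bp, markers_per_chrom)
            frac = (bp - 1) / max(length_bp - 1, 1)
            if cm_profile is None:
                cmfrac = frac
            else:
                cmfrac = np.asarray([cm_profile(f) for f in frac], dtype=float)
                if (np.diff(cmfrac) < 0).any():
                    raise ValueError("cm_profile must be monotone non-decreasing")
            cm = np.clip(cmfrac, 0.0, 1.0) * length_cm
            ids = [f"c{ci}m{k:04d}" for k in range(markers_per_chrom)]
            chroms.append(ChromosomeModel(str(ci), length_cm, length_bp, ids, cm, bp))
        return cls(chroms)


def _sample_unique_positions(rng: np.random.Generator, length_bp: int,
                             n: int) -> np.ndarray:
    """n distinct bp positions in [1, length_bp] without materializing the
    full coordinate range."""
    if n > length_bp:
        raise ValueError("more markers than bp positions")
    if length_bp <= 4 * n:
        return np.sort(rng.permutation(length_bp)[:n] + 1)
    pos: np.ndarray = np.unique(rng.integers(1, length_bp + 1, size=2 * n))
    while pos.size < n:
        extra = rng.integers(1, length_bp + 1, size=2 * n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.permutation(pos)[:n])


@dataclass
class PopulationDesign:
    """IRIL crossing design: F2 -> t generations of random intermating ->
    repeated selfing by single-seed descent."""

    n_lines: int = 239
    t_intermating: int = 4
    n_selfing: int = 6
    rng_seed: int = 0
    self_to_fixation: bool = False

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.t_intermating < 0:
            raise ValueError("t_intermating must be >= 0")
        if self.n_selfing < 1:
            raise ValueError("n_selfing must be >= 1")


@dataclass
class AssemblyEdit:
    """Base class for planted assembly corruptions."""


@dataclass
class Inversion(AssemblyEdit):
    chrom: str
    start_bp: int
    end_bp: int


@dataclass
class Translocation(AssemblyEdit):
    chrom: str
    start_bp: int
    end_bp: int
    dest_chrom: str
    dest_bp: int


@dataclass
class Deletion(AssemblyEdit):
    markers: tuple[str, ...]

    def __init__(self, markers: Sequence[str]):
        self.markers = tuple(markers)


@dataclass
class TruthSet:
    """Ground truth attached to simulator outputs."""

    true_order: dict[str, list[str]] = field(default_factory=dict)
    true_cm: dict[str, np.ndarray] = field(default_factory=dict)
    true_bp: dict[str, np.ndarray] = field(default_factory=dict)
    edits: list[dict] = field(default_factory=list)
    deleted_markers: list[str] = field(default_factory=list)
    crossover_counts: np.ndarray | None = None
    design: PopulationDesign | None = None

    def chrom_of_marker(self) -> dict[str, str]:
        out = {}
        for chrom, ids in self.true_order.items():
            for m in ids:
                out[m] = chrom
        return out
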