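"""Core data containers shared across the pipeline.

Genotype calls are stored as a dense ``int8`` matrix (markers x samples)
using the codes :data:`AA`, :data:`AB`, :data:`BB` and :data:`FAILED`.
IUPAC letters exist only at the file boundary (see :mod:`irilmap.genio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: genotype call codes
AA: int = 0
AB: int = 1
BB: int = 2
FAILED: int = -1

CALL_NAMES: Mapping[int, str] = {AA: "AA", AB: "AB", BB: "BB", FAILED: "FAILED"}

#: IUPAC ambiguity letter for an unordered base pair
IUPAC_HET = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}
HET_TO_PAIR = {v: tuple(sorted(k)) for k, v in IUPAC_HET.items()}

BASES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Markers x samples call table with optional per-call quality scores.

    Parameters
    ----------
    markers, samples
        Row / column identifiers (unique).
    calls
        ``int8`` array of shape ``(n_markers, n_samples)`` with values in
        ``{AA, AB, BB, FAILED}``.
    alleles
        Per-marker ``(allele_a, allele_b)`` base letters; canonical order is
        alphabetical so that round trips through the file format are exact.
    gc
        Optional per-call quality score in ``[0, 1]`` (same shape as
        ``calls``); ``NaN`` where not applicable.
    sources, dbsnp
        Optional per-marker annotation columns carried through file I/O.
    """

    markers: np.ndarray
    samples: np.ndarray
    calls: np.ndarray
    alleles: np.ndarray
    gc: np.ndarray | None = None
    sources: np.ndarray | None = None
    dbsnp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=object)
        self.samples = np.asarray(self.samples, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.alleles = np.asarray(self.alleles, dtype=object)
        if self.calls.shape != (self.markers.size, self.samples.size):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.markers.size} markers x {self.samples.size} samples"
            )
        if self.alleles.shape != (self.markers.size, 2):
            raise ValueError("alleles must have shape (n_markers, 2)")
        bad = ~np.isin(self.calls, (AA, AB, BB, FAILED))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"invalid call code {self.calls[i, j]} at marker "
                             f"{self.markers[i]!r}, sample {self.samples[j]!r}")
        if len(set(self.markers)) != self.markers.size:
            raise ValueError("duplicate marker ids")
        if len(set(self.samples)) != self.samples.size:
            raise ValueError("duplicate sample ids")
        if self.gc is not None:
            self.gc = np.asarray(self.gc, dtype=np.float64)
            if self.gc.shape != self.calls.shape:
                raise ValueError("gc shape must match calls")

    @property
    def n_markers(self) -> int:
        return int(self.markers.size)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            markers=self.markers.copy(),
            samples=self.samples.copy(),
            calls=self.calls.copy(),
            alleles=self.alleles.copy(),
            gc=None if self.gc is None else self.gc.copy(),
            sources=None if self.sources is None else self.sources.copy(),
            dbsnp=None if self.dbsnp is None else self.dbsnp.copy(),
        )

    def sample_index(self, sample: str) -> int:
        idx = np.flatnonzero(self.samples == sample)
        if idx.size == 0:
            raise KeyError(f"unknown sample {sample!r}")
        return int(idx[0])

    def sample_calls(self, sample: str) -> np.ndarray:
        return self.calls[:, self.sample_index(sample)]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.markers, other.markers)
            and np.array_equal(self.samples, other.samples)
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.alleles, other.alleles)
        )


UNPLACED = "unplaced"


@dataclass
class PhysicalPlacement:
    """Marker -> assembly chromosome + bp coordinate (or unplaced).

    Backed by a DataFrame with columns ``marker``, ``chrom`` (object,
    ``None`` for unplaced) and ``bp`` (nullable integer).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        required = {"marker", "chrom", "bp"}
        if not required.issubset(df.columns):
            raise ValueError(f"placement table needs columns {sorted(required)}")
        if df["marker"].duplicated().any():
            dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate placement row for marker {dup!r}")
        placed = df["chrom"].notna()
        bp = df.loc[placed, "bp"]
        if bp.isna().any():
            raise ValueError("placed marker without bp coordinate")
        if (bp < 1).any():
            raise ValueError("bp coordinates must be >= 1")
        self.df = df

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str | None, int | None]]
    ) -> "PhysicalPlacement":
        df = pd.DataFrame(records, columns=["marker", "chrom", "bp"])
        df["bp"] = df["bp"].astype("Int64")
        return cls(df)

    @property
    def placed(self) -> pd.DataFrame:
        return self.df[self.df["chrom"].notna()]

    def chrom_of(self) -> pd.Series:
        return self.df.set_index("marker")["chrom"]

    def bp_of(self) -> pd.Series:
        return self.df.set_index("marker")["bp"]

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        sub = self.placed
        return sub[sub["chrom"] == chrom].sort_values("bp").reset_index(drop=True)

    def copy(self) -> "PhysicalPlacement":
        return PhysicalPlacement(self.df.copy())


#: marker tiers in a linkage map, from most to least order-robust
TIER_SCAFFOLD = "scaffold"
TIER_FRAMEWORK = "framework"
TIER_PLACED = "placed"
TIERS = (TIER_SCAFFOLD, TIER_FRAMEWORK, TIER_PLACED)


@dataclass
class LinkageMap:
    """Ordered markers per chromosome with tier and genetic coordinates.

    ``chromosomes`` maps a linkage-group / chromosome label to a DataFrame
    with columns ``marker``, ``tier``, ``cm``, ``pseudo_cm``, ``score``
    (placement score, ``NaN`` for framework markers), sorted by ``cm``.
    """

    chromosomes: dict[str, pd.DataFrame] = field(default_factory=dict)
    population: str = "pop"

    def __post_init__(self) -> None:
        for chrom, df in self.chromosomes.items():
            missing = {"marker", "tier", "cm", "pseudo_cm"} - set(df.columns)
            if missing:
                raise ValueError(f"chromosome {chrom}: missing columns {sorted(missing)}")
            if "score" not in df.columns:
                df = df.assign(score=np.nan)
            df = df.sort_values(["cm", "marker"], kind="stable").reset_index(drop=True)
            if (np.diff(df["cm"].to_numpy(float)) < -1e-9).any():
                raise ValueError(f"chromosome {chrom}: cM not non-decreasing")
            bad = ~df["tier"].isin(TIERS)
            if bad.any():
                raise ValueError(f"chromosome {chrom}: unknown tier "
                                 f"{df.loc[bad, 'tier'].iloc[0]!r}")
            self.chromosomes[chrom] = df

    def to_frame(self) -> pd.DataFrame:
        """All markers as one table with a ``chrom`` column."""
        parts = []
        for chrom, df in self.chromosomes.items():
            parts.append(df.assign(chrom=chrom))
        if not parts:
            return pd.DataFrame(
                columns=["marker", "tier", "cm", "pseudo_cm", "score", "chrom"]
            )
        return pd.concat(parts, ignore_index=True)

    def framework(self, chrom: str) -> pd.DataFrame:
        df = self.chromosomes[chrom]
        return df[df["tier"].isin((TIER_SCAFFOLD, TIER_FRAMEWORK))].reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return int(sum(len(df) for df in self.chromosomes.values()))

    def total_length_cm(self) -> float:
        return float(sum(df["cm"].max() - df["cm"].min()
                         for df in self.chromosomes.values() if len(df)))

    def total_length_pseudo_cm(self) -> float:
        return float(sum(df["pseudo_cm"].max() - df["pseudo_cm"].min()
                         for df in self.chromosomes.values() if len(df)))
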