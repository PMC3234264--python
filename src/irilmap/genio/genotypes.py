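"""Genotype-table CSV dialect.

Layout: a header row ``Marker,Source,dbSNP,<sample...>``; one row per
marker; sample cells hold a single IUPAC base letter (homozygote), an
IUPAC ambiguity letter (heterozygote) or the literal token ``Failed``.
Per-call quality scores travel in a sibling CSV of identical layout with
numeric cells (empty where the call is FAILED).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from ..core import AA, AB, BB, FAILED, BASES, HET_TO_PAIR, IUPAC_HET, GenotypeMatrix

FAILED_TOKEN = "Failed"
_HEADER_FIXED = ("Marker", "Source", "dbSNP")


class GenotypeParseError(ValueError):
    pass


def _infer_alleles(hom_letters: set[str], het_codes: set[str],
                   marker: str) -> tuple[str, str]:
    pairs = {HET_TO_PAIR[c] for c in het_codes}
    if len(pairs) > 1:
        raise GenotypeParseError(
            f"marker {marker!r}: conflicting heterozygote codes {sorted(het_codes)}")
    if pairs:
        pair = next(iter(pairs))
        extra = hom_letters - set(pair)
        if extra:
            raise GenotypeParseError(
                f"marker {marker!r}: homozygous call {sorted(extra)} outside "
                f"allele pair {pair}")
        return pair
    letters = sorted(hom_letters)
    if len(letters) > 2:
        raise GenotypeParseError(
            f"marker {marker!r}: more than two alleles observed: {letters}")
    if len(letters) == 2:
        return letters[0], letters[1]
    if len(letters) == 1:  # monomorphic in this file; second allele unknown
        return letters[0], letters[0]
    return "N", "N"


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Parse a genotype CSV into a :class:`GenotypeMatrix`."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeParseError(f"{path}: empty file") from None
        if tuple(header[:3]) != _HEADER_FIXED:
            raise GenotypeParseError(
                f"{path}: header must start with {','.join(_HEADER_FIXED)}")
        samples = header[3:]
        if len(set(samples)) != len(samples):
            raise GenotypeParseError(f"{path}: duplicate sample columns")
        n_cols = len(header)

        markers, sources, dbsnp, rows, alleles = [], [], [], [], []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != n_cols:
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(row)}")
            marker = row[0]
            markers.append(marker)
            sources.append(row[1])
            dbsnp.append(row[2])
            hom_letters: set[str] = set()
            het_codes: set[str] = set()
            cells = row[3:]
            for j, cell in enumerate(cells):
                if cell == FAILED_TOKEN:
                    continue
                if cell in BASES:
                    hom_letters.add(cell)
                elif cell in HET_TO_PAIR:
                    het_codes.add(cell)
                else:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: unknown genotype token {cell!r} "
                        f"for marker {marker!r}, sample {samples[j]!r}")
            a, b = _infer_alleles(hom_letters, het_codes, marker)
            alleles.append((a, b))
            het_code = IUPAC_HET.get(frozenset((a, b)))
            codes = np.empty(len(cells), dtype=np.int8)
            for j, cell in enumerate(cells):
                if cell == FAILED_TOKEN:
                    codes[j] = FAILED
                elif cell == a:
                    codes[j] = AA
                elif cell == b:
                    codes[j] = BB
                elif cell == het_code:
                    codes[j] = AB
                else:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: call {cell!r} inconsistent with "
                        f"alleles {a}/{b} of marker {marker!r}, sample {samples[j]!r}")
            rows.append(codes)

    calls = (np.vstack(rows) if rows
             else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(
        markers=np.asarray(markers, dtype=object),
        samples=np.asarray(samples, dtype=object),
        calls=calls,
        alleles=np.asarray(alleles, dtype=object).reshape(-1, 2),
        sources=np.asarray(sources, dtype=object),
        dbsnp=np.asarray(dbsnp, dtype=object),
    )


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` in the genotype CSV dialect."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_HEADER_FIXED) + list(matrix.samples))
        sources = matrix.sources if matrix.sources is not None \
            else np.full(matrix.n_markers, "synthetic", dtype=object)
        dbsnp = matrix.dbsnp if matrix.dbsnp is not None \
            else np.full(matrix.n_markers, "", dtype=object)
        for i in range(matrix.n_markers):
            a, b = matrix.alleles[i]
            het = IUPAC_HET.get(frozenset((a, b)), "N")
            lut = {AA: a, BB: b, AB: het, FAILED: FAILED_TOKEN}
            writer.writerow(
                [matrix.markers[i], sources[i], dbsnp[i]]
                + [lut[int(c)] for c in matrix.calls[i]])


def write_gc_scores(matrix: GenotypeMatrix, path: str | Path) -> None:
    if matrix.gc is None:
        raise ValueError("matrix carries no GC scores")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Marker"] + list(matrix.samples))
        for i in range(matrix.n_markers):
            row = ["" if np.isnan(g) else f"{g:.4f}" for g in matrix.gc[i]]
            writer.writerow([matrix.markers[i]] + row)


def read_gc_scores(matrix: GenotypeMatrix, path: str | Path) -> GenotypeMatrix:
    """Attach GC scores from a sibling CSV; returns the same matrix."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[1:] != list(matrix.samples):
            raise GenotypeParseError(f"{path}: sample columns do not match matrix")
        gc = np.full(matrix.calls.shape, np.nan)
        index = {m: i for i, m in enumerate(matrix.markers)}
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise GenotypeParseError(f"{path}:{lineno}: ragged row")
            try:
                i = index[row[0]]
            except KeyError:
                raise GenotypeParseError(
                    f"{path}:{lineno}: unknown marker {row[0]!r}") from None
            gc[i] = [np.nan if c == "" else float(c) for c in row[1:]]
    matrix.gc = gc
    return matrix
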