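"""Marker filtering and conversion to parental-origin coding."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import AB, FAILED, GenotypeMatrix

STAGE_FRAMEWORK = "framework"
STAGE_COMPLETE = "complete"

#: (gc_min, max_missing) defaults per stage
_STAGE_DEFAULTS = {
    STAGE_FRAMEWORK: (0.8, 0.35),
    STAGE_COMPLETE: (0.6, 0.50),
}


@dataclass
class FilterConfig:
    stage: str = STAGE_FRAMEWORK
    gc_min: float | None = None
    max_missing: float | None = None
    maf_min: float = 0.10

    def __post_init__(self) -> None:
        if self.stage not in _STAGE_DEFAULTS:
            raise ValueError(f"unknown stage {self.stage!r}")
        gc, mm = _STAGE_DEFAULTS[self.stage]
        if self.gc_min is None:
            self.gc_min = gc
        if self.max_missing is None:
            self.max_missing = mm


@dataclass
class FilterResult:
    """Origin-coded matrix for retained markers plus exclusion diagnostics."""

    marker_ids: np.ndarray              # retained markers, matrix order
    origins: np.ndarray                 # (n_retained, n_lines) in {0, 1, -1}
    line_samples: np.ndarray
    diagnostics: pd.DataFrame           # per input marker: reason or None
    config: FilterConfig = field(default=None)

    @property
    def n_markers(self) -> int:
        return int(self.marker_ids.size)


def filter_markers(
    matrix: GenotypeMatrix,
    parent1: str | np.ndarray,
    parent2: str | np.ndarray,
    config: FilterConfig | None = None,
) -> FilterResult:
    """Apply the stage's quality rules and recode calls as parental origins.

    Per-call: calls with GC score below ``gc_min`` and heterozygous calls
    become missing.  Per-marker: excluded when the parents are not both
    homozygous and polymorphic, when the missing fraction among lines
    exceeds ``max_missing``, or when the minor allele frequency is not
    greater than ``maf_min``.
    """
    config = config or FilterConfig()

    def parent_vec(p):
        if isinstance(p, str):
            return matrix.sample_calls(p).copy()
        return np.asarray(p, dtype=np.int8)

    try:
        p1 = parent_vec(parent1)
        p2 = parent_vec(parent2)
    except KeyError as exc:
        raise ValueError(f"parent sample not in matrix: {exc}") from exc

    parent_names = {p for p in (parent1, parent2) if isinstance(p, str)}
    line_mask = ~np.isin(matrix.samples, list(parent_names))
    line_samples = matrix.samples[line_mask]
    calls = matrix.calls[:, line_mask].copy()
    if matrix.gc is not None and config.gc_min is not None:
        gc = matrix.gc[:, line_mask]
        calls[np.isfinite(gc) & (gc < config.gc_min)] = FAILED
    calls[calls == AB] = FAILED  # heterozygous -> missing

    parents_ok = (p1 != FAILED) & (p2 != FAILED) & (p1 != AB) & (p2 != AB) & (p1 != p2)

    origins = np.full(calls.shape, -1, dtype=np.int8)
    origins[calls == p1[:, None]] = 0
    origins[calls == p2[:, None]] = 1

    n_lines = calls.shape[1]
    n_missing = (origins == -1).sum(axis=1)
    missing_frac = n_missing / n_lines
    n_info = n_lines - n_missing
    n1 = (origins == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_info > 0, n1 / np.maximum(n_info, 1), np.nan)
    maf = np.minimum(freq, 1.0 - freq)

    reason = np.full(matrix.n_markers, None, dtype=object)
    reason[~parents_ok] = "parents"
    rule_missing = parents_ok & (missing_frac > config.max_missing)
    reason[rule_missing] = "missing"
    rule_maf = parents_ok & ~rule_missing & ~(maf > config.maf_min)
    reason[rule_maf] = "maf"

    keep = np.asarray([r is None for r in reason])
    diagnostics = pd.DataFrame({
        "marker": matrix.markers,
        "excluded_reason": reason,
        "missing_frac": missing_frac,
        "maf": maf,
    })
    return FilterResult(
        marker_ids=matrix.markers[keep],
        origins=origins[keep],
        line_samples=line_samples,
        diagnostics=diagnostics,
        config=config,
    )
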