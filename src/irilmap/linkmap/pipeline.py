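"""End-to-end de-novo map construction: filter -> group -> scaffold ->
framework -> bin placement -> corrected distances."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import (
    TIER_FRAMEWORK,
    TIER_PLACED,
    TIER_SCAFFOLD,
    GenotypeMatrix,
    LinkageMap,
)
from .binplace import FrameworkMessages, Placement, place_bins
from .filtering import (
    STAGE_COMPLETE,
    STAGE_FRAMEWORK,
    FilterConfig,
    FilterResult,
    filter_markers,
)
from .framework import extend_framework
from .mapfunc import MapFunction
from .scaffold import OrderedMap, build_scaffold
from .twopoint import group_markers, pairwise_R


@dataclass
class MapConfig:
    t: int = 4
    framework_filter: FilterConfig = field(
        default_factory=lambda: FilterConfig(stage=STAGE_FRAMEWORK))
    complete_filter: FilterConfig = field(
        default_factory=lambda: FilterConfig(stage=STAGE_COMPLETE))
    lod_threshold: float = 6.0
    r_threshold: float = 0.45
    min_group_size: int = 3
    min_spacing_cm: float = 10.0
    score_threshold: float = 3.0
    robustness_threshold: float = 3.0
    n_replicates: int = 10
    placement_min_score: float = 0.5
    eps: float = 0.005


@dataclass
class ChromosomeBuild:
    chrom: str
    framework: OrderedMap
    marker_ids: np.ndarray       # group marker ids (framework-stage order)
    scaffold_markers: set[str]
    messages: FrameworkMessages

    def framework_marker_ids(self) -> list[str]:
        return [str(self.marker_ids[i]) for i in self.framework.idx]


@dataclass
class MapBuildResult:
    linkage_map: LinkageMap
    chromosomes: dict[str, ChromosomeBuild]
    placements: list[Placement]
    framework_filter: FilterResult
    complete_filter: FilterResult
    group_of_marker: dict[str, str]


def _cross_two_point(Xa: np.ndarray, Xb: np.ndarray):
    """N, D, LOD between rows of Xa and rows of Xb (origin-coded)."""
    A1, B1 = (Xa == 0).astype(float), (Xa == 1).astype(float)
    A2, B2 = (Xb == 0).astype(float), (Xb == 1).astype(float)
    N = (A1 + B1) @ (A2 + B2).T
    D = A1 @ B2.T + B1 @ A2.T
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.clip(D / np.maximum(N, 1), 1e-12, 0.5)
        lod = D * np.log10(p) + (N - D) * np.log10(1 - p) - N * np.log10(0.5)
    lod = np.where(N > 0, np.maximum(lod, 0.0), 0.0)
    R = np.where(N > 0, np.minimum(D / np.maximum(N, 1), 0.5), np.nan)
    return N, R, lod


def build_map(
    matrix: GenotypeMatrix,
    parent1: str | np.ndarray = "P1",
    parent2: str | np.ndarray = "P2",
    config: MapConfig | None = None,
    population: str = "pop",
) -> MapBuildResult:
    config = config or MapConfig()
    mapf = MapFunction(config.t)

    fw_res = filter_markers(matrix, parent1, parent2, config.framework_filter)
    groups = group_markers(fw_res.origins, fw_res.marker_ids,
                           config.lod_threshold, config.r_threshold)

    builds: dict[str, ChromosomeBuild] = {}
    group_of: dict[str, str] = {}
    chrom_no = 0
    for g in groups:
        if g.size < config.min_group_size:
            continue
        chrom_no += 1
        chrom = str(chrom_no)
        ids_g = fw_res.marker_ids[g]
        X_g = fw_res.origins[g]
        for m in ids_g:
            group_of[str(m)] = chrom
        R2 = pairwise_R(X_g)[0]
        scaffold = build_scaffold(
            X_g, ids_g, mapf,
            min_spacing_cm=config.min_spacing_cm,
            score_threshold=config.score_threshold,
            n_replicates=config.n_replicates,
            eps=config.eps, R2=R2)
        fwk = extend_framework(
            scaffold, X_g, ids_g, mapf,
            robustness_threshold=config.robustness_threshold,
            eps=config.eps, R2=R2)
        Xf = X_g[fwk.idx].T  # lines x framework markers, map order
        msg = FrameworkMessages(Xf, fwk, mapf)
        builds[chrom] = ChromosomeBuild(
            chrom=chrom,
            framework=fwk,
            marker_ids=ids_g,
            scaffold_markers={str(ids_g[i]) for i in scaffold.idx},
            messages=msg,
        )

    cp_res = filter_markers(matrix, parent1, parent2, config.complete_filter)
    framework_ids = {m for b in builds.values() for m in b.framework_marker_ids()}
    cand_mask = ~np.isin(cp_res.marker_ids.astype(str), sorted(framework_ids))
    cand_ids = cp_res.marker_ids[cand_mask]
    cand_X = cp_res.origins[cand_mask]

    # assign each candidate to the chromosome of its best-linked framework marker
    placements: list[Placement] = []
    if cand_ids.size and builds:
        fw_X = np.vstack([
            fw_res.origins[_group_rows(fw_res, b)] for b in builds.values()
        ])
        fw_chroms = np.concatenate([
            np.full(len(b.framework.idx), chrom, dtype=object)
            for chrom, b in builds.items()
        ])
        N, R, lod = _cross_two_point(cand_X, fw_X)
        best_j = np.argmax(lod, axis=1)
        best_lod = lod[np.arange(cand_X.shape[0]), best_j]
        best_R = R[np.arange(cand_X.shape[0]), best_j]
        for ci, marker in enumerate(cand_ids):
            marker = str(marker)
            group_of.setdefault(marker, None)
            linked = (best_lod[ci] >= config.lod_threshold
                      and best_R[ci] <= config.r_threshold)
            if not linked:
                placements.append(Placement(marker, None, mapped=False))
                continue
            chrom = str(fw_chroms[best_j[ci]])
            group_of[marker] = chrom
            placements.extend(place_bins(
                {chrom: builds[chrom].messages},
                {marker: cand_X[ci]},
                min_score=config.placement_min_score))

    linkage_map = _compose_map(builds, placements, mapf, population)
    return MapBuildResult(
        linkage_map=linkage_map,
        chromosomes=builds,
        placements=placements,
        framework_filter=fw_res,
        complete_filter=cp_res,
        group_of_marker=group_of,
    )


def _group_rows(fw_res: FilterResult, build: ChromosomeBuild) -> np.ndarray:
    """Rows of the framework-stage origin matrix for a build's framework
    markers, in map order."""
    index = {str(m): i for i, m in enumerate(fw_res.marker_ids)}
    return np.asarray([index[str(build.marker_ids[i])]
                       for i in build.framework.idx], dtype=int)


def _compose_map(
    builds: dict[str, ChromosomeBuild],
    placements: list[Placement],
    mapf: MapFunction,
    population: str,
) -> LinkageMap:
    placed_by_chrom: dict[str, list[Placement]] = {}
    for p in placements:
        if p.mapped:
            placed_by_chrom.setdefault(p.chrom, []).append(p)

    chroms: dict[str, pd.DataFrame] = {}
    for chrom, b in builds.items():
        cm = b.framework.cm_positions(mapf)
        pseudo = b.framework.pseudo_cm_positions(mapf)
        rows = []
        for pos, i in enumerate(b.framework.idx):
            marker = str(b.marker_ids[i])
            tier = TIER_SCAFFOLD if marker in b.scaffold_markers else TIER_FRAMEWORK
            rows.append((marker, tier, cm[pos], pseudo[pos], np.nan))
        for p in placed_by_chrom.get(chrom, []):
            rows.append((p.marker, TIER_PLACED, p.cm, p.pseudo_cm, p.score))
        df = pd.DataFrame(rows, columns=["marker", "tier", "cm", "pseudo_cm", "score"])
        df["cm"] -= df["cm"].min()
        df["pseudo_cm"] -= df["pseudo_cm"].min()
        chroms[chrom] = df
    return LinkageMap(chromosomes=chroms, population=population)
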