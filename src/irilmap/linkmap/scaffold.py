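"""Scaffold construction: a sparse, maximally order-robust marker skeleton.

Markers are accreted one at a time onto a seed; a candidate is admitted
only when its best insertion slot beats every alternative slot by a
log10-likelihood margin above ``score_threshold`` and the resulting
adjacent spacings stay above ``min_spacing_cm``.  Several replicates with
different seeds are reconciled by dropping markers whose relative order
is not supported by all replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau

from . import chain
from .mapfunc import MapFunction

_LN10 = np.log(10.0)


@dataclass
class OrderedMap:
    """A marker order with fitted interval probabilities."""

    idx: list[int]           # row indices into the group's origin matrix
    R: np.ndarray            # per-interval line-level recombinant probability
    eps: float
    loglik: float

    @property
    def size(self) -> int:
        return len(self.idx)

    def cm_positions(self, mapf: MapFunction) -> np.ndarray:
        d = np.asarray([mapf.cm(R) for R in self.R], dtype=float)
        return np.concatenate([[0.0], np.cumsum(d)])

    def pseudo_cm_positions(self, mapf: MapFunction) -> np.ndarray:
        p = mapf.pseudo
        d = np.asarray([p.cm(R) for R in self.R], dtype=float)
        return np.concatenate([[0.0], np.cumsum(d)])


def informativeness_order(origins: np.ndarray, marker_ids: np.ndarray) -> np.ndarray:
    """Marker indices ordered by fewest missing, then highest MAF, then id."""
    missing = (origins == -1).sum(axis=1)
    n_info = origins.shape[1] - missing
    n1 = (origins == 1).sum(axis=1)
    freq = n1 / np.maximum(n_info, 1)
    maf = np.minimum(freq, 1 - freq)
    keys = sorted(range(origins.shape[0]),
                  key=lambda i: (missing[i], -maf[i], str(marker_ids[i])))
    return np.asarray(keys, dtype=int)


def pick_seeds(
    R2: np.ndarray,
    info_order: np.ndarray,
    n_replicates: int,
    min_R: float = 0.2,
) -> list[int]:
    """Most-informative markers, mutually separated by two-point R >= min_R."""
    seeds: list[int] = []
    for i in info_order:
        if all(R2[i, s] >= min_R for s in seeds):
            seeds.append(int(i))
        if len(seeds) == n_replicates:
            break
    # fall back to plain informativeness if spacing is unreachable
    for i in info_order:
        if len(seeds) == n_replicates:
            break
        if int(i) not in seeds:
            seeds.append(int(i))
    return seeds[:n_replicates]


def _interval_R(order: list[int], R2: np.ndarray) -> np.ndarray:
    return np.asarray([min(max(R2[a, b], 1e-6), 0.5 - 1e-6)
                       for a, b in zip(order, order[1:])])


def _canonical(order: tuple[int, ...]) -> tuple[int, ...]:
    rev = order[::-1]
    return order if order <= rev else rev


def _local_polish(order: list[int], origins: np.ndarray, R2: np.ndarray,
                  eps: float) -> list[int]:
    """Adjacent-transposition hill climb on the chain likelihood."""
    improved = True
    X = origins.T
    best_ll = chain.loglik(X[:, order], _interval_R(order, R2), eps)
    while improved:
        improved = False
        for i in range(len(order) - 1):
            trial = order.copy()
            trial[i], trial[i + 1] = trial[i + 1], trial[i]
            ll = chain.loglik(X[:, trial], _interval_R(trial, R2), eps)
            if ll > best_ll + 1e-9:
                order, best_ll, improved = trial, ll, True
    return order


def _build_one(
    seed: int,
    origins: np.ndarray,
    R2: np.ndarray,
    candidates: np.ndarray,
    mapf: MapFunction,
    min_spacing_cm: float,
    score_threshold: float,
    eps: float,
    link_max_cm: float = 30.0,
) -> OrderedMap:
    """Grow one scaffold replicate outward from a seed marker.

    Admissible candidates sit between ``min_spacing_cm`` and
    ``link_max_cm`` (two-point) of their nearest scaffold member, so the
    map grows by tightly-linked steps and insertion margins stay
    informative.  Nearest candidates are tried first; rejected ones are
    retried after the scaffold has grown.
    """
    X = origins.T  # lines x markers
    min_R = mapf.R_of_cm(min_spacing_cm)
    max_R = mapf.R_of_cm(link_max_cm)
    info_rank = {int(m): k for k, m in enumerate(candidates)}
    order: list[int] = [seed]
    while True:
        near = {}
        for c in candidates:
            c = int(c)
            if c in order:
                continue
            rmin = np.nanmin(R2[c, order])
            if min_R <= rmin <= max_R:
                near[c] = rmin
        accepted = False
        for c in sorted(near, key=lambda c: (near[c], info_rank[c])):
            lls: dict[tuple[int, ...], float] = {}
            for slot in range(len(order) + 1):
                trial = order[:slot] + [c] + order[slot:]
                key = _canonical(tuple(trial))
                if key in lls:
                    continue
                lls[key] = chain.loglik(X[:, trial], _interval_R(trial, R2), eps)
            ranked = sorted(lls.items(), key=lambda kv: -kv[1])
            if len(ranked) > 1:
                margin = (ranked[0][1] - ranked[1][1]) / _LN10
            else:
                margin = np.inf
            if margin < score_threshold:
                continue
            order = _local_polish(list(ranked[0][0]), origins, R2, eps)
            accepted = True
            break
        if not accepted:
            break
    R, eps_fit, ll = chain.fit_intervals(
        X[:, order], R0=_interval_R(order, R2), eps=eps, tol=1e-6)
    return OrderedMap(idx=order, R=R, eps=eps_fit, loglik=ll)


def reconcile_replicates(
    replicates: list[OrderedMap],
    origins: np.ndarray,
    R2: np.ndarray,
    info_rank: dict[int, int],
    eps: float,
) -> OrderedMap:
    """Keep the best replicate's markers whose order all replicates support."""
    best = max(replicates, key=lambda m: (m.size, m.loglik))
    keep = list(best.idx)

    def conflict_counts(members: list[int]) -> dict[int, int]:
        pos = {m: i for i, m in enumerate(members)}
        counts = {m: 0 for m in members}
        for rep in replicates:
            if rep is best:
                continue
            shared = [m for m in rep.idx if m in pos]
            if len(shared) < 2:
                continue
            rb = [pos[m] for m in shared]
            tau = kendalltau(rb, list(range(len(shared)))).statistic
            if tau is not None and tau < 0:
                shared = shared[::-1]
                rb = [pos[m] for m in shared]
            for i in range(len(shared)):
                for j in range(i + 1, len(shared)):
                    if rb[i] > rb[j]:
                        counts[shared[i]] += 1
                        counts[shared[j]] += 1
        return counts

    counts = conflict_counts(keep)
    while any(v > 0 for v in counts.values()) and len(keep) > 3:
        worst = max(counts, key=lambda m: (counts[m], info_rank.get(m, 0)))
        keep.remove(worst)
        counts = conflict_counts(keep)

    X = origins.T
    R, eps_fit, ll = chain.fit_intervals(
        X[:, keep], R0=_interval_R(keep, R2), eps=eps, tol=1e-6)
    return OrderedMap(idx=keep, R=R, eps=eps_fit, loglik=ll)


def build_scaffold(
    origins: np.ndarray,
    marker_ids: np.ndarray,
    mapf: MapFunction,
    *,
    min_spacing_cm: float = 10.0,
    score_threshold: float = 3.0,
    n_replicates: int = 10,
    eps: float = 0.005,
    R2: np.ndarray | None = None,
    seeds: list[int] | None = None,
) -> OrderedMap:
    """Replicate-reconciled scaffold for one linkage group."""
    if origins.shape[0] < 3:
        raise ValueError("need at least 3 markers to build a scaffold")
    if R2 is None:
        from .twopoint import pairwise_R
        R2 = pairwise_R(origins)[0]
    info = informativeness_order(origins, marker_ids)
    if seeds is None:
        seeds = pick_seeds(R2, info, n_replicates)
    replicates = [
        _build_one(s, origins, R2, info, mapf,
                   min_spacing_cm, score_threshold, eps)
        for s in seeds
    ]
    info_rank = {int(m): k for k, m in enumerate(info)}
    return reconcile_replicates(replicates, origins, R2, info_rank, eps)
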