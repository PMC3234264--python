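"""Framework extension: densify a scaffold while keeping order robustness.

Candidates are tentatively inserted one at a time (most informative
first).  An insertion is kept only when the chosen order's
log10-likelihood margin over both the runner-up slot and the best local
permutation (window of 3 adjacent markers around the insertion point)
reaches ``robustness_threshold``; interval distances are re-estimated
after each acceptance.
"""

from __future__ import annotations

import numpy as np

from . import chain
from .mapfunc import MapFunction
from .scaffold import OrderedMap, _interval_R, informativeness_order

_LN10 = np.log(10.0)


def _slot_candidates(c: int, order: list[int], R2: np.ndarray,
                     span: int = 2) -> list[int]:
    rc = R2[c, order]
    anchor = int(np.nanargmin(rc))
    lo = max(0, anchor - span + 1)
    hi = min(len(order), anchor + span)
    return list(range(lo, hi + 1))


def _window_permutations(order: list[int], pos: int) -> list[list[int]]:
    """All non-identity orders permuting the 3 markers centered at pos."""
    lo = max(0, min(pos - 1, len(order) - 3))
    window = order[lo:lo + 3]
    out = []
    from itertools import permutations
    for perm in permutations(window):
        if list(perm) == window:
            continue
        out.append(order[:lo] + list(perm) + order[lo + 3:])
    return out


def extend_framework(
    scaffold: OrderedMap,
    origins: np.ndarray,
    marker_ids: np.ndarray,
    mapf: MapFunction,
    *,
    robustness_threshold: float = 3.0,
    eps: float = 0.005,
    R2: np.ndarray | None = None,
    em_iter_per_accept: int = 4,
) -> OrderedMap:
    """Insert as many markers as possible into the scaffold order."""
    if R2 is None:
        from .twopoint import pairwise_R
        R2 = pairwise_R(origins)[0]
    X = origins.T
    order = list(scaffold.idx)
    R = np.asarray(scaffold.R, dtype=float)
    eps_cur = scaffold.eps if scaffold.eps else eps

    def ll_of(trial: list[int]) -> float:
        return chain.loglik(X[:, trial], _interval_R(trial, R2), eps_cur)

    candidates = [int(c) for c in informativeness_order(origins, marker_ids)
                  if int(c) not in order]
    for c in candidates:
        if np.isnan(R2[c, order]).all():
            continue
        slots = _slot_candidates(c, order, R2)
        scored = []
        for slot in slots:
            trial = order[:slot] + [c] + order[slot:]
            scored.append((ll_of(trial), slot))
        scored.sort(reverse=True)
        best_ll, best_slot = scored[0]
        slot_margin = ((best_ll - scored[1][0]) / _LN10
                       if len(scored) > 1 else np.inf)
        if slot_margin < robustness_threshold:
            continue
        new_order = order[:best_slot] + [c] + order[best_slot:]
        perm_lls = [ll_of(p) for p in _window_permutations(new_order, best_slot)]
        perm_margin = ((best_ll - max(perm_lls)) / _LN10
                       if perm_lls else np.inf)
        if perm_margin < robustness_threshold:
            continue
        order = new_order
        R, eps_cur, _ = chain.fit_intervals(
            X[:, order], R0=_interval_R(order, R2), eps=eps_cur,
            tol=1e-4, max_iter=em_iter_per_accept)

    R, eps_fit, ll = chain.fit_intervals(
        X[:, order], R0=_interval_R(order, R2), eps=eps_cur, tol=1e-6)
    return OrderedMap(idx=order, R=R, eps=eps_fit, loglik=ll)
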