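"""Bin-placement of markers onto fixed framework maps.

A candidate marker is never inserted into the framework order; instead
its genotypes are scored against every framework interval (plus the two
terminal half-open intervals) using the chain forward/backward messages,
and it is assigned the maximum-likelihood interval with a point position
found by 1-D likelihood maximization inside it.  The placement score is
the log10 likelihood ratio of the best over the second-best interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import chain
from .mapfunc import MapFunction
from .scaffold import OrderedMap

_LN10 = np.log(10.0)
_MAX_END_CM = 100.0


@dataclass
class IntervalScore:
    slot: int          # 0 = before first marker, K = after last
    loglik: float
    offset_cm: float   # distance from the left edge of the interval


@dataclass
class Placement:
    marker: str
    chrom: str | None
    mapped: bool
    cm: float = np.nan
    pseudo_cm: float = np.nan
    score: float = np.nan       # log10 LR best vs second-best interval
    delta_ll: float = np.nan    # gain over the bare framework likelihood
    slot: int = -1


class FrameworkMessages:
    """Cached forward/backward messages of a framework chromosome."""

    def __init__(self, Xf: np.ndarray, fw: OrderedMap, mapf: MapFunction):
        self.fw = fw
        self.mapf = mapf
        R = np.clip(fw.R, 1e-7, 0.5 - 1e-7)
        eps = fw.eps
        self.eps = eps
        alpha, scale_log, self.loglik = chain.forward(Xf, R, eps)
        self.alpha = alpha
        self.Sa = np.cumsum(scale_log, axis=1)
        e = chain._emissions(Xf, eps)
        n, K = Xf.shape
        beta = np.empty((n, K, 2))
        Sb = np.zeros((n, K))
        beta[:, K - 1, :] = 1.0
        for k in range(K - 2, -1, -1):
            b0 = e[:, k + 1, 0] * beta[:, k + 1, 0]
            b1 = e[:, k + 1, 1] * beta[:, k + 1, 1]
            nb0 = (1 - R[k]) * b0 + R[k] * b1
            nb1 = R[k] * b0 + (1 - R[k]) * b1
            c = nb0 + nb1
            beta[:, k, 0] = nb0 / c
            beta[:, k, 1] = nb1 / c
            Sb[:, k] = Sb[:, k + 1] + np.log(c)
        self.beta = beta
        self.Sb = Sb
        self.e = e
        self.K = K
        self.cm = fw.cm_positions(mapf)
        self.pseudo_cm = fw.pseudo_cm_positions(mapf)

    def _em(self, y: np.ndarray) -> np.ndarray:
        eps = self.eps
        em = np.empty((y.size, 2))
        em[:, 0] = np.where(y == -1, 1.0, np.where(y == 0, 1.0 - eps, eps))
        em[:, 1] = np.where(y == -1, 1.0, np.where(y == 1, 1.0 - eps, eps))
        return em

    def _slot_loglik(self, y_em: np.ndarray, slot: int,
                     Ra: float, Rb: float) -> float:
        """Chain loglik with the candidate between slot-1 and slot."""
        K = self.K
        if slot == 0:
            G = self.e[:, 0, :] * self.beta[:, 0, :]
            inner0 = (1 - Ra) * G[:, 0] + Ra * G[:, 1]
            inner1 = Ra * G[:, 0] + (1 - Ra) * G[:, 1]
            L = 0.5 * (y_em[:, 0] * inner0 + y_em[:, 1] * inner1)
            return float((np.log(L) + self.Sb[:, 0]).sum())
        if slot == K:
            a = self.alpha[:, K - 1, :]
            t0 = a[:, 0] * (1 - Ra) + a[:, 1] * Ra
            t1 = a[:, 0] * Ra + a[:, 1] * (1 - Ra)
            L = t0 * y_em[:, 0] + t1 * y_em[:, 1]
            return float((np.log(L) + self.Sa[:, K - 1]).sum())
        k = slot - 1
        G = self.e[:, k + 1, :] * self.beta[:, k + 1, :]
        inner0 = (1 - Rb) * G[:, 0] + Rb * G[:, 1]
        inner1 = Rb * G[:, 0] + (1 - Rb) * G[:, 1]
        mid0 = y_em[:, 0] * inner0
        mid1 = y_em[:, 1] * inner1
        a = self.alpha[:, k, :]
        L = (a[:, 0] * ((1 - Ra) * mid0 + Ra * mid1)
             + a[:, 1] * (Ra * mid0 + (1 - Ra) * mid1))
        return float((np.log(L) + self.Sa[:, k] + self.Sb[:, k + 1]).sum())

    def _optimize_slot(self, y_em: np.ndarray, slot: int) -> IntervalScore:
        mapf = self.mapf
        if slot == 0 or slot == self.K:
            def neg(d_cm):
                Re = mapf.R_of_cm(float(d_cm))
                return -self._slot_loglik(y_em, slot, Re, 0.0)
            res = minimize_scalar(neg, bounds=(0.0, _MAX_END_CM),
                                  method="bounded", options={"xatol": 1e-3})
            return IntervalScore(slot, -float(res.fun), float(res.x))
        d_k = self.cm[slot] - self.cm[slot - 1]
        if d_k <= 1e-9:
            mid = self._slot_loglik(y_em, slot, 0.0, 0.0)
            return IntervalScore(slot, mid, 0.0)

        def neg(f):
            Ra = mapf.R_of_cm(float(f) * d_k)
            Rb = mapf.R_of_cm((1.0 - float(f)) * d_k)
            return -self._slot_loglik(y_em, slot, Ra, Rb)
        res = minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-3})
        return IntervalScore(slot, -float(res.fun), float(res.x) * d_k)

    def score_marker(self, y: np.ndarray, refine_top: int = 4) -> list[IntervalScore]:
        """Per-slot log-likelihoods: a cheap midpoint scan of every slot,
        then exact 1-D optimization of the ``refine_top`` best slots."""
        y_em = self._em(y)
        mapf = self.mapf
        rough: list[IntervalScore] = []
        for slot in range(self.K + 1):
            if slot == 0 or slot == self.K:
                Re = mapf.R_of_cm(2.0)
                rough.append(IntervalScore(
                    slot, self._slot_loglik(y_em, slot, Re, 0.0), 2.0))
            else:
                d_k = self.cm[slot] - self.cm[slot - 1]
                Ra = mapf.R_of_cm(0.5 * d_k)
                rough.append(IntervalScore(
                    slot, self._slot_loglik(y_em, slot, Ra, Ra), 0.5 * d_k))
        rough.sort(key=lambda s: -s.loglik)
        refined = {s.slot: self._optimize_slot(y_em, s.slot)
                   for s in rough[:refine_top]}
        out = [refined.get(s.slot, s) for s in rough]
        out.sort(key=lambda s: -s.loglik)
        return out

    def position_of(self, score: IntervalScore) -> tuple[float, float]:
        """(cm, pseudo_cm) of a scored slot."""
        mapf = self.mapf
        if score.slot == 0:
            pseudo_off = mapf.pseudo.cm(mapf.R_of_cm(score.offset_cm))
            return self.cm[0] - score.offset_cm, self.pseudo_cm[0] - pseudo_off
        if score.slot == self.K:
            pseudo_off = mapf.pseudo.cm(mapf.R_of_cm(score.offset_cm))
            return self.cm[-1] + score.offset_cm, self.pseudo_cm[-1] + pseudo_off
        k = score.slot - 1
        d_k = self.cm[k + 1] - self.cm[k]
        f = score.offset_cm / d_k if d_k > 0 else 0.0
        pseudo = self.pseudo_cm[k] + f * (self.pseudo_cm[k + 1] - self.pseudo_cm[k])
        return self.cm[k] + score.offset_cm, pseudo


def place_bins(
    frameworks: dict[str, FrameworkMessages],
    candidates: dict[str, np.ndarray],
    *,
    min_score: float = 0.5,
    min_informative: int = 10,
) -> list[Placement]:
    """Place each candidate marker onto its best framework interval.

    A marker is reported unmapped when it has fewer than
    ``min_informative`` non-missing calls or when its best-interval margin
    is below ``min_score`` on every chromosome.
    """
    out: list[Placement] = []
    for marker, y in candidates.items():
        y = np.asarray(y, dtype=np.int8)
        if (y != -1).sum() < min_informative:
            out.append(Placement(marker, None, mapped=False))
            continue
        best: tuple[float, str, IntervalScore, float] | None = None
        for chrom, msg in frameworks.items():
            scores = msg.score_marker(y)
            scores.sort(key=lambda s: -s.loglik)
            margin = ((scores[0].loglik - scores[1].loglik) / _LN10
                      if len(scores) > 1 else np.inf)
            if margin < min_score:
                continue
            delta = scores[0].loglik - msg.loglik
            if best is None or delta > best[0]:
                best = (delta, chrom, scores[0], margin)
        if best is None:
            out.append(Placement(marker, None, mapped=False))
            continue
        delta, chrom, top, margin = best
        cm, pseudo = frameworks[chrom].position_of(top)
        out.append(Placement(marker, chrom, mapped=True, cm=cm,
                             pseudo_cm=pseudo, score=margin,
                             delta_ll=delta, slot=top.slot))
    return out
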