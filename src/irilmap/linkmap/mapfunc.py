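"""Conversions between meiotic recombination fraction r, line-level
recombinant fraction R and map distance d (cM) for intermated RILs.

For a population derived from an F2 by ``t`` generations of random
intermating (infinite-population approximation) followed by selfing to
fixation, the fixed-line recombinant fraction for two loci at meiotic
recombination fraction ``r`` is::

    R(r, t) = 0.5 * (1 - (1 - r)**t * (1 - 2 r) / (1 + 2 r))

``t = 0`` reduces to the classic selfed-RIL form ``R = 2 r / (1 + 2 r)``.
Map distances are Haldane: ``d = -50 ln(1 - 2 r)``.  The *pseudo-cM*
scale converts R back to distance with ``t`` forced to 0, i.e. as if the
lines were plain RILs; it systematically overestimates d when t > 0.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

_EPS = 1e-12


def haldane_cm_from_r(r):
    """Haldane map distance (cM) from meiotic recombination fraction."""
    r = np.asarray(r, dtype=float)
    out = np.where(r >= 0.5 - _EPS, np.inf, -50.0 * np.log(1.0 - 2.0 * np.minimum(r, 0.5 - _EPS)))
    return out if out.ndim else float(out)


def haldane_r_from_cm(d):
    """Meiotic recombination fraction from Haldane map distance (cM)."""
    d = np.asarray(d, dtype=float)
    out = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return out if out.ndim else float(out)


def R_from_r(r, t: int):
    """Line-level recombinant fraction after t intermating rounds + fixation."""
    if t < 0:
        raise ValueError("t must be >= 0")
    r = np.asarray(r, dtype=float)
    if ((r < 0) | (r > 0.5)).any():
        raise ValueError("r must lie in [0, 0.5]")
    out = 0.5 * (1.0 - (1.0 - r) ** t * (1.0 - 2.0 * r) / (1.0 + 2.0 * r))
    return out if out.ndim else float(out)


def r_from_R(R, t: int):
    """Invert :func:`R_from_r` by monotone root finding."""
    if t < 0:
        raise ValueError("t must be >= 0")
    scalar = np.isscalar(R)
    R_arr = np.atleast_1d(np.asarray(R, dtype=float))
    if ((R_arr < 0) | (R_arr > 0.5 + 1e-12)).any():
        raise ValueError("R must lie in [0, 0.5]")
    out = np.empty_like(R_arr)
    for i, Ri in enumerate(R_arr):
        if Ri <= _EPS:
            out[i] = 0.0
        elif Ri >= 0.5 - _EPS:
            out[i] = 0.5
        else:
            out[i] = brentq(lambda r: R_from_r(r, t) - Ri, 0.0, 0.5,
                            xtol=1e-14, rtol=8.9e-16)
    return float(out[0]) if scalar else out


def cm_from_R(R, t: int):
    """Map distance in cM from a line-level recombinant fraction.

    ``R >= 0.5`` maps to infinity (unlinked); callers must handle it.
    """
    return haldane_cm_from_r(r_from_R(R, t))


def R_from_cm(d, t: int):
    return R_from_r(haldane_r_from_cm(d), t)


class MapFunction:
    """Bundled r/R/d conversions at a fixed intermating depth ``t``.

    ``pseudo`` is the same object with t forced to 0 (plain-RIL algebra),
    used for the pseudo-cM coordinate columns.
    """

    def __init__(self, t: int):
        if t < 0:
            raise ValueError("t must be >= 0")
        self.t = int(t)

    def R(self, r):
        return R_from_r(r, self.t)

    def r(self, R):
        return r_from_R(R, self.t)

    def cm(self, R):
        return cm_from_R(R, self.t)

    def R_of_cm(self, d):
        return R_from_cm(d, self.t)

    @property
    def pseudo(self) -> "MapFunction":
        return MapFunction(0)
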