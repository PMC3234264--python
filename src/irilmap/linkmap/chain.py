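"""Line-level chain likelihood for a fixed marker order.

Each line's parental-origin sequence along an ordered set of markers is
modelled as a two-state Markov chain: between adjacent markers ``k`` and
``k+1`` the origin flips with the interval's line-level recombinant
probability ``R_k``.  Observations are the origin-coded genotypes
(0 = parent 1, 1 = parent 2, -1 = missing) with a symmetric genotyping
error probability ``eps`` in the emission; missing calls are
marginalized.  Interval probabilities are estimated by Baum-Welch EM.

Genotype matrices are passed lines x markers (``X``) in map order.
"""

from __future__ import annotations

import numpy as np

_RMIN = 1e-7
_RMAX = 0.5 - 1e-7


def _emissions(X: np.ndarray, eps: float) -> np.ndarray:
    """Emission probabilities, shape (n_lines, K, 2)."""
    e = np.empty(X.shape + (2,), dtype=float)
    e[:, :, 0] = np.where(X == -1, 1.0, np.where(X == 0, 1.0 - eps, eps))
    e[:, :, 1] = np.where(X == -1, 1.0, np.where(X == 1, 1.0 - eps, eps))
    return e


def forward(X: np.ndarray, R: np.ndarray, eps: float):
    """Scaled forward pass.

    Returns (alpha, scale_log, loglik) where ``alpha[:, k, :]`` is the
    normalized state posterior-prefix and ``scale_log[:, k]`` the log of
    the per-step normalizer.
    """
    n, K = X.shape
    e = _emissions(X, eps)
    alpha = np.empty((n, K, 2))
    scale_log = np.empty((n, K))
    a = 0.5 * e[:, 0, :]
    c = a.sum(axis=1)
    scale_log[:, 0] = np.log(c)
    alpha[:, 0, :] = a / c[:, None]
    for k in range(1, K):
        prev = alpha[:, k - 1, :]
        Rk = R[k - 1]
        trans0 = prev[:, 0] * (1 - Rk) + prev[:, 1] * Rk
        trans1 = prev[:, 0] * Rk + prev[:, 1] * (1 - Rk)
        a0 = trans0 * e[:, k, 0]
        a1 = trans1 * e[:, k, 1]
        c = a0 + a1
        scale_log[:, k] = np.log(c)
        alpha[:, k, 0] = a0 / c
        alpha[:, k, 1] = a1 / c
    return alpha, scale_log, float(scale_log.sum())


def loglik(X: np.ndarray, R: np.ndarray, eps: float) -> float:
    """Total log-likelihood of the order with interval probabilities R."""
    n, K = X.shape
    e = _emissions(X, eps)
    a = 0.5 * e[:, 0, :]
    c = a.sum(axis=1)
    ll = np.log(c)
    a /= c[:, None]
    for k in range(1, K):
        Rk = R[k - 1]
        t0 = a[:, 0] * (1 - Rk) + a[:, 1] * Rk
        t1 = a[:, 0] * Rk + a[:, 1] * (1 - Rk)
        a0 = t0 * e[:, k, 0]
        a1 = t1 * e[:, k, 1]
        c = a0 + a1
        ll += np.log(c)
        a[:, 0] = a0 / c
        a[:, 1] = a1 / c
    if not np.isfinite(ll).all():
        raise FloatingPointError("non-finite chain likelihood")
    return float(ll.sum())


def backward(X: np.ndarray, R: np.ndarray, eps: float) -> np.ndarray:
    """Scaled backward pass; ``beta[:, k, :]`` normalized per step."""
    n, K = X.shape
    e = _emissions(X, eps)
    beta = np.empty((n, K, 2))
    beta[:, K - 1, :] = 1.0
    for k in range(K - 2, -1, -1):
        Rk = R[k]
        b0 = e[:, k + 1, 0] * beta[:, k + 1, 0]
        b1 = e[:, k + 1, 1] * beta[:, k + 1, 1]
        beta[:, k, 0] = (1 - Rk) * b0 + Rk * b1
        beta[:, k, 1] = Rk * b0 + (1 - Rk) * b1
        norm = beta[:, k, :].sum(axis=1)
        beta[:, k, :] /= norm[:, None]
    return beta


def fit_intervals(
    X: np.ndarray,
    R0: np.ndarray | None = None,
    eps: float = 0.005,
    estimate_eps: bool = False,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, float, float]:
    """Baum-Welch estimation of per-interval recombinant probabilities.

    Returns (R, eps, loglik) at convergence (|delta loglik| < tol).
    """
    n, K = X.shape
    if K < 2:
        return np.empty(0), eps, loglik(X, np.empty(0), eps) if K else 0.0
    R = np.full(K - 1, 0.1) if R0 is None else np.clip(
        np.asarray(R0, dtype=float), _RMIN, _RMAX)
    prev_ll = -np.inf
    for _ in range(max_iter):
        e = _emissions(X, eps)
        alpha, scale_log, ll = forward(X, R, eps)
        beta = backward(X, R, eps)

        newR = np.empty_like(R)
        for k in range(K - 1):
            Rk = R[k]
            a = alpha[:, k, :]
            b = e[:, k + 1, :] * beta[:, k + 1, :]
            # xi(z, z') ~ alpha_k(z) T(z,z') e_{k+1}(z') beta_{k+1}(z')
            same = a[:, 0] * (1 - Rk) * b[:, 0] + a[:, 1] * (1 - Rk) * b[:, 1]
            flip = a[:, 0] * Rk * b[:, 1] + a[:, 1] * Rk * b[:, 0]
            p_flip = flip / (same + flip)
            newR[k] = p_flip.mean()
        R = np.clip(newR, _RMIN, _RMAX)

        if estimate_eps:
            gamma = alpha * beta
            gamma /= gamma.sum(axis=2, keepdims=True)
            obs = X != -1
            mismatch = np.zeros(())
            total = obs.sum()
            m0 = (X == 1) & obs
            m1 = (X == 0) & obs
            mismatch = gamma[:, :, 0][m0].sum() + gamma[:, :, 1][m1].sum()
            eps = float(np.clip(mismatch / max(total, 1), 1e-6, 0.2))

        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return R, eps, loglik(X, R, eps)
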