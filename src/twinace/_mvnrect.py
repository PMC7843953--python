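"""Deterministic quasi-Monte-Carlo rectangle probabilities for MVN, d >= 3.

Genz's sequential-conditioning transformation of the multivariate normal
rectangle integral, evaluated on a fixed Richtmyer (Kronecker) lattice so
repeated calls are bit-identical.  The implementation is vectorized across
many rectangles that share one correlation matrix — the layout produced by
liability-threshold twin models, where each zygosity group contributes one
correlation matrix and as many rectangles as observed response patterns.

Accuracy with the default 1 << 11 antithetic lattice points is ~1e-6 for
the 3-6 dimensional integrals used here (checked against scipy's
integrator in the test suite).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["mvn_rect_probs"]

_SQRT_PRIMES = np.sqrt(np.array([2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37], float))
_EPS = 1e-14


def _lattice(n_points: int, dim: int) -> np.ndarray:
    """Richtmyer lattice in [0,1)^dim with antithetic reflection."""
    k = np.arange(1, n_points + 1)[:, None]
    w = np.mod(k * _SQRT_PRIMES[None, :dim], 1.0)
    return np.vstack([w, 1.0 - w])


def _rect_probs_ordered(lower, upper, corr, n_points) -> np.ndarray:
    """Sequential-conditioning QMC for rectangles sharing one variable order."""
    n_rect, d = lower.shape
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(d))

    w = _lattice(n_points, d - 1)  # (m, d-1)
    m = w.shape[0]

    # first dimension: closed form
    e = ndtr(upper[:, 0] / L[0, 0])  # (n_rect,)
    f0 = ndtr(lower[:, 0] / L[0, 0])
    prob = np.broadcast_to((e - f0)[None, :], (m, n_rect)).copy()  # running product
    dlo = np.broadcast_to(f0[None, :], (m, n_rect)).copy()
    dhi = np.broadcast_to(e[None, :], (m, n_rect)).copy()

    y = np.empty((m, n_rect, d - 1))
    for i in range(1, d):
        u = np.clip(dlo + w[:, i - 1][:, None] * (dhi - dlo), _EPS, 1 - _EPS)
        y[:, :, i - 1] = ndtri(u)
        shift = np.tensordot(y[:, :, :i], L[i, :i], axes=([2], [0]))  # (m, n_rect)
        dhi = ndtr((upper[:, i][None, :] - shift) / L[i, i])
        dlo = ndtr((lower[:, i][None, :] - shift) / L[i, i])
        prob *= np.maximum(dhi - dlo, 0.0)

    return np.clip(prob.mean(axis=0), 0.0, 1.0)


def mvn_rect_probs(
    lower: np.ndarray,
    upper: np.ndarray,
    corr: np.ndarray,
    n_points: int = 1 << 11,
) -> np.ndarray:
    """P(lower < Z <= upper) for N(0, corr), vectorized over rectangles.

    ``lower``/``upper`` are (n_rect, d); ``corr`` is (d, d).  Infinite
    bounds are allowed.  Each rectangle is integrated with its most
    constrained dimension first (that factor is then exact), which keeps
    the *relative* error of rare-pattern probabilities small; rectangles
    sharing a variable ordering are processed as one vectorized batch.
    """
    lower = np.atleast_2d(np.asarray(lower, float))
    upper = np.atleast_2d(np.asarray(upper, float))
    n_rect, d = lower.shape
    # marginal interval mass per dimension; integrate smallest first
    mass = ndtr(upper) - ndtr(lower)
    orders = np.argsort(mass, axis=1, kind="stable")
    out = np.empty(n_rect)
    uniq, inv = np.unique(orders, axis=0, return_inverse=True)
    for g, order in enumerate(uniq):
        rows = np.flatnonzero(inv == g)
        out[rows] = _rect_probs_ordered(
            lower[np.ix_(rows, order)],
            upper[np.ix_(rows, order)],
            corr[np.ix_(order, order)],
            n_points,
        )
    return out
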