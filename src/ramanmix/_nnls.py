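"""Exact non-negative least squares for many right-hand sides, small p.

Solves min_x ||A x - b||^2 subject to x >= 0 for every column b of B, given
only the Gram quantities G = A^T A (p x p) and H = A^T B (p x N).  For the
ranks used in unmixing (p <= ~10) the optimum is found exactly by enumerating
active sets and checking the KKT conditions, fully vectorized over columns;
columns that no candidate satisfies (near-degenerate G) fall back to
scipy's Lawson-Hanson solver through a Cholesky square root.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import linalg as sla
from scipy.optimize import nnls as _scipy_nnls

__all__ = ["nnls_gram", "nnls_columns"]

_MAX_ENUM_P = 12


def nnls_gram(G: np.ndarray, H: np.ndarray, A=None, B=None) -> np.ndarray:
    """Return X (p x N) minimizing x'Gx - 2x'h, x >= 0, per column h of H.

    When the design matrix ``A`` (m x p) and right-hand sides ``B`` (m x N)
    are also given, the per-active-set solves use a QR factorization of the
    design instead of the Gram system, avoiding the squared condition
    number of the normal equations.
    """
    G = np.asarray(G, dtype=float)
    H = np.asarray(H, dtype=float)
    p, N = H.shape
    if G.shape != (p, p):
        raise ValueError("G must be p x p matching H's row count")
    if p > _MAX_ENUM_P:
        return _fallback_all(G, H)

    hscale = np.maximum(np.abs(H).max(axis=0), 1e-300)
    gscale = max(np.abs(G).max(), 1e-300)
    X = np.zeros((p, N))
    best = np.full(N, np.inf)
    solved = np.zeros(N, dtype=bool)

    # empty active set: x = 0 optimal iff gradient -2h >= 0
    zero_ok = np.all(H <= 1e-12 * hscale, axis=0)
    solved |= zero_ok
    best[zero_ok] = 0.0

    idx = np.arange(p)
    for size in range(1, p + 1):
        for F in combinations(idx, size):
            F = list(F)
            GF = G[np.ix_(F, F)]
            if A is not None:
                Q, R = np.linalg.qr(A[:, F])
                if np.abs(np.diag(R)).min() > 1e-12 * np.abs(R).max():
                    XF = sla.solve_triangular(R, Q.T @ B)
                else:
                    XF, *_ = np.linalg.lstsq(A[:, F], B, rcond=None)
            else:
                try:
                    XF = np.linalg.solve(GF, H[F])
                except np.linalg.LinAlgError:
                    XF, *_ = np.linalg.lstsq(GF, H[F], rcond=None)
            xmax = np.maximum(np.abs(XF).max(axis=0), 1.0)
            feas = XF.min(axis=0) >= -1e-9 * xmax
            grad = G[:, F] @ XF - H  # ~0 on F by construction
            notF = np.setdiff1d(idx, F)
            if notF.size:
                gtol = 1e-10 * (gscale * xmax + hscale)
                opt = grad[notF].min(axis=0) >= -gtol
            else:
                opt = np.ones(N, dtype=bool)
            obj = -np.einsum("fn,fn->n", XF, H[F])  # x'Gx - 2x'h at the solve
            margin = 1e-12 * np.where(np.isfinite(best), np.abs(best), 0.0)
            take = feas & opt & (obj < best - margin)
            if np.any(take):
                X[:, take] = 0.0
                X[np.ix_(F, np.nonzero(take)[0])] = np.clip(XF[:, take], 0.0, None)
                best[take] = obj[take]
                solved |= take

    if not np.all(solved):
        X[:, ~solved] = _fallback_all(G, H[:, ~solved])
    return X


def _fallback_all(G: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Lawson-Hanson per column via a (regularized) Cholesky square root."""
    p = G.shape[0]
    shift = 1e-12 * max(np.trace(G), 1e-300)
    L = sla.cholesky(G + shift * np.eye(p), lower=True)
    A = L.T
    X = np.empty_like(H)
    for j in range(H.shape[1]):
        b = sla.solve_triangular(L, H[:, j], lower=True)
        X[:, j], _ = _scipy_nnls(A, b)
    return X


def nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """NNLS of every column of B against A (m x p); returns X (p x N)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    return nnls_gram(A.T @ A, A.T @ B)
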