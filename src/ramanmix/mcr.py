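"""Multivariate Curve Resolution - Alternating Least Squares.

C and S are optimized alternately under non-negativity in both directions:
the C-step solves an exact non-negative least squares problem per pixel
against the current spectra, the S-step per channel against the current
abundances (active-set solutions, not clipping).  After every S-step the
spectra are scaled to unit Euclidean norm with the abundances rescaled
inversely, leaving the product C S unchanged.  Convergence is monitored by
the lack of fit against a reference matrix: the PCA-filtered data when
``pca_filter`` is on (truncated SVD with the model rank), the raw data
otherwise; the iterate with the best LOF is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._nnls import nnls_gram
from .datamodel import HyperspectralImage, UnmixingResult
from .vca import VcaOptions, vca_extract

__all__ = ["McrOptions", "pca_filter", "purest_variable_init", "mcr_als_fit"]


@dataclass
class McrOptions:
    rank: int
    init: str = "vca"  # vca | purest_variables | user_spectra
    init_spectra: Optional[np.ndarray] = None
    pca_filter: bool = False
    max_iter: int = 50
    tol: float = 0.001  # relative LOF change (0.1%)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.init not in ("vca", "purest_variables", "user_spectra"):
            raise ValueError("init must be vca, purest_variables or user_spectra")
        if self.init == "user_spectra" and self.init_spectra is None:
            raise ValueError("user_spectra init requires init_spectra")


def pca_filter(D: np.ndarray, p: int) -> np.ndarray:
    """Rank-p truncated SVD reconstruction (no mean-centering)."""
    D = np.asarray(D, dtype=float)
    if p > min(D.shape):
        raise ValueError("p exceeds the data dimensions")
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    return (U[:, :p] * s[:p]) @ Vt[:p]


def purest_variable_init(D: np.ndarray, p: int) -> np.ndarray:
    """Deterministic initial spectra: p maximally dissimilar pixel spectra.

    The first pick is the largest-norm pixel (a simplex vertex for exact
    mixtures); each further pick maximizes the Gram determinant of the
    unit-normalized selected spectra (a normalized volume criterion).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if p > n:
        raise ValueError("p exceeds the number of pixels")
    norms = np.linalg.norm(D, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Y = D / safe[:, None]
    chosen = [int(np.argmax(norms))]
    Gfull = Y @ Y.T
    for _ in range(1, p):
        best_j, best_det = None, -np.inf
        sub = np.ix_(chosen, chosen)
        base = Gfull[sub]
        for j in range(n):
            if j in chosen:
                continue
            rows = chosen + [j]
            det = np.linalg.det(Gfull[np.ix_(rows, rows)])
            if det > best_det + 1e-15:
                best_det, best_j = det, j
        chosen.append(best_j)
        del base
    return D[chosen].copy()


def _unit_rows(S: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(S, axis=1)
    return S / np.where(norms > 0, norms, 1.0)[:, None]


def _lof(Dref: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    E = Dref - C @ S
    return 100.0 * float(np.sqrt((E**2).sum() / (Dref**2).sum()))


def mcr_als_fit(D: np.ndarray | HyperspectralImage, opts: McrOptions) -> UnmixingResult:
    """Alternating least squares under non-negativity in both directions.

    ``options['lof_vs_raw']`` always reports the lack of fit against the raw
    data for comparability, regardless of the reference matrix used during
    optimization.
    """
    if isinstance(D, HyperspectralImage):
        D = D.D
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("D must be finite")
    p = opts.rank

    Dw = pca_filter(D, p) if opts.pca_filter else D
    if (Dw**2).sum() <= 0:
        raise ValueError("reference matrix is all zero")

    if opts.init == "vca":
        _, S = vca_extract(D, VcaOptions(rank=p, seed=opts.seed))
    elif opts.init == "purest_variables":
        S = purest_variable_init(D, p)
    else:
        S = np.asarray(opts.init_spectra, dtype=float).copy()
        if S.shape != (p, D.shape[1]):
            raise ValueError("init_spectra must be [p x m]")
    S = _unit_rows(np.clip(S, 0.0, None))

    best = None
    trace = []
    prev_lof = None
    reseeded = set()
    for it in range(1, opts.max_iter + 1):
        # C-step: per-pixel NNLS against current spectra (QR-based solves)
        C = nnls_gram(S @ S.T, S @ Dw.T, A=S.T, B=Dw.T).T
        dead = np.nonzero(C.max(axis=0) <= 0)[0]
        for kdx in dead:
            if kdx in reseeded:
                raise RuntimeError(f"component {kdx} collapsed twice")
            reseeded.add(kdx)
            resid = Dw - C @ S
            S[kdx] = np.clip(resid[int(np.argmax((resid**2).sum(axis=1)))], 0.0, None)
            S = _unit_rows(S)
            C = nnls_gram(S @ S.T, S @ Dw.T, A=S.T, B=Dw.T).T
        # S-step: per-channel NNLS against current abundances
        S = nnls_gram(C.T @ C, C.T @ Dw, A=C, B=Dw)
        dead = np.nonzero(S.max(axis=1) <= 0)[0]
        for kdx in dead:
            if kdx in reseeded:
                raise RuntimeError(f"component {kdx} collapsed twice")
            reseeded.add(kdx)
            resid = Dw - C @ S
            S[kdx] = np.clip(resid[int(np.argmax((resid**2).sum(axis=1)))], 0.0, None)
        norms = np.linalg.norm(S, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        S = S / safe[:, None]
        C = C * safe[None, :]

        lof = _lof(Dw, C, S)
        trace.append((it, lof))
        if best is None or lof < best[2]:
            best = (C.copy(), S.copy(), lof)
        if prev_lof is not None and abs(prev_lof - lof) <= opts.tol * max(prev_lof, 1e-12):
            break
        prev_lof = lof

    C, S, lof = best
    return UnmixingResult(
        method="MCR_ALS", rank=p, S=S, C=C,
        options={"seed": opts.seed, "init": opts.init,
                 "pca_filter": opts.pca_filter, "tol": opts.tol,
                 "lof_vs_reference": lof, "lof_vs_raw": _lof(D, C, S),
                 "iterations": len(trace)},
        trace=trace,
    )
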