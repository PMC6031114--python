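"""Vertex Component Analysis: sequential endmember extraction.

VCA assumes every pixel spectrum lies in the simplex spanned by a small set
of pure-component spectra (endmembers) and that for each component at least
one pure pixel exists.  Endmembers are found one at a time: the data are
projected onto a signal subspace, a random direction is orthogonalized
against the span of the endmembers found so far, and the pixel with the
largest absolute projection onto that direction is the next vertex.
Selected endmember spectra are actual pixel spectra of the input.
Abundances are estimated per pixel under non-negativity and closure (each
row of C sums to one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._nnls import nnls_gram
from .datamodel import HyperspectralImage, UnmixingResult

__all__ = ["VcaOptions", "vca_extract", "vca_abundances", "run_vca"]


@dataclass
class VcaOptions:
    rank: int
    seed: int = 0
    snr_db: Optional[float] = None  # auto-estimated when None
    abundance_mode: str = "nnls_closure"  # or "closure_only"

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.abundance_mode not in ("nnls_closure", "closure_only"):
            raise ValueError("abundance_mode must be nnls_closure or closure_only")


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| component positive."""
    out = U.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def estimate_snr_db(R: np.ndarray, p: int) -> float:
    """SNR estimate (dB) from the energy captured by the top-p subspace.

    ``R`` is channels x pixels.  Compares the total power with the power of
    the mean-removed projection onto the top-p singular subspace.
    """
    m, n = R.shape
    r_m = R.mean(axis=1, keepdims=True)
    R0 = R - r_m
    U, _, _ = np.linalg.svd(R0, full_matrices=False)
    x = U[:, :p].T @ R0
    p_y = float((R**2).sum()) / n
    p_x = float((x**2).sum()) / n + float((r_m**2).sum())
    denom = p_y - p_x
    if denom <= 0:
        return np.inf
    ratio = (p_x - (p / m) * p_y) / denom
    if ratio <= 0:
        return -np.inf
    return 10.0 * np.log10(ratio)


def _project(D: np.ndarray, p: int, snr_db: float):
    """Signal-subspace coordinates Y (p x n) used for vertex seeking.

    Above the SNR threshold 15 + 10 log10(p) dB: project onto the top-p
    right singular subspace of the raw data with projective scaling.  Below:
    mean-center, keep p-1 components, append a constant coordinate.
    """
    R = D.T  # channels x pixels
    snr_th = 15.0 + 10.0 * np.log10(p)
    if snr_db > snr_th:
        U, _, _ = np.linalg.svd(R, full_matrices=False)
        Ud = _fix_signs(U[:, :p])
        x = Ud.T @ R
        u = x.mean(axis=1, keepdims=True)
        denom = (x * u).sum(axis=0)
        tiny = 1e-12 * max(np.abs(denom).max(), 1.0)
        denom = np.where(np.abs(denom) < tiny, tiny, denom)
        Y = x / denom
    else:
        r_m = R.mean(axis=1, keepdims=True)
        U, _, _ = np.linalg.svd(R - r_m, full_matrices=False)
        d = max(p - 1, 1)
        Ud = _fix_signs(U[:, :d])
        x = Ud.T @ (R - r_m)
        c = float(np.sqrt((x**2).sum(axis=0)).max())
        Y = np.vstack([x, np.full((1, x.shape[1]), c if c > 0 else 1.0)])
    return Y


def vca_extract(D: np.ndarray, opts: VcaOptions):
    """Select p pure-pixel indices and their spectra.

    Returns ``(indices, S)`` where ``S`` rows are the selected pixels'
    spectra (rows of ``D``), so non-negative input yields non-negative
    endmembers.
    """
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("D must be finite")
    n, m = D.shape
    p = opts.rank
    if p > min(n, m):
        raise ValueError("rank exceeds data dimensions")
    rng = np.random.default_rng(opts.seed)
    if p == 1:
        # single endmember: pixel with the largest projection onto the
        # leading singular direction
        U, _, _ = np.linalg.svd(D.T, full_matrices=False)
        x = _fix_signs(U[:, :1]).T @ D.T
        idx = int(np.argmax(np.abs(x)))
        return [idx], D[[idx]].copy()

    snr_db = opts.snr_db if opts.snr_db is not None else estimate_snr_db(D.T, p)
    Y = _project(D, p, snr_db)

    A = np.zeros((p, p))
    A[-1, 0] = 1.0
    indices: list[int] = []
    for i in range(p):
        for _ in range(100):
            w = rng.standard_normal(p)
            f = w - A @ (np.linalg.pinv(A) @ w)
            nf = float(np.linalg.norm(f))
            if nf < 1e-12:
                continue
            f /= nf
            v = f @ Y
            j = int(np.argmax(np.abs(v)))  # ties -> lowest pixel index
            if j not in indices:
                break
        else:
            raise RuntimeError("VCA failed to find a new vertex in 100 redraws")
        indices.append(j)
        A[:, i] = Y[:, j]
    return indices, D[indices].copy()


def vca_abundances(D: np.ndarray, S: np.ndarray, mode: str = "nnls_closure"):
    """Per-pixel abundances under the closure constraint.

    ``nnls_closure``: non-negative least squares then renormalization to
    unit row sum (rows summing to zero get a uniform 1/p row and a flag).
    ``closure_only``: equality-constrained least squares with sum-to-one.
    Returns ``(C, flagged_pixel_indices)``.
    """
    D = np.asarray(D, dtype=float)
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    G = S @ S.T
    cond = np.linalg.cond(G)
    if cond > 1e12:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.nan_to_num(np.corrcoef(S))
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"endmember spectra are rank deficient (cond {cond:.2e}); "
            f"most correlated pair: ({i}, {j})"
        )
    H = S @ D.T
    flagged: list[int] = []
    if mode == "nnls_closure":
        C = nnls_gram(G, H).T
        sums = C.sum(axis=1)
        zero = sums <= 1e-300
        if np.any(zero):
            flagged = list(np.nonzero(zero)[0])
            C[zero] = 1.0 / p
            sums[zero] = 1.0
        C = C / sums[:, None]
    elif mode == "closure_only":
        K = np.zeros((p + 1, p + 1))
        K[:p, :p] = 2.0 * G
        K[:p, p] = 1.0
        K[p, :p] = 1.0
        rhs = np.vstack([2.0 * H, np.ones((1, D.shape[0]))])
        sol = np.linalg.solve(K, rhs)
        C = sol[:p].T
    else:
        raise ValueError(f"unknown abundance mode {mode!r}")
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite abundances")
    return C, flagged


def run_vca(img: HyperspectralImage | np.ndarray, opts: VcaOptions) -> UnmixingResult:
    """Full VCA: extraction + closure-constrained abundances."""
    D = img.D if isinstance(img, HyperspectralImage) else np.asarray(img, float)
    indices, S = vca_extract(D, opts)
    C, flagged = vca_abundances(D, S, opts.abundance_mode)
    if opts.abundance_mode == "closure_only":
        C = np.clip(C, 0.0, None)  # closure-only solutions can dip below zero
        C = C / C.sum(axis=1, keepdims=True)
    cost = float(((D - C @ S) ** 2).sum())
    return UnmixingResult(
        method="VCA", rank=opts.rank, S=S, C=C,
        options={"seed": opts.seed, "indices": list(map(int, indices)),
                 "abundance_mode": opts.abundance_mode,
                 "flagged_pixels": flagged,
                 "require_nonneg_S": bool(D.min() >= 0),
                 "snr_db": opts.snr_db if opts.snr_db is not None else "auto"},
        trace=[(0, cost)],
    )
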