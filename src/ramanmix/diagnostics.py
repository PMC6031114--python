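"""Model statistics and cross-method comparison.

Lack of fit and explained variance of a bilinear model are computed from the
same residual matrix E = D_ref - C S:

    LOF (%) = 100 * sqrt( sum(E^2) / sum(D_ref^2) )
    r^2 (%) = 100 * ( 1 - sum(E^2) / sum(D_ref^2) )

so r^2 = 100 - LOF^2 / 100 holds identically.  Endmembers from different
methods are matched by the permutation maximizing total spectral Pearson
correlation (exhaustive for p <= 8), with abundance-map correlation as the
tie-breaker.  A singular-value scree suggests the model rank, and two small
presentation rules (min-max map scaling, band normalization) mirror the way
abundance maps and endmember spectra are conventionally displayed.
"""

from __future__ import annotations

import warnings
from itertools import permutations

import numpy as np

from .datamodel import DiagnosticsReport, SpectralAxis, UnmixingResult

__all__ = [
    "lack_of_fit",
    "variance_explained",
    "r2_from_lof",
    "endmember_correlations",
    "match_endmembers",
    "rank_scree",
    "render_abundance_map",
    "normalize_to_band",
    "diagnostics_report",
]


def _residual_ratio(D_ref, C, S) -> tuple[float, float]:
    D_ref = np.asarray(D_ref, float)
    E = D_ref - np.asarray(C, float) @ np.asarray(S, float)
    dss = float((D_ref**2).sum())
    if dss <= 0:
        raise ValueError("reference data are all zero")
    return float((E**2).sum()), dss


def lack_of_fit(D_ref, C, S) -> float:
    """LOF in percent: 100 * sqrt(residual SS / data SS)."""
    ess, dss = _residual_ratio(D_ref, C, S)
    return 100.0 * float(np.sqrt(ess / dss))


def variance_explained(D_ref, C, S) -> float:
    """Explained variance r^2 in percent: 100 * (1 - residual SS / data SS)."""
    ess, dss = _residual_ratio(D_ref, C, S)
    return 100.0 * (1.0 - ess / dss)


def r2_from_lof(lof_percent: float) -> float:
    """The residual identity r^2 = 100 - LOF^2/100 (both in percent)."""
    return 100.0 - lof_percent**2 / 100.0


def endmember_correlations(S_a: np.ndarray, S_b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of S_a and every row of S_b.

    Constant spectra have undefined correlation; their entries are set to 0
    and a warning is emitted.
    """
    S_a = np.atleast_2d(np.asarray(S_a, float))
    S_b = np.atleast_2d(np.asarray(S_b, float))
    if S_a.shape[1] != S_b.shape[1]:
        raise ValueError("channel counts differ")
    A = S_a - S_a.mean(axis=1, keepdims=True)
    B = S_b - S_b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    flat_a, flat_b = na <= 0, nb <= 0
    if flat_a.any() or flat_b.any():
        warnings.warn("constant spectrum: correlation set to 0")
    na = np.where(flat_a, 1.0, na)
    nb = np.where(flat_b, 1.0, nb)
    R = (A / na[:, None]) @ (B / nb[:, None]).T
    R[flat_a, :] = 0.0
    R[:, flat_b] = 0.0
    return R


def match_endmembers(result_a, result_b, max_exhaustive: int = 8):
    """Assign endmembers of ``result_b`` to those of ``result_a``.

    Accepts :class:`UnmixingResult` objects or bare ``S`` matrices (then no
    abundance tie-break is available).  Returns ``(perm, spectral_r,
    abundance_r)`` where ``perm[i]`` is the index in b matched to i of a.
    The assignment maximizes total spectral Pearson r, exhaustively for
    p <= ``max_exhaustive``; ties are broken by total abundance-map
    correlation, then by lexicographic order.
    """
    S_a = result_a.S if isinstance(result_a, UnmixingResult) else np.asarray(result_a)
    S_b = result_b.S if isinstance(result_b, UnmixingResult) else np.asarray(result_b)
    if S_a.shape[0] != S_b.shape[0]:
        raise ValueError("ranks differ; cannot match endmembers")
    p = S_a.shape[0]
    R = endmember_correlations(S_a, S_b)
    Rc = None
    if isinstance(result_a, UnmixingResult) and isinstance(result_b, UnmixingResult):
        Rc = endmember_correlations(result_a.C.T, result_b.C.T)

    if p <= max_exhaustive:
        best_perm, best_key = None, None
        for perm in permutations(range(p)):
            total = sum(R[i, perm[i]] for i in range(p))
            tie = sum(Rc[i, perm[i]] for i in range(p)) if Rc is not None else 0.0
            key = (round(total, 12), round(tie, 12), tuple(-q for q in perm))
            if best_key is None or key > best_key:
                best_key, best_perm = key, perm
        perm = best_perm
    else:
        warnings.warn(f"rank {p} > {max_exhaustive}: greedy endmember matching")
        perm_l, used = [], set()
        for i in range(p):
            order = np.argsort(-R[i])
            j = next(int(q) for q in order if q not in used)
            used.add(j)
            perm_l.append(j)
        perm = tuple(perm_l)

    spectral_r = [float(R[i, perm[i]]) for i in range(p)]
    abundance_r = [float(Rc[i, perm[i]]) for i in range(p)] if Rc is not None else None
    return tuple(perm), spectral_r, abundance_r


def rank_scree(D: np.ndarray, noise_factor: float = 3.0,
               rel_floor: float = 1e-8):
    """Singular values (descending) and a suggested model rank.

    The suggested rank counts singular values above the noise floor, taken
    as ``noise_factor`` times the median of the trailing half of the
    spectrum, but never below ``rel_floor`` times the leading value (guards
    exactly low-rank data whose trailing values are rounding noise).
    """
    D = np.asarray(D, float)
    s = np.linalg.svd(D, compute_uv=False)
    tail = s[s.size // 2:]
    floor = max(noise_factor * float(np.median(tail)), rel_floor * float(s[0]))
    return s, int(np.sum(s > floor))


def render_abundance_map(C: np.ndarray, k: int, grid_shape: tuple[int, int]):
    """Min-max scale abundance column k onto the pixel grid, in [0, 1].

    Black (0) is the minimum, white (1) the maximum of that endmember.
    Constant columns come back as all zeros with ``flag=True``.
    Returns ``(grid_image, flag)``.
    """
    C = np.asarray(C, float)
    if not 0 <= k < C.shape[1]:
        raise ValueError("endmember index out of range")
    col = C[:, k]
    rows, cols = grid_shape
    if col.size != rows * cols:
        raise ValueError("grid shape does not match the number of pixels")
    lo, hi = float(col.min()), float(col.max())
    if hi - lo <= 0:
        return np.zeros((rows, cols)), True
    return ((col - lo) / (hi - lo)).reshape(rows, cols), False


def normalize_to_band(s: np.ndarray, axis: SpectralAxis, center: float,
                      window: float = 20.0) -> np.ndarray:
    """Divide a spectrum by its maximum within ``center ± window/2``."""
    sel = axis.window_slice(center, window)
    if not sel.any():
        raise ValueError(f"band window {center}±{window / 2} misses the axis")
    peak = float(np.asarray(s, float)[sel].max())
    if peak <= 0:
        raise ValueError("normalization band has non-positive maximum")
    return np.asarray(s, float) / peak


def diagnostics_report(D_ref, result: UnmixingResult,
                       reference: UnmixingResult | None = None) -> DiagnosticsReport:
    """Bundle LOF/r2, within-method correlations and optional matching."""
    ess, dss = _residual_ratio(D_ref, result.C, result.S)
    lof = 100.0 * float(np.sqrt(ess / dss))
    r2 = 100.0 * (1.0 - ess / dss)
    corr_within = endmember_correlations(result.S, result.S)
    corr_between = None
    matching = None
    if reference is not None:
        corr_between = endmember_correlations(reference.S, result.S)
        matching, _, _ = match_endmembers(reference, result)
    return DiagnosticsReport(
        lof_percent=lof, r2_percent=r2, residual_ss=ess, data_ss=dss,
        corr_within=corr_within, corr_between=corr_between, matching=matching,
    )
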