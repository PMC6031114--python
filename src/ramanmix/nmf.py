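"""Non-negative matrix factorization with Euclidean multiplicative updates.

Both factors are updated with the classic multiplicative rules for the
squared Euclidean cost, which make the cost non-increasing at every step.
Missing entries can be excluded through a boolean mask (True = observed):
numerators and denominators of the updates are then computed over observed
entries only (weighted multiplicative updates).  Because the updates cannot
leave the non-negative orthant, the input data must be non-negative;
baseline-corrected spectra are clipped first (:func:`clip_for_nmf`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import HyperspectralImage, UnmixingResult

__all__ = ["NmfOptions", "nmf_cost", "nmf_fit", "clip_for_nmf"]


@dataclass
class NmfOptions:
    rank: int
    iterations: int = 100_000
    seed: int = 0
    epsilon: float = 1e-12
    early_stop_tol: Optional[float] = None  # relative cost change
    mask: Optional[np.ndarray] = None  # True = observed
    restarts: int = 1
    trace_every: int = 50
    burn_in: Optional[int] = None  # restart-selection budget; None = iterations//10
    keep_best: int = 2  # restarts continued past burn-in

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.keep_best < 1:
            raise ValueError("keep_best must be >= 1")


def nmf_cost(D: np.ndarray, C: np.ndarray, S: np.ndarray,
             mask: Optional[np.ndarray] = None) -> float:
    """Squared Euclidean cost over observed entries."""
    R = np.asarray(D, float) - np.asarray(C, float) @ np.asarray(S, float)
    if mask is not None:
        R = R[np.asarray(mask, bool)]
    return float((R**2).sum())


def _mu_run(D, p, iters, rng, eps, tol, mask, trace_every,
            state=None, it0=0):
    """One multiplicative-update run; resumable from a previous state.

    Resuming from ``state=(C, S, trace)`` continues the exact trajectory the
    run would have followed uninterrupted (the RNG is only used at
    initialization), so burn-in + continuation equals one straight run.
    """
    n, m = D.shape
    if state is None:
        amp = np.sqrt(max(float(D[mask].mean() if mask is not None else D.mean()), eps) / p)
        C = rng.uniform(0.0, 1.0, size=(n, p)) * amp
        S = rng.uniform(0.0, 1.0, size=(p, m)) * amp
        trace = []
    else:
        C, S, trace = state
        C, S, trace = C.copy(), S.copy(), list(trace)
    W = None if mask is None else mask.astype(float)
    Dw = D if W is None else D * W
    prev = trace[-1][1] if trace else None
    for it in range(it0 + 1, iters + 1):
        if W is None:
            # Gram form of the same updates: C S S^T and C^T C S are exact
            # rewrites of (C S) S^T and C^T (C S)
            C *= (D @ S.T) / (C @ (S @ S.T) + eps)
            S *= (C.T @ D) / ((C.T @ C) @ S + eps)
        else:
            CS = (C @ S) * W
            C *= (Dw @ S.T) / (CS @ S.T + eps)
            CS = (C @ S) * W
            S *= (C.T @ Dw) / (C.T @ CS + eps)
        if it % trace_every == 0 or it == iters:
            cost = nmf_cost(D, C, S, mask)
            trace.append((it, cost))
            if tol is not None and prev is not None:
                if abs(prev - cost) <= tol * max(prev, 1e-300):
                    break
            prev = cost
    return C, S, trace


def _normalize_report(C, S):
    """Scale S rows to unit maximum, rescaling C to keep C S unchanged."""
    peaks = S.max(axis=1)
    safe = np.where(peaks > 0, peaks, 1.0)
    return C * safe[None, :], S / safe[:, None]


def nmf_fit(D: np.ndarray | HyperspectralImage, opts: NmfOptions) -> UnmixingResult:
    """Multiplicative-update NMF; best of ``opts.restarts`` seeded runs.

    The returned ``trace`` holds ``(iteration, cost)`` of the winning run;
    ``options['all_final_costs']`` records every restart's final cost.
    """
    if isinstance(D, HyperspectralImage):
        if opts.mask is None and D.mask is not None:
            opts = NmfOptions(**{**opts.__dict__, "mask": D.mask})
        D = D.D
    D = np.asarray(D, dtype=float)
    mask = None if opts.mask is None else np.asarray(opts.mask, bool)
    observed = D if mask is None else D[mask]
    if observed.min(initial=0.0) < 0:
        raise ValueError(
            "NMF requires non-negative data; clip negatives first "
            "(see clip_for_nmf)"
        )
    master = np.random.default_rng(opts.seed)
    seeds = master.integers(0, 2**31 - 1, size=opts.restarts)

    burn = opts.burn_in if opts.burn_in is not None else max(opts.iterations // 10, 1)
    burn = min(burn, opts.iterations)
    keep = min(opts.keep_best, opts.restarts)

    # burn-in every restart, continue only the most promising ones; the
    # continued trajectory is identical to an uninterrupted run
    states = []
    for s in seeds:
        C, S, trace = _mu_run(
            D, opts.rank, burn, np.random.default_rng(int(s)),
            opts.epsilon, opts.early_stop_tol, mask, opts.trace_every,
        )
        states.append((C, S, trace))
    order = np.argsort([st[2][-1][1] for st in states], kind="stable")

    best = None
    finals = [st[2][-1][1] for st in states]
    for i in order[:keep] if burn < opts.iterations else order[:0]:
        C, S, trace = _mu_run(
            D, opts.rank, opts.iterations, None,
            opts.epsilon, opts.early_stop_tol, mask, opts.trace_every,
            state=states[i], it0=burn,
        )
        final = trace[-1][1]
        finals[i] = final
        if best is None or final < best[3]:
            best = (C, S, trace, final)
    if best is None:  # burn-in was the whole budget
        i = int(order[0])
        C, S, trace = states[i]
        best = (C, S, trace, trace[-1][1])
    C, S, trace, final = best
    C, S = _normalize_report(C, S)
    return UnmixingResult(
        method="NMF", rank=opts.rank, S=S, C=C,
        options={"seed": opts.seed, "iterations": opts.iterations,
                 "restarts": opts.restarts, "masked": mask is not None,
                 "all_final_costs": finals, "final_cost": final},
        trace=trace,
    )


def clip_for_nmf(img: HyperspectralImage):
    """Zero out negative intensities; report how much was clipped.

    Returns ``(image, report)`` with ``report = {'n_clipped', 'clipped_mass',
    'total_mass'}`` where masses are sums of absolute intensities.
    """
    D = img.D
    neg = D < 0
    report = {
        "n_clipped": int(neg.sum()),
        "clipped_mass": float(-D[neg].sum()),
        "total_mass": float(np.abs(D).sum()),
    }
    return img.replace(D=np.clip(D, 0.0, None)), report
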