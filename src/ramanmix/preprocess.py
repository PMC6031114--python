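"""Spectral pre-processing: cropping, cosmic-ray removal, baseline subtraction.

The processing chain mirrors standard Raman map preparation: spectra are cut
to the fingerprint region (default 300-1800 cm^-1), cosmic-ray spikes are
flagged against the median of a spatial-spectral neighborhood and replaced by
interpolation, and a per-spectrum order-3 polynomial background is removed by
an iterative peak-excluding least-squares fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import HyperspectralImage

__all__ = ["PreprocessConfig", "crop", "despike", "subtract_baseline"]


@dataclass
class PreprocessConfig:
    """Tunable pre-processing parameters.

    ``despike_threshold`` is in multiples of the robust neighborhood scale
    (1.4826 x median absolute deviation); ``despike_neighborhood`` is
    (spatial radius in pixels, spectral radius in channels).
    """

    crop_lo: float = 300.0
    crop_hi: float = 1800.0
    despike_threshold: float = 8.0
    despike_neighborhood: tuple[int, int] = (1, 2)
    baseline_order: int = 3
    baseline_max_passes: int = 100
    clip_negative: bool = False

    def __post_init__(self) -> None:
        if self.crop_lo >= self.crop_hi:
            raise ValueError("crop_lo must be < crop_hi")
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        if self.despike_threshold <= 0:
            raise ValueError("despike_threshold must be positive")


def crop(img: HyperspectralImage, lo: float, hi: float) -> HyperspectralImage:
    """Restrict the axis to channels with lo <= wavenumber <= hi (inclusive)."""
    if lo >= hi:
        raise ValueError(f"invalid crop bounds [{lo}, {hi}]")
    keep = (img.axis.wavenumbers >= lo) & (img.axis.wavenumbers <= hi)
    if keep.sum() < 2:
        raise ValueError(f"crop window [{lo}, {hi}] leaves fewer than 2 channels")
    from .datamodel import SpectralAxis

    return img.replace(
        axis=SpectralAxis(img.axis.wavenumbers[keep]),
        D=img.D[:, keep],
        mask=None if img.mask is None else img.mask[:, keep],
    )


def _neighborhood_stats(cube: np.ndarray, sr: int, sv: int,
                        channel_block: int = 64):
    """Per-entry median, MAD and max of the spatial-spectral neighborhood.

    The neighborhood is the (2*sr+1)^2 x (2*sv+1) window around each entry,
    excluding the entry itself.  Spatial edges are mirror-padded (which
    never re-introduces the center sample at radius 1); spectral edges are
    padded with NaN and skipped by nan-aware reductions, so a boundary
    channel is never compared against its own reflection.  Processed in
    channel blocks to bound memory.
    """
    rows, cols, m = cube.shape
    padded = np.pad(cube, ((sr, sr), (sr, sr), (0, 0)), mode="reflect")
    padded = np.pad(padded, ((0, 0), (0, 0), (sv, sv)), mode="constant",
                    constant_values=np.nan)
    wlen = (2 * sr + 1) ** 2 * (2 * sv + 1)
    center = wlen // 2  # row-major center of the window
    med = np.empty_like(cube)
    mad = np.empty_like(cube)
    nmax = np.empty_like(cube)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for start in range(0, m, channel_block):
            stop = min(start + channel_block, m)
            block = padded[:, :, start:stop + 2 * sv]
            win = np.lib.stride_tricks.sliding_window_view(
                block, (2 * sr + 1, 2 * sr + 1, 2 * sv + 1)
            )  # (rows, cols, nb, w1, w2, w3)
            win = win.reshape(rows, cols, stop - start, wlen)
            win = np.delete(win, center, axis=-1)
            med[:, :, start:stop] = np.nanmedian(win, axis=-1)
            mad[:, :, start:stop] = np.nanmedian(
                np.abs(win - med[:, :, start:stop, None]), axis=-1
            )
            nmax[:, :, start:stop] = np.nanmax(np.abs(win), axis=-1)
    return med, mad, nmax


def despike(img: HyperspectralImage, cfg: PreprocessConfig | None = None,
            max_passes: int = 5):
    """Flag and repair cosmic-ray spikes.

    An entry is flagged iff its residual against the median of its
    spatial-spectral neighborhood exceeds ``despike_threshold`` robust scales
    (1.4826 x MAD) of that neighborhood.  Flagged entries are replaced by
    linear interpolation along the spectral axis.  The pass is repeated
    (up to ``max_passes``) until no new entries are flagged, so that spikes
    masking each other's neighborhoods are still caught.  Returns the
    corrected image and a DataFrame with columns pixel, channel, old, new.
    """
    cfg = cfg or PreprocessConfig()
    sr, sv = cfg.despike_neighborhood
    rows, cols = img.grid_shape
    m = img.n_channels
    wlen = (2 * sr + 1) ** 2 * (2 * sv + 1)
    if wlen <= 1:
        raise ValueError("despike neighborhood is empty; increase the radii")
    original = img.to_cube()
    work = original.copy()
    all_records: list[tuple] = []
    for _ in range(max_passes):
        work, records = _despike_pass(work, original, img, cfg, sr, sv)
        all_records.extend(records)
        if not records:
            break
    out = img.replace(D=work.reshape(rows * cols, m))
    log = pd.DataFrame(all_records, columns=["pixel", "channel", "old", "new"])
    return out, log


def _despike_pass(cube, original, img, cfg, sr, sv):
    rows, cols = img.grid_shape
    med, mad, nmax = _neighborhood_stats(cube, sr, sv)
    scale = 1.4826 * mad
    # robust-scale floors: cosmic rays tower over everything nearby, so the
    # scale is floored at a quarter of the neighborhood maximum (a spike must
    # exceed twice the largest neighbor at threshold 8) and at 1% of the mean
    # intensity (shot-noise tails in near-zero regions are not spikes).
    # Without these, band intensities at sharp tissue boundaries would be
    # mistaken for spikes.
    floor = np.maximum(0.25 * nmax, 0.01 * float(np.abs(cube).mean()))
    flags = np.abs(cube - med) > cfg.despike_threshold * np.maximum(scale, floor)

    corrected = cube.copy()
    records = []
    x = img.axis.wavenumbers
    for r, c in zip(*np.nonzero(flags.any(axis=2))):
        bad = flags[r, c]
        good = ~bad
        if not good.any():
            raise ValueError(f"all channels flagged for pixel ({r}, {c})")
        corrected[r, c, bad] = np.interp(x[bad], x[good], cube[r, c, good])
        for j in np.nonzero(bad)[0]:
            records.append((int(r * cols + c), int(j),
                            float(original[r, c, j]), float(corrected[r, c, j])))
    return corrected, records


def _iterative_polyfit(x: np.ndarray, Y: np.ndarray, order: int,
                       max_passes: int, tol: float = 1e-6) -> np.ndarray:
    """Peak-excluding polynomial baseline for each row of Y.

    Fit an order-``order`` polynomial by least squares, replace points above
    the fit by the fit, and repeat until no point moves by more than ``tol``
    of the spectrum range or ``max_passes`` is reached.  Returns the final
    polynomial evaluated on x, one row per spectrum.
    """
    # scale x to [-1, 1] for conditioning; the fit itself is unchanged
    xs = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    V = np.polynomial.polynomial.polyvander(xs, order)
    work = Y.copy()
    rng_ = Y.max(axis=1) - Y.min(axis=1)
    thresh = tol * np.where(rng_ > 0, rng_, 1.0)
    fit = np.zeros_like(Y)
    for _ in range(max_passes):
        coef, *_ = np.linalg.lstsq(V, work.T, rcond=None)
        fit = (V @ coef).T
        clipped = np.minimum(work, fit)
        delta = np.max(np.abs(clipped - work), axis=1)
        work = clipped
        if np.all(delta <= thresh):
            break
    return fit


def subtract_baseline(img: HyperspectralImage, cfg: PreprocessConfig | None = None):
    """Remove a per-spectrum polynomial background (default order 3).

    Returns the corrected image and the estimated background matrix
    ``[n_pixels x m]``.  If ``cfg.clip_negative``, corrected intensities are
    floored at zero (required before NMF).
    """
    cfg = cfg or PreprocessConfig()
    if not np.all(np.isfinite(img.D)):
        raise ValueError("baseline subtraction requires finite intensities")
    if cfg.baseline_order >= img.n_channels:
        raise ValueError("baseline order must be below the channel count")
    bg = _iterative_polyfit(img.axis.wavenumbers, img.D,
                            cfg.baseline_order, cfg.baseline_max_passes)
    out = img.D - bg
    if cfg.clip_negative:
        out = np.clip(out, 0.0, None)
    return img.replace(D=out), bg
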