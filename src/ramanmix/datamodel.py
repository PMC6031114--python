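"""Core containers for Raman hyperspectral unmixing.

The data model is the bilinear mixing model D = C S: a hyperspectral image is
an ``n_pixels x m`` intensity matrix ``D`` over a wavenumber axis of length
``m``, decomposed into per-pixel abundances ``C`` (``n_pixels x p``) and
endmember spectra ``S`` (``p x m``).  Pixels are stored in row-major grid
order (the row index varies slowest); the wavenumber axis is stored ascending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SpectralAxis",
    "HyperspectralImage",
    "UnmixingResult",
    "DiagnosticsReport",
]


@dataclass(frozen=True)
class SpectralAxis:
    """Wavenumber axis in cm^-1: strictly increasing, finite, length >= 2."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("spectral axis must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(w)):
            raise ValueError("spectral axis contains non-finite values")
        if not np.all(np.diff(w) > 0):
            raise ValueError("spectral axis must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    @property
    def lo(self) -> float:
        return float(self.wavenumbers[0])

    @property
    def hi(self) -> float:
        return float(self.wavenumbers[-1])

    def index_of(self, wavenumber: float) -> int:
        """Index of the channel nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def window_slice(self, center: float, window: float) -> np.ndarray:
        """Boolean channel selector for ``center ± window/2`` (inclusive)."""
        w = self.wavenumbers
        return (w >= center - window / 2.0) & (w <= center + window / 2.0)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_channels


def regular_axis(lo: float = 300.0, hi: float = 1800.0, step: float = 4.0) -> SpectralAxis:
    """Evenly spaced axis from ``lo`` to ``hi`` (inclusive when it fits)."""
    n = int(np.floor((hi - lo) / step + 0.5)) + 1
    return SpectralAxis(lo + step * np.arange(n))


@dataclass
class HyperspectralImage:
    """Pixel grid + wavenumber axis + intensity matrix D.

    Parameters
    ----------
    grid_shape
        ``(rows, cols)`` of the scanned pixel grid.
    axis
        Wavenumber axis shared by all pixels.
    D
        ``(rows*cols, m)`` intensity matrix, one spectrum per row, pixels in
        row-major grid order.
    mask
        Optional boolean matrix, same shape as ``D``; ``True`` marks observed
        (valid) entries, ``False`` marks missing ones.  ``None`` means fully
        observed.
    meta
        Free-form string metadata (sample name, laser wavelength nm,
        objective NA, step size um, ...).
    """

    grid_shape: tuple[int, int]
    axis: SpectralAxis
    D: np.ndarray
    mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError("grid_shape entries must be positive")
        self.grid_shape = (int(rows), int(cols))
        self.D = np.asarray(self.D, dtype=np.float64)
        if self.D.ndim != 2:
            raise ValueError("D must be a 2-D matrix [n_pixels x m]")
        if self.D.shape[0] != rows * cols:
            raise ValueError(
                f"grid {rows}x{cols} implies {rows * cols} pixels, "
                f"but D has {self.D.shape[0]} rows"
            )
        if self.D.shape[1] != self.axis.n_channels:
            raise ValueError(
                f"D has {self.D.shape[1]} channels but the axis has "
                f"{self.axis.n_channels}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.D.shape:
                raise ValueError("mask shape must match D")
            observed = self.mask
        else:
            observed = np.ones_like(self.D, dtype=bool)
        if not np.all(np.isfinite(self.D[observed])):
            raise ValueError("D contains non-finite values at observed entries")

    # -- pixel-order contract ------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return self.D.shape[0]

    @property
    def n_channels(self) -> int:
        return self.D.shape[1]

    def to_cube(self) -> np.ndarray:
        """View D as a (rows, cols, m) cube (row-major pixel order)."""
        rows, cols = self.grid_shape
        return self.D.reshape(rows, cols, self.n_channels)

    @classmethod
    def from_cube(
        cls,
        cube: np.ndarray,
        axis: SpectralAxis,
        mask: Optional[np.ndarray] = None,
        meta: Optional[dict] = None,
    ) -> "HyperspectralImage":
        cube = np.asarray(cube, dtype=np.float64)
        rows, cols, m = cube.shape
        flat_mask = None if mask is None else np.asarray(mask).reshape(rows * cols, m)
        return cls((rows, cols), axis, cube.reshape(rows * cols, m),
                   mask=flat_mask, meta=dict(meta or {}))

    def map_from_vector(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-pixel vector (e.g. one abundance column) to the grid."""
        v = np.asarray(values)
        if v.shape != (self.n_pixels,):
            raise ValueError("expected one value per pixel")
        return v.reshape(self.grid_shape)

    def replace(self, **kwargs) -> "HyperspectralImage":
        """Copy with some fields replaced (D, mask, axis, meta, grid_shape)."""
        fields = dict(
            grid_shape=self.grid_shape,
            axis=self.axis,
            D=self.D,
            mask=None if self.mask is None else self.mask.copy(),
            meta=dict(self.meta),
        )
        fields.update(kwargs)
        return HyperspectralImage(**fields)

    def require_nonnegative(self) -> None:
        """Raise if any observed intensity is negative (raw-counts contract)."""
        observed = np.ones_like(self.D, bool) if self.mask is None else self.mask
        if np.any(self.D[observed] < 0):
            raise ValueError("image contains negative observed intensities")


_METHODS = ("VCA", "NMF", "MCR_ALS")


@dataclass
class UnmixingResult:
    """Fitted bilinear model D ~ C S.

    ``S`` holds the p endmember spectra as rows, ``C`` the per-pixel
    abundances as columns of the pixel matrix.  ``trace`` records
    ``(iteration, objective)`` pairs: squared Euclidean cost for NMF,
    lack-of-fit percent for MCR-ALS, the final reconstruction cost for VCA.
    """

    method: str
    rank: int
    S: np.ndarray
    C: np.ndarray
    options: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        self.S = np.asarray(self.S, dtype=np.float64)
        self.C = np.asarray(self.C, dtype=np.float64)
        p = int(self.rank)
        if p < 1:
            raise ValueError("rank must be a positive integer")
        if self.S.shape[0] != p or self.C.shape[1] != p:
            raise ValueError("S must be [p x m] and C [n_pixels x p]")
        if self.C.min(initial=0.0) < -1e-10:
            raise ValueError("C must be non-negative (within 1e-10)")
        # VCA endmembers are pixel spectra: on baseline-corrected (partly
        # negative) input they legitimately carry negative entries
        if self.options.get("require_nonneg_S", True) \
                and self.S.min(initial=0.0) < -1e-10:
            raise ValueError("S must be non-negative (within 1e-10)")

    @property
    def reconstruction(self) -> np.ndarray:
        return self.C @ self.S


@dataclass
class DiagnosticsReport:
    """Model statistics for one fitted unmixing model.

    ``lof_percent`` and ``r2_percent`` are computed from the same residuals,
    so ``r2 = 100 - lof**2 / 100`` holds by construction.
    """

    lof_percent: float
    r2_percent: float
    residual_ss: float
    data_ss: float
    corr_within: np.ndarray
    corr_between: Optional[np.ndarray] = None
    matching: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        ident = 100.0 - self.lof_percent**2 / 100.0
        if abs(ident - self.r2_percent) > 1e-9:
            raise ValueError("lof/r2 pair violates the residual identity")
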