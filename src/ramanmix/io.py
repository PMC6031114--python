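"""Portable on-disk formats for hyperspectral images.

Two dialects:

* ``hdf5`` — one group with datasets ``D``, ``wavenumbers`` and optionally
  ``mask`` (uint8, 1 = observed) plus attributes ``rows``, ``cols`` and a
  JSON-encoded ``meta`` string.  Bit-exact round trip.
* ``csv+json`` — a headerless CSV intensity matrix (pixels as rows, channels
  as columns) next to a JSON sidecar ``{rows, cols, wavenumbers, meta,
  missing}`` where ``missing`` lists ``[pixel, channel]`` pairs.  Round trip
  exact to >= 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .datamodel import HyperspectralImage, SpectralAxis

__all__ = ["read_image", "write_image", "sidecar_path"]

FORMATS = ("hdf5", "csv+json")


def sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}")
        return format
    if path.suffix.lower() in (".h5", ".hdf5"):
        return "hdf5"
    return "csv+json"


def write_image(img: HyperspectralImage, path, format: Optional[str] = None) -> Path:
    """Write an image; returns the primary file path."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("D", data=img.D)
            f.create_dataset("wavenumbers", data=img.axis.wavenumbers)
            if img.mask is not None:
                f.create_dataset("mask", data=img.mask.astype(np.uint8))
            f.attrs["rows"], f.attrs["cols"] = img.grid_shape
            f.attrs["meta"] = json.dumps(img.meta)
    else:
        np.savetxt(path, img.D, delimiter=",", fmt="%.17g")
        missing = []
        if img.mask is not None:
            missing = [[int(i), int(j)] for i, j in zip(*np.nonzero(~img.mask))]
        sidecar = {
            "rows": img.grid_shape[0],
            "cols": img.grid_shape[1],
            "wavenumbers": img.axis.wavenumbers.tolist(),
            "meta": img.meta,
            "missing": missing,
        }
        sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def read_image(path, format: Optional[str] = None) -> HyperspectralImage:
    """Read and validate an image written by :func:`write_image`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "wavenumbers" not in f:
                raise ValueError(f"{path}: missing wavenumber axis")
            D = np.asarray(f["D"], dtype=np.float64)
            axis = SpectralAxis(np.asarray(f["wavenumbers"], dtype=np.float64))
            mask = np.asarray(f["mask"], bool) if "mask" in f else None
            if "rows" not in f.attrs or "cols" not in f.attrs:
                raise ValueError(f"{path}: missing grid shape attributes")
            grid = (int(f.attrs["rows"]), int(f.attrs["cols"]))
            meta = json.loads(f.attrs.get("meta", "{}"))
    else:
        side = sidecar_path(path)
        if not side.exists():
            raise ValueError(f"{path}: missing JSON sidecar {side}")
        info = json.loads(side.read_text())
        if "wavenumbers" not in info:
            raise ValueError(f"{side}: sidecar lacks the wavenumber axis")
        D = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=np.float64))
        axis = SpectralAxis(np.asarray(info["wavenumbers"], dtype=np.float64))
        grid = (int(info["rows"]), int(info["cols"]))
        mask = None
        if info.get("missing"):
            mask = np.ones(D.shape, dtype=bool)
            for i, j in info["missing"]:
                mask[i, j] = False
        meta = info.get("meta", {})
    # HyperspectralImage validates grid/axis/shape consistency.
    return HyperspectralImage(grid, axis, D, mask=mask, meta=meta)
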