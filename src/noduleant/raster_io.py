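"""Grayscale raster and edge-map I/O.

Two in-memory currencies are used throughout the package:

``GrayRaster``
    A 2-D ``float64`` array with every value in ``[0, 1]``.  Whatever the
    source bit depth (8- or 16-bit PNG/TIFF/PGM), intensities are linearly
    rescaled to this range on load so that downstream thresholds are
    depth-independent.

``EdgeMap``
    A 2-D boolean array of the same shape as its source raster.  Foreground
    (edge) pixels are ``True`` internally and are rendered as 255 on export;
    the "edges are black pixels" convention seen in print is a display
    choice only.

Coordinates are ``(row, col)``, 0-based, row 0 at the top — raster file
order.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = [
    "as_gray_raster",
    "as_edge_map",
    "load_gray",
    "save_edge_map",
    "load_edge_map",
]


def as_gray_raster(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce *arr* into a GrayRaster (float64 in [0, 1])."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"GrayRaster must be 2-D and non-empty, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("GrayRaster values must be finite")
    if a.min() < 0.0 or a.max() > 1.0:
        raise ValueError("GrayRaster values must lie in [0, 1]")
    return a


def as_edge_map(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce *arr* into an EdgeMap (2-D boolean array)."""
    a = np.asarray(arr)
    if a.dtype != bool:
        if not np.isin(a, (0, 1)).all():
            raise ValueError("EdgeMap must be strictly binary")
        a = a.astype(bool)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"EdgeMap must be 2-D and non-empty, got shape {a.shape}")
    return a


def _read(path: str | os.PathLike) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise IOError(f"cannot read image file: {path!s} (not found)") from None
    except Exception as exc:  # noqa: BLE001 - normalise backend errors
        raise IOError(f"cannot read image file: {path!s} ({exc})") from exc
    return np.asarray(arr)


def _to_single_channel(arr: np.ndarray, path: str | os.PathLike) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        # RGB(A): average the colour channels, dropping alpha.
        return arr[..., :3].mean(axis=-1)
    if arr.ndim == 3:
        raise IOError(
            f"{path!s} appears to be a multi-frame image of shape {arr.shape}; "
            "extract a single frame (e.g. with tifffile) before loading"
        )
    raise IOError(f"unsupported image shape {arr.shape} in {path!s}")


def load_gray(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/TIFF/PGM file as a GrayRaster.

    Integer images are rescaled by their dtype's full range (255 for 8-bit,
    65535 for 16-bit); floating-point images are expected to already be in
    ``[0, 1]`` and are clipped.  RGB inputs are averaged to one channel.
    """
    raw = _read(path)
    # record the native scale before channel averaging turns the array float
    full = float(np.iinfo(raw.dtype).max) if np.issubdtype(raw.dtype, np.integer) else None
    arr = _to_single_channel(raw, path).astype(np.float64)
    out = arr / full if full is not None else arr
    return as_gray_raster(np.clip(out, 0.0, 1.0))


def save_edge_map(edge_map: np.ndarray, path: str | os.PathLike) -> None:
    """Write an EdgeMap as an 8-bit PNG: foreground 255, background 0."""
    m = as_edge_map(edge_map)
    out = np.where(m, 255, 0).astype(np.uint8)
    try:
        iio.imwrite(path, out)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write edge map to {path!s} ({exc})") from exc


def load_edge_map(path: str | os.PathLike) -> np.ndarray:
    """Load a single-channel image as an EdgeMap.

    Pixels strictly above half of the full scale (127.5 for 8-bit) are
    foreground, so a 0/255 export round-trips bit-exactly.
    """
    arr = _to_single_channel(_read(path), path)
    if np.issubdtype(arr.dtype, np.integer):
        half = np.iinfo(arr.dtype).max / 2.0
    else:
        half = 0.5
    return as_edge_map(arr > half)
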