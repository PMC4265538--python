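"""Non-ant baseline edge detectors: Otsu, watershed, and region growing.

Each detector reduces a GrayRaster to a boolean EdgeMap.  Thresholding and
region methods produce a *segmentation* first; the edge image is the inner
boundary of the segmented foreground (a foreground pixel with at least one
4-neighbour outside the region).  For the threshold-based detector the
image border is treated as "more foreground" (replicated), so a bright
half-plane yields only the step column and not a frame; for region growing
the raster border counts as outside the region, so a region that fills the
raster yields its border ring.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .raster_io import as_gray_raster

__all__ = [
    "RegionGrowParams",
    "quantize256",
    "histogram256",
    "otsu_threshold",
    "inner_boundary",
    "otsu_edges",
    "watershed_edges",
    "region_growing_edges",
]


@dataclass(frozen=True)
class RegionGrowParams:
    """Seed pixel and admission tolerance for region growing.

    ``intensity_tolerance`` is the largest allowed |pixel - region mean|
    (on the normalized [0, 1] scale) for a frontier pixel to join the
    region.
    """

    seed: tuple[int, int]
    intensity_tolerance: float = 0.1

    def __post_init__(self) -> None:
        if self.intensity_tolerance < 0:
            raise ValueError("intensity_tolerance must be >= 0")


def quantize256(img: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] raster to integer bins 0..255 (round to nearest)."""
    img = as_gray_raster(img)
    return np.rint(img * 255.0).astype(np.int64)


def histogram256(img: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of a GrayRaster."""
    return np.bincount(quantize256(img).ravel(), minlength=256)


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin histogram.

    Returns the bin index ``t`` splitting ``[0..t]`` from ``[t+1..255]``
    that minimizes the within-class variance (equivalently maximizes the
    between-class variance), the smallest such ``t`` on ties.  A histogram
    with a single occupied bin admits no split; that bin is returned with a
    warning.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    total = hist.sum()
    if total == 0:
        raise ValueError("empty histogram")
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        warnings.warn(
            "histogram has a single occupied bin; no threshold separates "
            "foreground from background",
            stacklevel=2,
        )
        return int(nonzero[0])

    bins = np.arange(256, dtype=np.float64)
    p = hist / total
    w0 = np.cumsum(p)                 # class-0 weight for split at t
    mu = np.cumsum(p * bins)          # class-0 unnormalized mean
    mu_t = mu[-1]
    # Between-class variance: w0*w1*(mu0-mu1)^2 == (mu_t*w0 - mu)^2/(w0*w1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bcv = (mu_t * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    bcv[~np.isfinite(bcv)] = 0.0
    return int(np.argmax(bcv))        # argmax takes the first (lowest) tie


_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def inner_boundary(foreground: np.ndarray, border_is_background: bool = False) -> np.ndarray:
    """Pixels of *foreground* with at least one 4-neighbour outside it.

    ``border_is_background`` decides whether stepping off the raster counts
    as leaving the foreground.
    """
    fg = np.asarray(foreground, dtype=bool)
    mode = "constant" if border_is_background else "edge"
    pad = np.pad(fg, 1, mode=mode, **({"constant_values": False} if border_is_background else {}))
    any_bg = np.zeros_like(fg)
    for dr, dc in _N4:
        any_bg |= ~pad[1 + dr : 1 + dr + fg.shape[0], 1 + dc : 1 + dc + fg.shape[1]]
    return fg & any_bg


def otsu_edges(img: np.ndarray) -> np.ndarray:
    """Otsu-threshold the raster and return the foreground's inner boundary."""
    img = as_gray_raster(img)
    q = quantize256(img)
    t = otsu_threshold(np.bincount(q.ravel(), minlength=256))
    return inner_boundary(q > t, border_is_background=False)


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    # Central differences with the border row/column replicated.
    pad = np.pad(img, 1, mode="edge")
    gr = (pad[2:, 1:-1] - pad[:-2, 1:-1]) / 2.0
    gc = (pad[1:-1, 2:] - pad[1:-1, :-2]) / 2.0
    return np.hypot(gr, gc)


def watershed_edges(img: np.ndarray, n_smooth: int = 1) -> np.ndarray:
    """Watershed dams of the gradient-magnitude relief.

    The raster is smoothed ``n_smooth`` times with a 3x3 mean (controls
    oversegmentation), the gradient magnitude is flooded from its regional
    minima (8-connectivity), and pixels where two catchment basins meet —
    the dams — form the edge map.  A constant raster has a single basin and
    therefore an empty edge map.
    """
    img = as_gray_raster(img)
    if n_smooth < 0:
        raise ValueError("n_smooth must be >= 0")
    sm = img
    for _ in range(n_smooth):
        sm = ndi.uniform_filter(sm, size=3, mode="nearest")
    grad = _gradient_magnitude(sm)
    minima = local_minima(grad, connectivity=2)
    markers, n_basins = ndi.label(minima, structure=np.ones((3, 3), dtype=int))
    if n_basins <= 1:
        return np.zeros_like(img, dtype=bool)
    labels = watershed(grad, markers=markers, connectivity=1, watershed_line=True)
    return labels == 0


def count_basins(img: np.ndarray, n_smooth: int = 0) -> int:
    """Number of regional minima (8-connected) of the smoothed gradient."""
    img = as_gray_raster(img)
    sm = img
    for _ in range(n_smooth):
        sm = ndi.uniform_filter(sm, size=3, mode="nearest")
    _, n = ndi.label(local_minima(_gradient_magnitude(sm), connectivity=2),
                     structure=np.ones((3, 3), dtype=int))
    return int(n)


def region_growing_edges(img: np.ndarray, params: RegionGrowParams) -> np.ndarray:
    """Grow a 4-connected region from a seed, tracking the running mean.

    Frontier pixels are visited in FIFO order; a pixel joins the region when
    its intensity is within ``intensity_tolerance`` of the *current* region
    mean, which is updated after every admission.  Neighbours are enqueued
    in N, S, W, E order, making the result fully deterministic.  The edge
    map is the inner boundary of the final region, with the raster border
    counting as outside.
    """
    img = as_gray_raster(img)
    h, w = img.shape
    r0, c0 = params.seed
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"seed {params.seed} outside raster bounds {img.shape}")
    tol = params.intensity_tolerance

    region = np.zeros((h, w), dtype=bool)
    queued = np.zeros((h, w), dtype=bool)
    region[r0, c0] = queued[r0, c0] = True
    mean = img[r0, c0]
    count = 1
    frontier: deque[tuple[int, int]] = deque()
    for dr, dc in _N4:
        rr, cc = r0 + dr, c0 + dc
        if 0 <= rr < h and 0 <= cc < w:
            frontier.append((rr, cc))
            queued[rr, cc] = True
    while frontier:
        r, c = frontier.popleft()
        if abs(img[r, c] - mean) <= tol:
            region[r, c] = True
            count += 1
            mean += (img[r, c] - mean) / count
            for dr, dc in _N4:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not queued[rr, cc]:
                    frontier.append((rr, cc))
                    queued[rr, cc] = True
    return inner_boundary(region, border_is_background=True)
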