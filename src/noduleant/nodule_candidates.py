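"""Black-circular-neighbourhood candidate detection.

An edge map mixes two kinds of foreground structure: thin, extended curves
(lung borders, vessels) and compact clusters of edge pixels left by small
round-ish nodules.  Candidate detection partitions the foreground into
connected components, rejects line-like components (sparse bounding box or
extreme aspect ratio; the fill floor of 0.3 admits the closed 1-px
boundary rings of admissible nodules, whose bbox fill runs down to about
0.4 at the 5-px size ceiling, while still rejecting open 1-px paths), applies the diameter ceiling (nodules up to 5 units
across, taken as pixels here and configurable per image resolution), and
reports each survivor's centre pixel, equivalent diameter, and shape class
(spherical vs elliptical by bounding-box aspect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .raster_io import as_edge_map

__all__ = [
    "PixelComponent",
    "NoduleCandidate",
    "DetectionConfig",
    "find_components",
    "is_line_like",
    "candidate_from_component",
    "detect_candidates",
]


@dataclass(frozen=True)
class PixelComponent:
    """One maximal connected set of foreground pixels."""

    pixels: np.ndarray  # (area, 2) int array of (row, col)
    area: int
    bbox: tuple[int, int, int, int]  # min_row, min_col, max_row, max_col (inclusive)
    extent_major: int
    extent_minor: int


@dataclass(frozen=True)
class NoduleCandidate:
    """A surviving component summarized as a nodule candidate."""

    center: tuple[int, int]
    equiv_diameter: float
    shape: str  # "spherical" | "elliptical"
    area: int
    id: int = -1


@dataclass(frozen=True)
class DetectionConfig:
    connectivity: int = 8
    fill_ratio_min: float = 0.3
    aspect_max: float = 3.0
    d_max: float = 5.0
    ecc_threshold: float = 1.5


def find_components(edge_map: np.ndarray, connectivity: int = 8) -> list[PixelComponent]:
    """Partition foreground pixels into maximal connected components.

    Components come back ordered by (min_row, min_col) of their bounding
    boxes, so the result is deterministic for a given map.
    """
    edge_map = as_edge_map(edge_map)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndi.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndi.label(edge_map, structure=structure)
    comps: list[PixelComponent] = []
    if n == 0:
        return comps
    all_rows, all_cols = np.nonzero(labels)
    order = np.argsort(labels[all_rows, all_cols], kind="stable")
    all_rows, all_cols = all_rows[order], all_cols[order]
    starts = np.searchsorted(labels[all_rows, all_cols], np.arange(1, n + 2))
    for i in range(n):
        rows = all_rows[starts[i] : starts[i + 1]]
        cols = all_cols[starts[i] : starts[i + 1]]
        rmin, rmax = int(rows.min()), int(rows.max())
        cmin, cmax = int(cols.min()), int(cols.max())
        h, w = rmax - rmin + 1, cmax - cmin + 1
        comps.append(
            PixelComponent(
                pixels=np.column_stack([rows, cols]),
                area=int(rows.size),
                bbox=(rmin, cmin, rmax, cmax),
                extent_major=max(h, w),
                extent_minor=min(h, w),
            )
        )
    comps.sort(key=lambda c: (c.bbox[0], c.bbox[1]))
    return comps


def is_line_like(
    comp: PixelComponent, fill_ratio_min: float = 0.3, aspect_max: float = 3.0
) -> bool:
    """Reject thin/extended components as lung-edge or vessel lines.

    A component is line-like when its bounding box is sparsely filled
    (area / (major * minor) below ``fill_ratio_min``) or strongly
    elongated (major / minor above ``aspect_max``).  Compact nodule blobs
    fail both tests.
    """
    fill = comp.area / (comp.extent_major * comp.extent_minor)
    aspect = comp.extent_major / comp.extent_minor
    return fill < fill_ratio_min or aspect > aspect_max


def _round_half_down(x: float) -> int:
    # Rounding ties go to the smaller index.
    return int(math.ceil(x - 0.5))


def candidate_from_component(
    comp: PixelComponent, d_max: float = 5.0, ecc_threshold: float = 1.5
) -> NoduleCandidate | None:
    """Summarize a non-line component, or reject it on the size ceiling.

    The equivalent diameter is ``2*sqrt(area/pi)``; components above
    ``d_max`` are rejected (returned as ``None``).  The centre is the pixel
    centroid rounded to the nearest pixel (ties toward the smaller index);
    the shape class is spherical when the bounding-box aspect is at most
    ``ecc_threshold``, else elliptical.
    """
    equiv_diameter = 2.0 * math.sqrt(comp.area / math.pi)
    if equiv_diameter > d_max:
        return None
    cr, cc = comp.pixels.mean(axis=0)
    aspect = comp.extent_major / comp.extent_minor
    return NoduleCandidate(
        center=(_round_half_down(cr), _round_half_down(cc)),
        equiv_diameter=equiv_diameter,
        shape="spherical" if aspect <= ecc_threshold else "elliptical",
        area=comp.area,
    )


def detect_candidates(
    edge_map: np.ndarray, cfg: DetectionConfig | None = None
) -> list[NoduleCandidate]:
    """Full candidate chain: components -> line filter -> size/shape rules.

    Candidates come back sorted by centre (row, col) with sequential ids.
    """
    if cfg is None:
        cfg = DetectionConfig()
    out: list[NoduleCandidate] = []
    for comp in find_components(edge_map, cfg.connectivity):
        if is_line_like(comp, cfg.fill_ratio_min, cfg.aspect_max):
            continue
        cand = candidate_from_component(comp, cfg.d_max, cfg.ecc_threshold)
        if cand is not None:
            out.append(cand)
    out.sort(key=lambda c: c.center)
    return [
        NoduleCandidate(c.center, c.equiv_diameter, c.shape, c.area, id=i)
        for i, c in enumerate(out)
    ]
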