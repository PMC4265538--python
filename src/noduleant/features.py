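"""Intensity-based filtering and the per-candidate feature matrix.

Candidate centres come from the edge image, but whether a candidate looks
like tissue is decided on the *original* raster: the mean intensity over a
circular region around the centre must exceed a threshold.  Survivors
yield one feature row each — mean intensity, size (component area in
pixels), shape class, and optionally the patient's age — which feeds the
clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nodule_candidates import NoduleCandidate
from .raster_io import as_gray_raster

__all__ = [
    "FeatureRow",
    "circular_mean_intensity",
    "build_feature_matrix",
    "features_to_frame",
    "SHAPE_CODES",
]

# Numeric encoding used when feature rows enter a distance computation.
SHAPE_CODES = {"spherical": 0.0, "elliptical": 1.0}


@dataclass(frozen=True)
class FeatureRow:
    candidate_id: int
    center: tuple[int, int]
    mean_intensity: float
    size: int
    shape: str
    age: float | None = None


def circular_mean_intensity(
    img: np.ndarray, center: tuple[int, int], radius: float
) -> float:
    """Mean of *img* over the disk of given radius around *center*.

    The disk contains every pixel whose centre lies within the Euclidean
    radius (midpoint convention), clipped to the raster; radius 0 reduces
    to the centre pixel's value.
    """
    img = as_gray_raster(img)
    h, w = img.shape
    r0, c0 = center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"center {center} outside raster bounds {img.shape}")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    ri = int(np.floor(radius))
    rlo, rhi = max(0, r0 - ri), min(h - 1, r0 + ri)
    clo, chi = max(0, c0 - ri), min(w - 1, c0 + ri)
    rr, cc = np.mgrid[rlo : rhi + 1, clo : chi + 1]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return float(img[rlo : rhi + 1, clo : chi + 1][inside].mean())


def build_feature_matrix(
    img: np.ndarray,
    candidates: list[NoduleCandidate],
    intensity_threshold: float = 0.5,
    radius_policy: str = "equiv",
    fixed_radius: float | None = None,
    age: float | None = None,
) -> list[FeatureRow]:
    """Filter candidates by regional mean intensity and build feature rows.

    Each candidate's probe radius is half its equivalent diameter
    (``radius_policy="equiv"``, the default) or ``fixed_radius``
    (``radius_policy="fixed"``).  A candidate survives iff its circular
    mean intensity strictly exceeds ``intensity_threshold``; raising the
    threshold can only remove rows.
    """
    img = as_gray_raster(img)
    if not (0.0 <= intensity_threshold <= 1.0):
        raise ValueError("intensity_threshold must lie in [0, 1]")
    if radius_policy not in ("equiv", "fixed"):
        raise ValueError("radius_policy must be 'equiv' or 'fixed'")
    if radius_policy == "fixed" and (fixed_radius is None or fixed_radius < 0):
        raise ValueError("fixed radius_policy requires a non-negative fixed_radius")
    if age is not None and age < 0:
        raise ValueError("age must be non-negative")
    rows: list[FeatureRow] = []
    for cand in candidates:
        radius = cand.equiv_diameter / 2.0 if radius_policy == "equiv" else fixed_radius
        mean = circular_mean_intensity(img, cand.center, radius)
        if mean > intensity_threshold:
            rows.append(
                FeatureRow(
                    candidate_id=cand.id,
                    center=cand.center,
                    mean_intensity=mean,
                    size=cand.area,
                    shape=cand.shape,
                    age=age,
                )
            )
    return rows


def features_to_frame(rows: list[FeatureRow]) -> pd.DataFrame:
    """Feature rows as a DataFrame with the on-disk CSV schema."""
    return pd.DataFrame(
        {
            "candidate_id": [r.candidate_id for r in rows],
            "row": [r.center[0] for r in rows],
            "col": [r.center[1] for r in rows],
            "mean_intensity": [r.mean_intensity for r in rows],
            "area_px": [r.size for r in rows],
            "shape": [r.shape for r in rows],
            "age": [r.age for r in rows],
        }
    )
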