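"""Seeded synthetic CT-slice phantoms with exact ground truth.

Each phantom emulates the regime the detection chain targets: a dark
background, a handful of bright nodules a few pixels across (spherical or
elliptical; malignant ones larger and slightly brighter), thin bright
polylines standing in for lung borders and vessels (the dominant
false-positive source), and additive Gaussian noise.  Every nodule's
centre, diameter, shape class, and malignancy label is recorded, along
with a binary mask of nodule pixels, so every pipeline stage can be scored
objectively.

All randomness flows from the spec's seed; one seed yields one byte
stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PhantomSpec", "TrueNodule", "GroundTruth", "generate_phantom", "standard_suite"]

# Elongation of elliptical nodules (major/minor axis ratio).  Mildly oval:
# clearly above the 1.5 bounding-box aspect that separates the spherical
# from the elliptical shape class, while keeping the minor axis wide
# enough that the smallest nodules stay solid, plateau-interior blobs.
ELLIPSE_ASPECT = 1.8


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; the defaults define the standard test regime.

    Nodule diameters sit in 3-5 px so candidates fall under the 5-pixel
    detection ceiling; contrast 0.5 over a 0.2 background with noise sigma
    0.02 gives sharply visible blobs without being noise-free.  Malignant
    nodules draw from the upper half of the diameter range and get 10%
    extra contrast.
    """

    height: int = 256
    width: int = 256
    n_nodules: int = 6
    diameter_range: tuple[float, float] = (3.0, 5.0)
    elliptical_fraction: float = 0.3
    contrast: float = 0.5
    background_level: float = 0.2
    noise_sigma: float = 0.02
    n_lines: int = 3
    malignant_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be positive")
        if self.n_nodules < 0 or self.n_lines < 0:
            raise ValueError("n_nodules and n_lines must be non-negative")
        dmin, dmax = self.diameter_range
        if not (0 < dmin <= dmax):
            raise ValueError("diameter_range must satisfy 0 < min <= max")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must lie in (0, 1]")
        if not (0.0 <= self.background_level < 1.0):
            raise ValueError("background_level must lie in [0, 1)")
        if self.background_level + self.contrast > 1.0:
            raise ValueError("background_level + contrast must not exceed 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("elliptical_fraction", "malignant_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class TrueNodule:
    center: tuple[int, int]
    diameter: float
    shape: str  # "spherical" | "elliptical"
    label: str  # "benign" | "malignant"


@dataclass
class GroundTruth:
    nodules: list[TrueNodule] = field(default_factory=list)
    mask: np.ndarray | None = None  # bool raster of nodule pixels


def _nodule_coverage(
    shape: tuple[int, int],
    center: tuple[float, float],
    r_major: float,
    r_minor: float,
    angle: float,
) -> np.ndarray:
    """Per-pixel coverage of an anti-aliased filled ellipse in [0, 1].

    The profile is a plateau with a roughly half-pixel soft rim: coverage
    is 0.5 exactly on the ellipse boundary and saturates to 1 about half a
    pixel inside it, so even the smallest nodules keep a solid plateau
    interior rather than a fully graded profile.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (dr * ca + dc * sa) / r_major
    v = (-dr * sa + dc * ca) / r_minor
    rho = np.sqrt(u**2 + v**2)
    return np.clip(0.5 + (1.0 - rho) * 2.0 * r_minor, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one phantom and its ground truth.

    Nodule placement is rejection-sampled so that no two nodules come
    within 3 px of touching and none clips the border; a spec that cannot
    be placed within 1000 attempts per nodule raises.  Lines are likewise
    re-sampled until they keep clear of every nodule, so nodule components
    stay isolated in the ideal edge image.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.full((h, w), spec.background_level, dtype=np.float64)
    mask = np.zeros((h, w), dtype=bool)
    dmin, dmax = spec.diameter_range
    dmid = (dmin + dmax) / 2.0

    n_mal = int(round(spec.malignant_fraction * spec.n_nodules))
    labels = ["malignant"] * n_mal + ["benign"] * (spec.n_nodules - n_mal)
    labels = [labels[i] for i in rng.permutation(spec.n_nodules)]

    nodules: list[TrueNodule] = []
    placed: list[tuple[float, float, float]] = []  # row, col, diameter
    for label in labels:
        if label == "malignant":
            diameter = float(rng.uniform(dmid, dmax))
            contrast = min(spec.contrast * 1.1, 1.0 - spec.background_level)
        else:
            diameter = float(rng.uniform(dmin, dmid))
            contrast = spec.contrast
        shape_cls = "elliptical" if rng.random() < spec.elliptical_fraction else "spherical"
        angle = float(rng.uniform(0.0, np.pi)) if shape_cls == "elliptical" else 0.0
        margin = diameter / 2.0 * np.sqrt(ELLIPSE_ASPECT) + 2.0
        for attempt in range(1000):
            r = float(rng.uniform(margin, h - margin))
            c = float(rng.uniform(margin, w - margin))
            if all(
                np.hypot(r - pr, c - pc) >= (diameter + pd) / 2.0 + 3.0
                for pr, pc, pd in placed
            ):
                break
        else:
            raise RuntimeError(
                "could not place all nodules without overlap; "
                "reduce n_nodules or diameter_range"
            )
        # `diameter` is the area-equivalent diameter for both shape
        # classes, matching the detector's size measure; an ellipse
        # preserves the area of the equally-sized disk.
        if shape_cls == "elliptical":
            r_major = diameter / 2.0 * np.sqrt(ELLIPSE_ASPECT)
            r_minor = diameter / 2.0 / np.sqrt(ELLIPSE_ASPECT)
        else:
            r_major = r_minor = diameter / 2.0
        cov = _nodule_coverage((h, w), (r, c), r_major, r_minor, angle)
        img = np.maximum(img, spec.background_level + contrast * cov)
        mask |= cov >= 0.5
        placed.append((r, c, diameter))
        nodules.append(
            TrueNodule(
                center=(int(round(r)), int(round(c))),
                diameter=diameter,
                shape=shape_cls,
                label=label,
            )
        )

    line_level = min(spec.background_level + spec.contrast, 1.0)
    for _ in range(spec.n_lines):
        for attempt in range(1000):
            pts = _sample_polyline(rng, h, w)
            rows, cols = _rasterize_polyline(pts)
            if _clear_of_nodules(rows, cols, placed):
                img[rows, cols] = line_level
                break
        # A line that cannot avoid every nodule is silently dropped; lines
        # are decoys, not ground truth.

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    img = np.clip(img, 0.0, 1.0)
    return img, GroundTruth(nodules=nodules, mask=mask)


def _sample_polyline(rng: np.random.Generator, h: int, w: int) -> list[tuple[int, int]]:
    r = float(rng.uniform(0, h - 1))
    c = float(rng.uniform(0, w - 1))
    theta = float(rng.uniform(0, 2 * np.pi))
    pts = [(int(round(r)), int(round(c)))]
    for _ in range(3):
        length = float(rng.uniform(15, 30))
        theta += float(rng.uniform(-0.6, 0.6))
        r = float(np.clip(r + length * np.sin(theta), 0, h - 1))
        c = float(np.clip(c + length * np.cos(theta), 0, w - 1))
        pts.append((int(round(r)), int(round(c))))
    return pts


def _rasterize_polyline(pts: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    from skimage.draw import line

    rows, cols = [], []
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(r0, c0, r1, c1)
        rows.append(rr)
        cols.append(cc)
    return np.concatenate(rows), np.concatenate(cols)


def _clear_of_nodules(
    rows: np.ndarray, cols: np.ndarray, placed: list[tuple[float, float, float]]
) -> bool:
    for pr, pc, pd in placed:
        if np.min(np.hypot(rows - pr, cols - pc)) < pd / 2.0 + 4.0:
            return False
    return True


def standard_suite(
    n_images: int = 10, base_seed: int = 0, spec: PhantomSpec | None = None
) -> list[tuple[np.ndarray, GroundTruth]]:
    """The fixed multi-phantom benchmark: default spec, seeds base_seed+i."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if spec is None:
        spec = PhantomSpec()
    return [generate_phantom(replace(spec, seed=base_seed + i)) for i in range(n_images)]
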