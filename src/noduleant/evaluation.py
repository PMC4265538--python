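"""Detection scoring: recall ratio, sensitivity, specificity, accuracy, precision.

Two granularities are supported.  *Object mode* matches detected
candidates to true nodules one-to-one by centre distance; unmatched
candidates are false positives, unmatched truths false negatives, and no
true-negative class exists (accuracy falls back to the Jaccard-style
``tp/(tp+fp+fn)``).  *Pixel mode* compares two binary masks per pixel and
therefore has the true negatives that specificity and the conventional
accuracy need.

The recall ratio is the number of detected candidates divided by the
number of true nodules.  It deliberately may exceed 1: an over-detecting
method reports more candidates than there are nodules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nodule_candidates import NoduleCandidate
from .raster_io import as_edge_map

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "match_objects",
    "pixel_confusion",
    "compute_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int | None = None  # defined in pixel mode only

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be >= 0")


@dataclass(frozen=True)
class MetricReport:
    """Undefined metrics (zero denominator) are None, never divided."""

    recall_ratio: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "recall_ratio": self.recall_ratio,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
        }


def match_objects(
    candidates: list[NoduleCandidate],
    truth_centers: np.ndarray,
    max_dist: float | np.ndarray | None = None,
    truth_diameters: np.ndarray | None = None,
) -> ConfusionCounts:
    """Greedy one-to-one matching of candidates to true nodules.

    Candidate/truth pairs are considered in order of ascending centre
    distance (candidate index, then truth index, break exact ties); a pair
    within ``max_dist`` becomes a true positive and removes both parties.
    ``max_dist`` may be a scalar, a per-truth array, or None, in which
    case each truth's own radius (``truth_diameters / 2``) is used so the
    tolerance scales with nodule size.
    """
    truth_centers = np.asarray(truth_centers, dtype=np.float64).reshape(-1, 2)
    n_truth = truth_centers.shape[0]
    if max_dist is None:
        if truth_diameters is None:
            raise ValueError("provide max_dist or truth_diameters")
        limits = np.asarray(truth_diameters, dtype=np.float64) / 2.0
    else:
        limits = np.broadcast_to(np.asarray(max_dist, dtype=np.float64), (n_truth,))
    if n_truth and np.any(limits <= 0):
        raise ValueError("max_dist must be > 0")

    if not candidates or n_truth == 0:
        return ConfusionCounts(tp=0, fp=len(candidates), fn=n_truth)

    cand_centers = np.array([c.center for c in candidates], dtype=np.float64)
    dist = np.sqrt(((cand_centers[:, None, :] - truth_centers[None, :, :]) ** 2).sum(axis=2))
    pairs = [
        (dist[i, j], i, j)
        for i in range(len(candidates))
        for j in range(n_truth)
        if dist[i, j] <= limits[j]
    ]
    pairs.sort()
    cand_free = np.ones(len(candidates), dtype=bool)
    truth_free = np.ones(n_truth, dtype=bool)
    tp = 0
    for _, i, j in pairs:
        if cand_free[i] and truth_free[j]:
            cand_free[i] = truth_free[j] = False
            tp += 1
    return ConfusionCounts(tp=tp, fp=int(cand_free.sum()), fn=int(truth_free.sum()))


def pixel_confusion(detected_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Per-pixel contingency of detected vs true foreground."""
    det = as_edge_map(detected_mask)
    tru = as_edge_map(truth_mask)
    if det.shape != tru.shape:
        raise ValueError(f"shape mismatch: {det.shape} vs {tru.shape}")
    return ConfusionCounts(
        tp=int(np.sum(det & tru)),
        fp=int(np.sum(det & ~tru)),
        fn=int(np.sum(~det & tru)),
        tn=int(np.sum(~det & ~tru)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(
    counts: ConfusionCounts, n_detected: int, n_truth: int
) -> MetricReport:
    """Derive the five measures from a confusion table.

    In object mode (``tn`` absent) specificity is undefined and accuracy is
    ``tp/(tp+fp+fn)``; in pixel mode accuracy is the conventional
    ``(tp+tn)/total``.  Any zero denominator leaves that metric undefined.
    """
    if n_detected < 0 or n_truth < 0:
        raise ValueError("counts must be non-negative")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if tn is None:
        accuracy = _ratio(tp, tp + fp + fn)
        specificity = None
    else:
        accuracy = _ratio(tp + tn, tp + tn + fp + fn)
        specificity = _ratio(tn, tn + fp)
    return MetricReport(
        recall_ratio=(n_detected / n_truth) if n_truth > 0 else None,
        sensitivity=_ratio(tp, tp + fn),
        specificity=specificity,
        accuracy=accuracy,
        precision=_ratio(tp, tp + fp),
    )
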