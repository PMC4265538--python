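"""End-to-end orchestration: edges -> candidates -> features -> clusters -> score.

`run_pipeline` executes the whole detection chain on one raster with a
fully resolved :class:`RunConfig`; `compare_methods` runs several edge
detectors over a phantom suite and tabulates the pooled detection metrics
per method, one row each — the shape used to compare the seven detectors.

Every run can persist its stage outputs plus a ``manifest.json`` capturing
the resolved configuration, package version, and seed, so a run can be
replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aco_engine import AcoParams, aco_edges
from .aco_variants import logical_aco, refined_aco, variant_aco
from .baseline_edges import (
    RegionGrowParams,
    otsu_edges,
    region_growing_edges,
    watershed_edges,
)
from .clustering import GAKMeans, feature_array, hierarchical_cluster, label_malignancy
from .evaluation import ConfusionCounts, MetricReport, compute_metrics, match_objects
from .features import FeatureRow, build_feature_matrix, features_to_frame
from .nodule_candidates import DetectionConfig, NoduleCandidate, detect_candidates
from .phantom import GroundTruth
from .raster_io import as_gray_raster, save_edge_map

__all__ = ["METHODS", "RunConfig", "PipelineResult", "detect_edges", "run_pipeline", "compare_methods"]

METHODS = ("otsu", "watershed", "region", "aco", "refined-aco", "logical-aco", "variant-aco")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved parameters of one pipeline run."""

    method: str = "variant-aco"
    aco: AcoParams = AcoParams()
    max_rounds: int = 4
    tol: float = 0.01
    n_smooth: int = 1
    region_seed: tuple[int, int] = (0, 0)
    region_tolerance: float = 0.1
    detection: DetectionConfig = DetectionConfig()
    intensity_threshold: float = 0.5
    radius_policy: str = "equiv"
    fixed_radius: float | None = None
    age: float | None = None
    cluster_algo: str = "ga"
    k: int = 2
    population: int = 20
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    elitism: int = 1
    max_dist: float | None = None  # None: per-truth radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; valid: {', '.join(METHODS)}")
        if self.cluster_algo not in ("ga", "hier"):
            raise ValueError("cluster_algo must be 'ga' or 'hier'")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        return d


def detect_edges(img: np.ndarray, cfg: RunConfig) -> np.ndarray:
    """Dispatch to the configured edge detector (seeded from cfg.seed)."""
    img = as_gray_raster(img)
    aco = replace(cfg.aco, seed=cfg.seed)
    if cfg.method == "otsu":
        return otsu_edges(img)
    if cfg.method == "watershed":
        return watershed_edges(img, n_smooth=cfg.n_smooth)
    if cfg.method == "region":
        return region_growing_edges(
            img, RegionGrowParams(seed=cfg.region_seed, intensity_tolerance=cfg.region_tolerance)
        )
    if cfg.method == "aco":
        return aco_edges(img, aco)
    if cfg.method == "refined-aco":
        return refined_aco(img, aco, max_rounds=cfg.max_rounds, tol=cfg.tol).final
    if cfg.method == "logical-aco":
        run = refined_aco(img, aco, max_rounds=max(cfg.max_rounds, 2), tol=cfg.tol)
        if len(run.rounds) < 2:
            raise RuntimeError("refined run converged in one round; logical ACO undefined")
        return logical_aco(run.final, run.prefinal)
    if cfg.method == "variant-aco":
        return variant_aco(img, aco)
    raise ValueError(f"unknown method {cfg.method!r}")


@dataclass
class PipelineResult:
    edges: np.ndarray
    candidates: list[NoduleCandidate]
    features: list[FeatureRow]
    clusters: pd.DataFrame = field(default_factory=pd.DataFrame)
    counts: ConfusionCounts | None = None
    report: MetricReport | None = None


def _cluster(rows: list[FeatureRow], cfg: RunConfig) -> pd.DataFrame:
    frame = pd.DataFrame({"candidate_id": [r.candidate_id for r in rows]})
    if len(rows) < max(cfg.k, 2):
        frame["cluster"] = range(len(rows))
        frame["label"] = "unclustered"
        return frame
    X = feature_array(rows)
    if cfg.cluster_algo == "ga":
        model = GAKMeans(
            n_clusters=cfg.k,
            population=cfg.population,
            generations=cfg.generations,
            crossover_prob=cfg.crossover_prob,
            mutation_prob=cfg.mutation_prob,
            elitism=cfg.elitism,
            random_state=cfg.seed,
        )
        labels = model.fit_predict(X)
    else:
        from .clustering import standardize

        labels = hierarchical_cluster(standardize(X)[0], cfg.k)
    frame["cluster"] = labels
    if cfg.k == 2 and len(np.unique(labels)) == 2:
        sizes = np.array([r.size for r in rows], dtype=float)
        intens = np.array([r.mean_intensity for r in rows], dtype=float)
        names = label_malignancy(labels, sizes, intens)
        frame["label"] = [names[int(l)] for l in labels]
    else:
        frame["label"] = [str(int(l)) for l in labels]
    return frame


def run_pipeline(
    cfg: RunConfig,
    img: np.ndarray,
    truth: GroundTruth | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run edge detection through clustering (and scoring, given truth)."""
    img = as_gray_raster(img)
    edges = detect_edges(img, cfg)
    candidates = detect_candidates(edges, cfg.detection)
    rows = build_feature_matrix(
        img,
        candidates,
        intensity_threshold=cfg.intensity_threshold,
        radius_policy=cfg.radius_policy,
        fixed_radius=cfg.fixed_radius,
        age=cfg.age,
    )
    result = PipelineResult(edges=edges, candidates=candidates, features=rows)
    result.clusters = _cluster(rows, cfg)
    if truth is not None:
        surviving = [c for c in candidates if any(r.candidate_id == c.id for r in rows)]
        centers = np.array([n.center for n in truth.nodules], dtype=float).reshape(-1, 2)
        diameters = np.array([n.diameter for n in truth.nodules], dtype=float)
        result.counts = match_objects(
            surviving, centers, max_dist=cfg.max_dist,
            truth_diameters=diameters if cfg.max_dist is None else None,
        )
        result.report = compute_metrics(result.counts, len(surviving), len(truth.nodules))
    if outdir is not None:
        _persist(Path(outdir), cfg, result)
    return result


def candidates_to_frame(candidates: list[NoduleCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in candidates],
            "row": [c.center[0] for c in candidates],
            "col": [c.center[1] for c in candidates],
            "area_px": [c.area for c in candidates],
            "equiv_diameter": [c.equiv_diameter for c in candidates],
            "shape": [c.shape for c in candidates],
        }
    )


def _persist(outdir: Path, cfg: RunConfig, result: PipelineResult) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    save_edge_map(result.edges, outdir / "edges.png")
    candidates_to_frame(result.candidates).to_csv(outdir / "candidates.csv", index=False)
    features_to_frame(result.features).to_csv(outdir / "features.csv", index=False)
    result.clusters.to_csv(outdir / "clusters.csv", index=False)
    if result.report is not None:
        payload = {"mode": "object", **dataclasses.asdict(result.counts), **result.report.as_dict()}
        (outdir / "report.json").write_text(json.dumps(payload, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(cfg.to_manifest(), indent=2))


def compare_methods(
    suite: list[tuple[np.ndarray, GroundTruth]],
    methods: list[str] | tuple[str, ...] = METHODS,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """One row of pooled detection metrics per edge-detection method.

    Confusion counts are pooled (summed) over the suite before the metrics
    are computed; ``fp_total`` carries the raw pooled false positives so
    methods can be ranked on over-detection directly.
    """
    if cfg is None:
        cfg = RunConfig()
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; valid: {', '.join(METHODS)}")
    records = []
    for method in methods:
        mcfg = replace(cfg, method=method)
        tp = fp = fn = n_det = n_tru = 0
        for img, truth in suite:
            res = run_pipeline(mcfg, img, truth=truth)
            tp += res.counts.tp
            fp += res.counts.fp
            fn += res.counts.fn
            n_det += res.counts.tp + res.counts.fp
            n_tru += len(truth.nodules)
        report = compute_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn), n_det, n_tru)
        records.append({"method": method, **report.as_dict(), "fp_total": fp})
    return pd.DataFrame.from_records(
        records,
        columns=["method", "recall_ratio", "sensitivity", "specificity",
                 "accuracy", "precision", "fp_total"],
    )
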