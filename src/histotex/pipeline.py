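"""End-to-end orchestration: image -> segmentation -> texture features ->
clustering -> evaluation -> overlays, plus the patch-size sensitivity sweep.

Every run is deterministic given (image, config, seed): clustering
restarts derive their streams from the single config seed, and all
outputs are written as plain CSV/JSON/PNG so two identical runs produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import image_io
from .clustering import (
    ElbowResult,
    GMMModel,
    KMeansModel,
    elbow_select,
    gmm_fit,
    kmeans_fit,
    standardize,
)
from .errors import HistotexError
from .evaluation import AgreementReport, EvaluationReport, compare_labelings, evaluate_clustering
from .segmentation import foreground_mask, histogram, otsu_threshold, tile_patches
from .texture import FeatureTable, GLCMConfig, featurize_patchset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_sweep", "SWEEP_COLUMNS"]

logger = logging.getLogger(__name__)

SWEEP_COLUMNS = ["Size", "K", "Silhouette Score", "Davies-Bouldin Index", "ARI", "NMI"]


@dataclass
class PipelineConfig:
    """All knobs of one analysis run.

    ``k`` is either a fixed cluster count or "auto" for elbow selection
    over [k_min, k_max]. ``sweep_sizes`` drives the patch-size
    sensitivity analysis.
    """

    seed: int
    patch_size: int = 50
    retention: float = 0.5
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    k: Union[int, str] = "auto"
    k_min: int = 1
    k_max: int = 10
    n_init: int = 10
    standardize: bool = True
    methods: tuple[str, ...] = ("kmeans", "gmm")
    sweep_sizes: tuple[int, ...] = (30, 50, 75, 100, 150)
    overlay_alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")
        if list(self.sweep_sizes) != sorted(self.sweep_sizes) or any(
            s < 2 for s in self.sweep_sizes
        ):
            raise ValueError("sweep_sizes must be sorted and all >= 2")
        unknown = set(self.methods) - {"kmeans", "gmm"}
        if unknown:
            raise ValueError(f"unknown clustering methods: {sorted(unknown)}")

    def to_dict(self) -> dict:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        return _plain(dataclasses.asdict(self))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "glcm" in raw:
            g = raw["glcm"]
            if "angles" in g:
                g["angles"] = tuple(g["angles"])
            raw["glcm"] = GLCMConfig(**g)
        for key in ("methods", "sweep_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    threshold: int
    n_patches: int
    k: int
    features: FeatureTable
    features_used: FeatureTable  # after optional standardization
    elbow: ElbowResult | None
    models: dict[str, Union[KMeansModel, GMMModel]]
    labels: dict[str, np.ndarray]
    reports: dict[str, EvaluationReport]
    agreement: AgreementReport | None
    patch_grid_cells: list[tuple[int, int]]

    def summary(self) -> dict:
        out: dict = {
            "threshold": self.threshold,
            "n_patches": self.n_patches,
            "k": self.k,
            "methods": {m: r.to_dict() for m, r in self.reports.items()},
        }
        if self.elbow is not None:
            out["elbow"] = {
                "k_range": self.elbow.k_range.tolist(),
                "wcss": self.elbow.wcss_curve.tolist(),
                "selected_k": self.elbow.selected_k,
            }
        if self.agreement is not None:
            out["agreement"] = self.agreement.to_dict()
        return out


def _load_grayscale(img: Union[str, os.PathLike, np.ndarray]) -> np.ndarray:
    if isinstance(img, np.ndarray):
        arr = img
    else:
        arr = image_io.read_image(img)
    return image_io.to_grayscale(arr) if arr.ndim == 3 else arr


def run_pipeline(
    img: Union[str, os.PathLike, np.ndarray],
    cfg: PipelineConfig,
    outdir: str | os.PathLike | None = None,
) -> PipelineResult:
    """Execute the full analysis on one image.

    Stages: grayscale conversion, Otsu foreground segmentation, patch
    tiling, per-patch co-occurrence features, optional standardization,
    elbow selection (if k="auto"), k-means and/or GMM clustering,
    internal quality indices per method and agreement indices between
    methods. With ``outdir`` set, all intermediate tables, the mask and
    per-method overlays are written there.
    """
    gray = _load_grayscale(img)
    logger.info("segmenting %dx%d image", *gray.shape)
    t = otsu_threshold(histogram(gray))
    mask = foreground_mask(gray, t)
    ps = tile_patches(gray, mask, cfg.patch_size, cfg.retention)
    if len(ps) == 0:
        raise HistotexError(
            "no foreground patches: the image appears to contain no tissue "
            f"at patch size {cfg.patch_size}"
        )
    logger.info("threshold %d, %d foreground patches", t, len(ps))
    ft = featurize_patchset(ps, cfg.glcm)
    used = standardize(ft) if cfg.standardize else ft

    elbow = None
    if cfg.k == "auto":
        k_max = min(cfg.k_max, len(used))
        if k_max < cfg.k_min + 2:
            raise HistotexError(
                f"too few patches (n={len(used)}) for elbow selection over "
                f"k in [{cfg.k_min}, {cfg.k_max}]"
            )
        elbow = elbow_select(used, cfg.k_min, k_max, seed=cfg.seed, n_init=cfg.n_init)
        k = elbow.selected_k
        logger.info("elbow-selected k = %d", k)
    else:
        k = int(cfg.k)

    models: dict[str, Union[KMeansModel, GMMModel]] = {}
    labels: dict[str, np.ndarray] = {}
    reports: dict[str, EvaluationReport] = {}
    for method in cfg.methods:
        if method == "kmeans":
            model = kmeans_fit(used, k, seed=cfg.seed, n_init=cfg.n_init)
        else:
            model = gmm_fit(used, k, seed=cfg.seed, n_init=cfg.n_init)
        models[method] = model
        labels[method] = model.labels
        reports[method] = evaluate_clustering(used.X, model.labels)

    agreement = None
    if "kmeans" in labels and "gmm" in labels:
        agreement = compare_labelings(labels["kmeans"], labels["gmm"])

    result = PipelineResult(
        config=cfg,
        threshold=int(t),
        n_patches=len(ps),
        k=k,
        features=ft,
        features_used=used,
        elbow=elbow,
        models=models,
        labels=labels,
        reports=reports,
        agreement=agreement,
        patch_grid_cells=ps.grid_cells,
    )
    if outdir is not None:
        _write_outputs(gray, mask.flags, result, outdir)
    return result


def _write_outputs(gray: np.ndarray, mask_flags: np.ndarray, res: PipelineResult, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    out = lambda name: os.path.join(outdir, name)  # noqa: E731
    image_io.write_image((mask_flags * 255).astype(np.uint8), out("mask.png"))
    image_io.export_table(res.features.to_frame(), out("features.csv"))
    for method, lab in res.labels.items():
        df = pd.DataFrame(res.patch_grid_cells, columns=["grid_row", "grid_col"])
        df["label"] = lab
        image_io.export_table(df, out(f"labels_{method}.csv"))
        ov = image_io.OverlayImage(
            base=gray,
            patch_size=res.config.patch_size,
            patch_labels={cell: int(l) for cell, l in zip(res.patch_grid_cells, lab)},
            alpha=res.config.overlay_alpha,
        )
        image_io.render_overlay(ov, out(f"overlay_{method}.png"))
    if res.elbow is not None:
        elbow_df = pd.DataFrame(
            {
                "k": res.elbow.k_range,
                "wcss": res.elbow.wcss_curve,
                "curvature": [
                    res.elbow.curvature_scores.get(int(k), float("nan"))
                    for k in res.elbow.k_range
                ],
            }
        )
        image_io.export_table(elbow_df, out("elbow.csv"))
    with open(out("report.json"), "w") as fh:
        json.dump(res.summary(), fh, indent=2)
        fh.write("\n")
    with open(out("config.yaml"), "w") as fh:
        yaml.safe_dump(res.config.to_dict(), fh, sort_keys=True)


def run_sweep(
    img: Union[str, os.PathLike, np.ndarray],
    cfg: PipelineConfig,
    outdir: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Repeat the full analysis at each patch size in ``cfg.sweep_sizes``.

    Each size re-tiles, re-featurizes, re-selects k (when k="auto") and
    refits with the same seed, so rows are independent replicates of the
    per-size analysis. A size that fails (e.g. too few patches) yields a
    row with status "failed" and NaN metrics; the sweep continues.
    """
    gray = _load_grayscale(img)
    rows = []
    for size in cfg.sweep_sizes:
        size_cfg = dataclasses.replace(cfg, patch_size=int(size))
        try:
            res = run_pipeline(gray, size_cfg)
        except (HistotexError, ValueError) as exc:
            logger.warning("sweep size %d failed: %s", size, exc)
            rows.append(
                {
                    "Size": size,
                    "K": np.nan,
                    "Silhouette Score": np.nan,
                    "Davies-Bouldin Index": np.nan,
                    "ARI": np.nan,
                    "NMI": np.nan,
                    "n_patches": np.nan,
                    "status": "failed",
                }
            )
            continue
        ref = res.reports.get("kmeans") or next(iter(res.reports.values()))
        rows.append(
            {
                "Size": size,
                "K": res.k,
                "Silhouette Score": ref.silhouette,
                "Davies-Bouldin Index": ref.davies_bouldin,
                "ARI": res.agreement.ari if res.agreement else np.nan,
                "NMI": res.agreement.nmi if res.agreement else np.nan,
                "n_patches": res.n_patches,
                "status": "ok",
            }
        )
    df = pd.DataFrame(rows, columns=SWEEP_COLUMNS + ["n_patches", "status"])
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        image_io.export_table(df, os.path.join(outdir, "sweep.csv"))
    return df
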