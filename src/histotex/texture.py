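"""Gray-level co-occurrence matrices and Haralick texture descriptors.

Each foreground patch is summarized by the four GLCM features used
throughout quantitative histopathology: contrast, correlation, energy
and homogeneity. The co-occurrence matrix is the normalized histogram of
gray-level pairs at a fixed pixel offset; its marginal structure captures
local contrast, granularity and periodicity of the tissue texture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .segmentation import PatchSet

__all__ = [
    "GLCMConfig",
    "GLCM",
    "TextureFeatures",
    "quantize",
    "compute_glcm",
    "texture_features",
    "featurize_patchset",
    "FeatureTable",
    "FEATURE_NAMES",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity")

# Offset (drow, dcol) per unit distance for each supported angle.
# 0 deg scans rightward along a row; 45/90/135 go up-right, up, up-left
# (the classic co-occurrence convention with row index increasing downward).
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMConfig:
    """Parameters of the co-occurrence computation.

    distance: offset magnitude in pixels.
    angles: subset of {0, 45, 90, 135} degrees.
    levels: number of gray levels L after requantization (2..256).
    symmetric: count each pair in both directions.
    aggregate: how per-angle feature values combine ("mean").
    """

    distance: int = 1
    angles: tuple[int, ...] = (0,)
    levels: int = 256
    symmetric: bool = False
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        if not 2 <= self.levels <= 256:
            raise ValueError(f"levels must be in [2, 256], got {self.levels}")
        if not self.angles:
            raise ValueError("at least one angle is required")
        bad = set(self.angles) - set(_ANGLE_OFFSETS)
        if bad:
            raise ValueError(f"unsupported angles {sorted(bad)}; allowed: 0, 45, 90, 135")
        if self.aggregate != "mean":
            raise ValueError(f"unsupported aggregate '{self.aggregate}'")


@dataclass
class GLCM:
    """Normalized co-occurrence distribution(s) for one patch.

    ``P`` sums counts over all configured angles and normalizes to 1;
    ``P_by_angle`` keeps one normalized L x L matrix per angle, which is
    what feature aggregation averages over.
    """

    P: np.ndarray
    P_by_angle: list[np.ndarray]
    config: GLCMConfig
    pair_count: int


def quantize(patch: np.ndarray, levels: int, bit_depth: int = 8) -> np.ndarray:
    """Uniform-width requantization of [0, 2^B - 1] into ``levels`` bins.

    q = floor(v * L / 2^B); with L = 2^B this is the identity.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    arr = np.asarray(patch, dtype=np.int64)
    return (arr * levels) // (2**bit_depth)


def _pair_counts(q: np.ndarray, levels: int, drow: int, dcol: int) -> np.ndarray:
    """Raw co-occurrence counts for a single offset, via array slicing."""
    h, w = q.shape
    r0, r1 = max(0, -drow), h - max(0, drow)
    c0, c1 = max(0, -dcol), w - max(0, dcol)
    if r1 <= r0 or c1 <= c0:
        return np.zeros((levels, levels), dtype=np.int64)
    i = q[r0:r1, c0:c1].ravel()
    j = q[r0 + drow : r1 + drow, c0 + dcol : c1 + dcol].ravel()
    return np.bincount(i * levels + j, minlength=levels * levels).reshape(levels, levels)


def compute_glcm(patch: np.ndarray, cfg: GLCMConfig = GLCMConfig()) -> GLCM:
    """Co-occurrence matrix of an already-quantized patch.

    For each configured angle, all pixel pairs (p, p + offset) with both
    endpoints inside the patch are counted; with ``symmetric`` the reversed
    pair is counted too. Counts are normalized to probability per angle,
    and also summed across angles into the overall ``P``.
    """
    q = np.asarray(patch, dtype=np.int64)
    L = cfg.levels
    if q.min() < 0 or q.max() >= L:
        raise ValueError(f"patch values must lie in [0, {L - 1}]; quantize first")
    per_angle_raw = []
    for ang in cfg.angles:
        dr, dc = _ANGLE_OFFSETS[ang]
        counts = _pair_counts(q, L, dr * cfg.distance, dc * cfg.distance)
        if cfg.symmetric:
            counts = counts + counts.T
        per_angle_raw.append(counts)
    total = int(sum(int(c.sum()) for c in per_angle_raw))
    if total == 0:
        raise DegenerateInputError(
            f"patch of shape {q.shape} has no valid pixel pair at distance "
            f"{cfg.distance} for angles {cfg.angles}"
        )
    P_by_angle = [
        c / c.sum() if c.sum() > 0 else np.zeros_like(c, dtype=float)
        for c in per_angle_raw
    ]
    P = sum(per_angle_raw) / total
    return GLCM(P=P, P_by_angle=P_by_angle, config=cfg, pair_count=total)


@dataclass(frozen=True)
class TextureFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float

    def as_array(self) -> np.ndarray:
        return np.array([self.contrast, self.correlation, self.energy, self.homogeneity])


def _features_one(P: np.ndarray) -> tuple[float, float, float, float]:
    L = P.shape[0]
    i = np.arange(L, dtype=float)[:, None]
    j = np.arange(L, dtype=float)[None, :]
    diff2 = (i - j) ** 2
    contrast = float((P * diff2).sum())
    homogeneity = float((P / (1.0 + diff2)).sum())
    energy = float(np.sqrt((P**2).sum()))
    pi, pj = P.sum(axis=1), P.sum(axis=0)
    mu_i = float((np.arange(L) * pi).sum())
    mu_j = float((np.arange(L) * pj).sum())
    var_i = float(((np.arange(L) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(L) - mu_j) ** 2 * pj).sum())
    if var_i < 1e-15 or var_j < 1e-15:
        # Degenerate marginal: the level sequence is perfectly predictable.
        correlation = 1.0
    else:
        cov = float((P * (i - mu_i) * (j - mu_j)).sum())
        correlation = cov / np.sqrt(var_i * var_j)
    return contrast, correlation, energy, homogeneity


def texture_features(g: GLCM) -> TextureFeatures:
    """The four Haralick descriptors, averaged over configured angles.

    contrast    = sum P(i,j) (i-j)^2
    correlation = sum P(i,j) (i-mu_i)(j-mu_j) / (sigma_i sigma_j)
    energy      = sqrt(sum P(i,j)^2)
    homogeneity = sum P(i,j) / (1 + (i-j)^2)

    A patch with a degenerate marginal (e.g. constant intensity) takes
    correlation = 1 by convention: its level sequence is perfectly
    predictable. This matters for near-constant background patches.
    """
    vals = np.array([_features_one(P) for P in g.P_by_angle])
    weights = np.array([float(P.sum()) for P in g.P_by_angle])
    keep = weights > 0
    c, r, e, h = vals[keep].mean(axis=0)
    return TextureFeatures(contrast=c, correlation=r, energy=e, homogeneity=h)


@dataclass
class FeatureTable:
    """Patches x features matrix with grid identifiers.

    Column order is fixed: contrast, correlation, energy, homogeneity.
    ``standardization`` holds per-column (mean, sd) after standardize().
    """

    ids: np.ndarray  # (n, 2) int: grid_row, grid_col
    X: np.ndarray  # (n, d) float
    column_names: tuple[str, ...] = FEATURE_NAMES
    standardized: bool = False
    standardization: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64).reshape(-1, 2)
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim == 1:
            self.X = self.X.reshape(len(self.ids), -1)
        if len(self.X) != len(self.ids):
            raise ValueError("ids and feature matrix disagree in length")
        if np.isnan(self.X).any():
            raise ValueError("feature table contains missing values")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ids, columns=["grid_row", "grid_col"])
        for name, col in zip(self.column_names, self.X.T):
            df[name] = col
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        feature_cols = [c for c in df.columns if c not in ("grid_row", "grid_col")]
        return cls(
            ids=df[["grid_row", "grid_col"]].to_numpy(),
            X=df[feature_cols].to_numpy(dtype=float),
            column_names=tuple(feature_cols),
        )


def featurize_patchset(ps: PatchSet, cfg: GLCMConfig = GLCMConfig()) -> FeatureTable:
    """One feature row per retained patch, in patch order."""
    if len(ps) == 0:
        logger.warning("empty patch set; returning an empty feature table")
        return FeatureTable(ids=np.empty((0, 2), dtype=np.int64), X=np.empty((0, 4)))
    rows, ids = [], []
    for p in ps.patches:
        q = quantize(p.pixels, cfg.levels)
        feats = texture_features(compute_glcm(q, cfg))
        rows.append(feats.as_array())
        ids.append((p.grid_row, p.grid_col))
    return FeatureTable(ids=np.array(ids), X=np.vstack(rows))
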