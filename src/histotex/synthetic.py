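"""Synthetic histology-like scenes with known tissue-region ground truth.

Real whole-slide scans of atherosclerotic plaques are large and rarely
shareable, so the test bed is a generated grayscale scene: a bright,
near-constant background (empty glass) plus K tissue regions, each
filled with a distinct stationary texture. The four default classes are
engineering caricatures of plaque components (fibrous tissue, dense
calcification, necrotic debris, layered/striped matrix): they differ in
local contrast, granularity and periodicity so that the four
co-occurrence features separate them, but they make no biological claim.

Geometry: the image is a grid of 150 x 150-pixel blocks. The leftmost
block column is background; the remaining blocks carry the K classes
round-robin. Because 150 is divisible by 30, 50, 75 and 150, patches at
those sizes never straddle a region boundary, so every retained patch
has a single true class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DegenerateInputError
from .evaluation import adjusted_rand_index, normalized_mutual_information
from .segmentation import PatchSet

__all__ = [
    "TextureSpec",
    "SyntheticScene",
    "DEFAULT_TEXTURES",
    "generate_scene",
    "truth_patch_labels",
    "score_recovery",
    "BLOCK",
]

BLOCK = 150  # region block side; divides patch sizes 30, 50, 75 and 150


@dataclass(frozen=True)
class TextureSpec:
    """A stationary grayscale texture: smoothed Gaussian noise, optionally
    plus horizontal sinusoidal stripes.

    base_mean: mean gray level of the region.
    base_sd: standard deviation of the noise field after smoothing.
    granularity: Gaussian smoothing radius in pixels (0 = white noise);
        larger values give coarser, blotchier texture.
    stripe_period / stripe_amplitude: optional periodic component along
        ``stripe_axis`` (0 = horizontal bands varying down the rows,
        1 = vertical bands varying across the columns). A period-2
        vertical stripe alternates adjacent columns, which drives the
        co-occurrence correlation of horizontal pixel pairs negative.
    """

    base_mean: float
    base_sd: float
    granularity: float = 0.0
    stripe_period: float | None = None
    stripe_amplitude: float = 0.0
    stripe_axis: int = 0


# Default class palette. All means sit well below the bright background so
# Otsu cleanly separates tissue, and the textures are chosen so the four
# standardized feature centroids are roughly equidistant (no pair of
# classes much closer than the rest): (1) fine faint speckle, (2) coarse
# smooth blobs, (3) faint fine check (negatively correlated neighbors),
# (4) strong noisy check, (5) smooth mid-scale blobs. Engineering
# caricatures of plaque tissue variety (fibrous, necrotic, calcified,
# layered), not biological models.
DEFAULT_TEXTURES: tuple[TextureSpec, ...] = (
    TextureSpec(base_mean=150.0, base_sd=5.0, granularity=0.0),
    TextureSpec(base_mean=100.0, base_sd=25.0, granularity=1.2),
    TextureSpec(base_mean=150.0, base_sd=4.0, granularity=0.0,
                stripe_period=2.0, stripe_amplitude=8.0, stripe_axis=1),
    TextureSpec(base_mean=120.0, base_sd=18.0, granularity=0.0,
                stripe_period=2.0, stripe_amplitude=8.0, stripe_axis=1),
    TextureSpec(base_mean=124.0, base_sd=18.0, granularity=3.0),
)

_BACKGROUND_MEAN = 245.0
_BACKGROUND_SD = 3.0


@dataclass
class SyntheticScene:
    """A generated grayscale image plus its per-pixel class truth.

    ``truth`` uses 0 for background and 1..K for tissue classes.
    """

    image: np.ndarray
    truth: np.ndarray
    params: dict = field(default_factory=dict)
    seed: int = 0


def _texture_field(shape: tuple[int, int], spec: TextureSpec, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if spec.granularity > 0:
        noise = gaussian_filter(noise, spec.granularity)
    sd = noise.std()
    if sd > 0:
        noise = noise / sd * spec.base_sd
    field_ = spec.base_mean + noise
    if spec.stripe_period:
        if spec.stripe_axis == 0:
            pos = np.arange(shape[0], dtype=float)[:, None]
        else:
            pos = np.arange(shape[1], dtype=float)[None, :]
        # Phase offset so a period-2 stripe alternates at full +/- amplitude.
        phase = 2 * np.pi * pos / spec.stripe_period + np.pi / 2
        field_ = field_ + spec.stripe_amplitude * np.sin(phase)
    return field_


def generate_scene(
    n_classes: int = 4,
    size: int = 600,
    seed: int = 0,
    textures: tuple[TextureSpec, ...] | None = None,
    background_mean: float = _BACKGROUND_MEAN,
    background_sd: float = _BACKGROUND_SD,
) -> SyntheticScene:
    """Lay out K textured regions on a bright background, deterministically.

    ``size`` must be a multiple of the 150-px block grid and large enough
    that, after reserving the leftmost block column for background, at
    least K tissue blocks remain (each class gets >= 1 full block, hence
    >= 1 full patch at every divisor patch size).
    """
    if n_classes < 1:
        raise ValueError(f"need n_classes >= 1, got {n_classes}")
    if size % BLOCK != 0 or size < 2 * BLOCK:
        raise ValueError(f"size must be a multiple of {BLOCK} and >= {2 * BLOCK}")
    if textures is None:
        textures = DEFAULT_TEXTURES
    if n_classes > len(textures):
        raise ValueError(
            f"{n_classes} classes requested but only {len(textures)} texture specs given"
        )
    nb = size // BLOCK
    tissue_blocks = [(r, c) for c in range(1, nb) for r in range(nb)]
    if n_classes > len(tissue_blocks):
        raise ValueError(
            f"{n_classes} regions cannot fit: only {len(tissue_blocks)} tissue "
            f"blocks available at size {size}"
        )
    rng = np.random.default_rng(seed)
    img = background_mean + background_sd * rng.standard_normal((size, size))
    truth = np.zeros((size, size), dtype=np.int64)
    for idx, (br, bc) in enumerate(tissue_blocks):
        cls = idx % n_classes + 1
        sl = (slice(br * BLOCK, (br + 1) * BLOCK), slice(bc * BLOCK, (bc + 1) * BLOCK))
        img[sl] = _texture_field((BLOCK, BLOCK), textures[cls - 1], rng)
        truth[sl] = cls
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticScene(
        image=image,
        truth=truth,
        params={
            "n_classes": n_classes,
            "size": size,
            "block": BLOCK,
            "background_mean": background_mean,
            "background_sd": background_sd,
            "textures": [vars(t) for t in textures[:n_classes]],
        },
        seed=seed,
    )


def truth_patch_labels(scene: SyntheticScene, ps: PatchSet) -> np.ndarray:
    """Project pixel-level truth onto the patch grid by majority vote.

    A patch is labeled by the majority class among its tissue pixels;
    patches whose pixels are mostly background get label 0.
    """
    if ps.image_shape != scene.truth.shape:
        raise ValueError("patch set was not tiled from this scene")
    out = np.empty(len(ps), dtype=np.int64)
    for i, p in enumerate(ps.patches):
        top, left, h, w = p.bbox
        cell = scene.truth[top : top + h, left : left + w]
        counts = np.bincount(cell.ravel(), minlength=1)
        if counts[0] > cell.size / 2 or counts[1:].sum() == 0:
            out[i] = 0
        else:
            out[i] = counts[1:].argmax() + 1
    return out


def score_recovery(scene: SyntheticScene, ps: PatchSet, labels) -> dict[str, float]:
    """ARI and NMI of predicted patch labels against the scene truth."""
    labels = np.asarray(labels).ravel()
    if len(labels) != len(ps):
        raise ValueError(
            f"{len(labels)} labels for {len(ps)} patches"
        )
    if len(ps) == 0:
        raise DegenerateInputError("cannot score an empty patch set")
    truth = truth_patch_labels(scene, ps)
    return {
        "ari": adjusted_rand_index(truth, labels),
        "nmi": normalized_mutual_information(truth, labels),
    }
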