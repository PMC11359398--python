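"""Foreground/background separation and patch tiling.

Otsu's method picks the gray level that maximizes the between-class
variance of the intensity histogram; tissue (the darker class under H&E,
where glass background is bright) becomes the foreground, which is then
cut into non-overlapping square patches on a grid anchored at the image
origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import DegenerateInputError

__all__ = [
    "histogram",
    "otsu_threshold",
    "ForegroundMask",
    "foreground_mask",
    "Patch",
    "PatchSet",
    "tile_patches",
]

logger = logging.getLogger(__name__)


def histogram(img: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Per-gray-level pixel counts, a vector of length ``2**bit_depth``."""
    arr = np.asarray(img)
    if arr.size == 0:
        raise DegenerateInputError("cannot histogram an empty image")
    return np.bincount(arr.ravel().astype(np.int64), minlength=2**bit_depth)


def otsu_threshold(counts: np.ndarray) -> int:
    """Otsu's optimal threshold on an integer intensity histogram.

    Returns the gray level t maximizing the between-class variance
    sigma_b^2(t) = w0 w1 (mu0 - mu1)^2, where class 0 holds levels <= t and
    class 1 levels > t. The scan is exhaustive over all candidate levels
    and evaluated in exact rational arithmetic, so ties are broken by the
    smallest t with no floating-point ambiguity.

    Raises
    ------
    DegenerateInputError
        If all histogram mass sits at a single level (no two classes).
    """
    c = np.asarray(counts, dtype=np.int64)
    if c.sum() <= 0:
        raise DegenerateInputError("histogram has no mass")
    if np.count_nonzero(c) < 2:
        raise DegenerateInputError(
            "histogram has mass at a single level; two classes do not exist"
        )
    levels = np.arange(c.size, dtype=np.int64)
    w0 = np.cumsum(c)  # pixels at levels <= t
    s0 = np.cumsum(c * levels)  # intensity sum of class 0
    total, s_total = int(w0[-1]), int(s0[-1])

    best_t, best_score = -1, Fraction(-1)
    for t in range(c.size - 1):
        n0, n1 = int(w0[t]), total - int(w0[t])
        if n0 == 0 or n1 == 0:
            continue
        # sigma_b^2 * total^2 = (s0*n1 - s1*n0)^2 / (n0*n1), exact
        s0t = int(s0[t])
        num = s0t * n1 - (s_total - s0t) * n0
        score = Fraction(num * num, n0 * n1)
        if score > best_score:
            best_score, best_t = score, t
    return best_t


@dataclass(frozen=True)
class ForegroundMask:
    """Boolean foreground flags, the Otsu threshold and polarity used.

    ``polarity`` is "le" when foreground pixels satisfy value <= threshold
    (the usual case: tissue is darker than the glass background) and "gt"
    otherwise.
    """

    flags: np.ndarray
    threshold: int
    polarity: str

    @property
    def foreground_count(self) -> int:
        return int(self.flags.sum())


def foreground_mask(img: np.ndarray, t: int) -> ForegroundMask:
    """Classify every pixel against threshold t, darker class = foreground.

    H&E tissue absorbs light while empty slide is bright, so the class
    with the lower mean intensity is taken as foreground regardless of
    which side of the threshold it falls on.
    """
    arr = np.asarray(img)
    low = arr <= t
    n_low = int(low.sum())
    n_high = arr.size - n_low
    if n_low == 0 or n_high == 0:
        # One-sided split: the populated side is foreground by default.
        polarity = "le" if n_low else "gt"
    else:
        mean_low = float(arr[low].mean())
        mean_high = float(arr[~low].mean())
        polarity = "le" if mean_low <= mean_high else "gt"
    flags = low if polarity == "le" else ~low
    return ForegroundMask(flags=flags, threshold=int(t), polarity=polarity)


@dataclass(frozen=True)
class Patch:
    grid_row: int
    grid_col: int
    bbox: tuple[int, int, int, int]  # (top, left, height, width), half-open
    pixels: np.ndarray
    foreground_fraction: float


@dataclass
class PatchSet:
    """Retained non-overlapping foreground tiles on a regular grid."""

    patch_size: int
    patches: list[Patch]
    retention_threshold: float
    image_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def grid_cells(self) -> list[tuple[int, int]]:
        return [(p.grid_row, p.grid_col) for p in self.patches]

    def pixel_stack(self) -> np.ndarray:
        """All retained patches as an (n, size, size) array."""
        return np.stack([p.pixels for p in self.patches])


def tile_patches(
    img: np.ndarray,
    mask: ForegroundMask,
    size: int,
    retention: float = 0.5,
) -> PatchSet:
    """Tile the image into size x size cells and keep foreground-rich ones.

    Cells are anchored at (0, 0); cells extending past the image edge are
    discarded rather than padded (padding would distort co-occurrence
    statistics). A cell is retained iff its foreground pixel fraction is
    >= ``retention``.
    """
    if size < 2:
        raise ValueError(f"patch size must be >= 2, got {size}")
    if not 0.0 < retention <= 1.0:
        raise ValueError(f"retention must be in (0, 1], got {retention}")
    arr = np.asarray(img)
    h, w = arr.shape
    if mask.flags.shape != (h, w):
        raise ValueError("mask dimensions do not match the image")
    n_rows, n_cols = h // size, w // size
    patches: list[Patch] = []
    for gr in range(n_rows):
        for gc in range(n_cols):
            top, left = gr * size, gc * size
            cell_mask = mask.flags[top : top + size, left : left + size]
            frac = float(cell_mask.mean())
            if frac >= retention:
                patches.append(
                    Patch(
                        grid_row=gr,
                        grid_col=gc,
                        bbox=(top, left, size, size),
                        pixels=arr[top : top + size, left : left + size].copy(),
                        foreground_fraction=frac,
                    )
                )
    if n_rows == 0 or n_cols == 0:
        logger.warning(
            "image %dx%d is smaller than one %dx%d patch; no patches produced",
            h, w, size, size,
        )
    return PatchSet(
        patch_size=size,
        patches=patches,
        retention_threshold=retention,
        image_shape=(h, w),
    )
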