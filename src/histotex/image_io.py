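"""Raster image input/output, grayscale conversion and cluster overlays.

Images are plain numpy arrays: a grayscale ("raster") image is a 2-D
``uint8`` array, a color image is an ``(H, W, 3)`` ``uint8`` array.
PNG and single-resolution TIFF are supported for reading and writing;
JPEG is accepted on read only, because its lossy round-trip would break
downstream texture statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "read_image",
    "write_image",
    "to_grayscale",
    "OverlayImage",
    "render_overlay",
    "export_table",
    "DEFAULT_PALETTE",
]

# ITU-R BT.709 luma weights, the convention of mainstream image stacks.
_LUMA_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])

# Colorblind-safe categorical palette (Okabe–Ito, 8 colors).
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (230, 159, 0),
    (86, 180, 233),
    (0, 158, 115),
    (240, 228, 66),
    (0, 114, 178),
    (213, 94, 0),
    (204, 121, 167),
    (0, 0, 0),
)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file into a uint8 array.

    Single-channel files yield a 2-D grayscale array; multi-channel files
    yield an ``(H, W, 3)`` RGB array (any alpha channel is dropped).

    Raises
    ------
    IOError
        If the file does not exist or cannot be decoded.
    DegenerateInputError
        If the decoded image has zero pixels.
    """
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("1", "I", "I;16", "F"):
                im = im.convert("L")
            if im.mode in ("RGBA", "P", "CMYK", "LA"):
                im = im.convert("RGB") if im.mode != "LA" else im.convert("L")
            arr = np.asarray(im)
    except FileNotFoundError:
        raise IOError(f"image file not found: {path}") from None
    except UnidentifiedImageError as exc:
        raise IOError(f"cannot decode image file: {path}") from exc
    if arr.size == 0:
        raise DegenerateInputError(f"zero-size image: {path}")
    if arr.ndim == 3:
        arr = arr[..., :3]
    return np.ascontiguousarray(arr.astype(np.uint8))


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a grayscale or RGB uint8 array to PNG or TIFF.

    JPEG output is refused: its lossy compression breaks the lossless
    read/write round-trip the rest of the pipeline relies on.
    """
    ext = os.path.splitext(os.fspath(path))[1].lower()
    if ext in (".jpg", ".jpeg"):
        raise ConfigurationError("JPEG output is not supported (lossy); use PNG or TIFF")
    arr = np.asarray(img, dtype=np.uint8)
    Image.fromarray(arr).save(path)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an ``(H, W, 3)`` RGB array to grayscale with BT.709 luma.

    Y = round(0.2125 R + 0.7154 G + 0.0721 B), clipped to [0, 255].
    A 2-D array is returned unchanged (already grayscale).
    """
    arr = np.asarray(img)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"expected (H, W, 3) color image, got shape {arr.shape}")
    y = arr[..., :3].astype(np.float64) @ _LUMA_WEIGHTS
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


@dataclass
class OverlayImage:
    """A grayscale base image with per-patch cluster colors blended on top.

    ``patch_labels`` maps patch grid cells ``(grid_row, grid_col)`` to
    integer cluster labels; cells are ``patch_size`` pixels square and
    anchored at the image origin.
    """

    base: np.ndarray
    patch_size: int
    patch_labels: Mapping[tuple[int, int], int]
    palette: Sequence[tuple[int, int, int]] = field(default=DEFAULT_PALETTE)
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0, 1], got {self.alpha}")
        h, w = self.base.shape[:2]
        for (gr, gc) in self.patch_labels:
            if (gr + 1) * self.patch_size > h or (gc + 1) * self.patch_size > w:
                raise ConfigurationError(
                    f"patch cell ({gr}, {gc}) at size {self.patch_size} "
                    f"exceeds image bounds {h}x{w}"
                )

    def render(self) -> np.ndarray:
        """Blend the labeled patches over the grayscale base.

        Inside a labeled patch, output = (1-alpha)*gray + alpha*color;
        unlabeled (background) pixels are left untouched.
        """
        gray = to_grayscale(self.base) if self.base.ndim == 3 else self.base
        out = np.repeat(gray[..., None], 3, axis=2).astype(np.float64)
        s = self.patch_size
        labels = sorted(set(self.patch_labels.values()))
        if any(lbl >= len(self.palette) or lbl < 0 for lbl in labels):
            raise ConfigurationError(
                f"palette with {len(self.palette)} colors cannot cover labels {labels}"
            )
        for (gr, gc), lbl in self.patch_labels.items():
            color = np.asarray(self.palette[lbl], dtype=np.float64)
            block = out[gr * s : (gr + 1) * s, gc * s : (gc + 1) * s]
            block[:] = (1.0 - self.alpha) * block + self.alpha * color
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def render_overlay(ov: OverlayImage, path: str | os.PathLike) -> np.ndarray:
    """Render a cluster overlay and write it as a PNG; returns the pixels."""
    rgb = ov.render()
    write_image(rgb, path)
    return rgb


def export_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | os.PathLike) -> None:
    """Write tabular records as RFC-4180 CSV with a header row.

    Floats keep full repr precision (>= 6 significant digits). An empty
    record list with no schema produces a header-only (empty) file.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False, lineterminator="\n")
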