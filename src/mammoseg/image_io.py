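"""Grayscale image and binary-mask I/O.

The whole pipeline trades in :class:`GrayImage` — a 2-D integer intensity
grid with 0-based (row, col) indexing plus the maximum representable level
(255 for 8-bit scans, 65535 for 16-bit) — and :class:`BinaryMask` for
ground-truth and ROI masks.  Supported on-disk formats are PGM (both the
ASCII ``P2`` and binary ``P5`` dialects) and 8/16-bit grayscale PNG.
RGB inputs are collapsed to luminance with a warning; multi-frame files
are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "BinaryMask",
    "UnsupportedImageError",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]

# ITU-R BT.601 luminance weights, the usual convention for collapsing RGB scans
_LUMA = np.array([0.299, 0.587, 0.114])


class UnsupportedImageError(ValueError):
    """Raised for multi-frame or otherwise unsupported image layouts."""


@dataclass(frozen=True)
class GrayImage:
    """2-D grid of integer intensities with bit-depth metadata.

    Parameters
    ----------
    pixels
        2-D integer array, row-major, 0-based (row, col) indexing.  The
        row-major rank of a pixel is its vertex index in the segmentation
        graph.
    max_level
        Maximum representable intensity (e.g. 255 for 8-bit).
    source
        Optional provenance string (file path or generator description).
    """

    pixels: np.ndarray
    max_level: int = 255
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must have an integer dtype")
        if px.min() < 0 or px.max() > self.max_level:
            raise ValueError(f"intensities must lie in [0, {self.max_level}]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """2-D boolean grid; shape must match its paired image when evaluated."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _load_2d(path: str | Path) -> np.ndarray:
    """Read a single-frame image as a 2-D array, collapsing RGB to luminance."""
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a mix of ValueError/OSError
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        warnings.warn(f"{path.name}: RGB(A) input collapsed to luminance")
        arr = np.round(arr[..., :3].astype(float) @ _LUMA).astype(np.int64)
    if arr.ndim != 2:
        raise UnsupportedImageError(
            f"{path.name}: expected a single-frame grayscale image, got shape {arr.shape}"
        )
    return arr


def read_image(path: str | Path) -> GrayImage:
    """Read a PGM or PNG grayscale image.

    ``max_level`` is inferred from the stored dtype: 8-bit containers map to
    255, 16-bit to 65535.  Round-trips losslessly with :func:`write_image`
    for 8-bit input.
    """
    arr = _load_2d(path)
    if arr.dtype == np.uint16 or arr.max() > 255:
        max_level = 65535
    else:
        max_level = 255
    return GrayImage(arr.astype(np.int64), max_level=max_level, source=str(path))


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write an image as PGM or PNG (by extension), 8- or 16-bit."""
    dtype = np.uint8 if img.max_level <= 255 else np.uint16
    try:
        iio.imwrite(Path(path), img.pixels.astype(dtype))
    except Exception as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask; any nonzero pixel is true."""
    return BinaryMask(_load_2d(path) != 0)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a 0/255 image; read-back equals the input."""
    try:
        iio.imwrite(Path(path), np.where(mask.pixels, 255, 0).astype(np.uint8))
    except Exception as exc:
        raise IOError(f"cannot write mask {path}: {exc}") from exc
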