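"""Grayscale image model, raster I/O and intensity normalization.

Every pipeline stage operates on :class:`GrayImage`, a thin wrapper around a
2-D numpy array that records the declared bit depth (8, 16, or ``"unit"`` for
normalized floating intensities in [0, 1]).  Coordinates are row-major,
0-based, origin at the top-left; binary masks use 1 = foreground.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np

Depth = Union[int, str]

__all__ = [
    "GrayImage",
    "BinaryMask",
    "read_gray",
    "write_gray",
    "read_mask",
    "write_mask",
    "normalize_unit",
    "denormalize",
]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale raster with a declared bit depth.

    Parameters
    ----------
    pixels
        2-D array of intensities (rows x cols).
    depth
        Bits per pixel, 8 or 16 for integer rasters, or the string
        ``"unit"`` for floating intensities normalized to [0, 1].
    """

    pixels: np.ndarray
    depth: Depth

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a 2-D array with rows, cols >= 1")
        if self.depth == "unit":
            px = px.astype(np.float64, copy=False)
            if px.min() < 0.0 or px.max() > 1.0:
                raise ValueError("unit image intensities must lie in [0, 1]")
        elif self.depth in (8, 16):
            maxval = (1 << self.depth) - 1
            if px.min() < 0 or px.max() > maxval:
                raise ValueError(
                    f"{self.depth}-bit image intensities must lie in [0, {maxval}]"
                )
        else:
            raise ValueError(f"unsupported depth {self.depth!r}; use 8, 16 or 'unit'")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def is_unit(self) -> bool:
        return self.depth == "unit"

    @property
    def max_value(self) -> float:
        """Largest representable intensity for this depth."""
        return 1.0 if self.is_unit else float((1 << int(self.depth)) - 1)


@dataclass(frozen=True)
class BinaryMask:
    """A {0, 1} raster paired with an image of the same shape."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        uniq = np.unique(px)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be exactly 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)


def read_gray(path: Union[str, Path]) -> GrayImage:
    """Read a single-channel PGM/PNG/TIFF raster as a :class:`GrayImage`.

    Depth is inferred from the file's sample type (uint8 -> 8, uint16 -> 16).
    Multi-channel input is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not grayscale: shape {arr.shape}")
    if arr.dtype == np.uint8:
        return GrayImage(arr, 8)
    # some decoders hand 16-bit PGM samples back as wider signed ints
    if np.issubdtype(arr.dtype, np.integer) and 0 <= arr.min() and arr.max() <= 65535:
        return GrayImage(arr.astype(np.uint16), 16)
    raise ValueError(f"unsupported raster sample type {arr.dtype} in {path}")


def write_gray(img: GrayImage, path: Union[str, Path]) -> None:
    """Write an image to PGM/PNG/TIFF. Unit images are written as 8-bit."""
    out = denormalize(img, 8) if img.is_unit else img
    dtype = np.uint8 if out.depth == 8 else np.uint16
    iio.imwrite(Path(path), out.pixels.astype(dtype))


def read_mask(path: Union[str, Path]) -> BinaryMask:
    """Read a binary mask; on-disk {0, >0} maps to in-memory {0, 1}."""
    img = read_gray(path)
    return BinaryMask((img.pixels > 0).astype(np.uint8))


def write_mask(mask: BinaryMask, path: Union[str, Path]) -> None:
    """Write a mask with foreground stored as 255."""
    iio.imwrite(Path(path), (mask.pixels * 255).astype(np.uint8))


def normalize_unit(img: GrayImage) -> GrayImage:
    """Map an integer-depth image onto [0, 1] by dividing by 2^depth - 1.

    A unit image is returned unchanged.  The mapping is strictly monotone,
    so the relative order of distinct pixel values is preserved.
    """
    if img.is_unit:
        return img
    maxval = (1 << int(img.depth)) - 1
    return GrayImage(img.pixels.astype(np.float64) / maxval, "unit")


def denormalize(img: GrayImage, depth: int) -> GrayImage:
    """Map a unit image back to integer intensities, rounding half up."""
    if not img.is_unit:
        raise ValueError("denormalize expects a unit image")
    if depth not in (8, 16):
        raise ValueError("target depth must be 8 or 16")
    maxval = (1 << depth) - 1
    # floor(x + 0.5) is round-half-up, unlike numpy's banker's rounding
    out = np.floor(img.pixels * maxval + 0.5).astype(np.int64)
    return GrayImage(np.clip(out, 0, maxval), depth)
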