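"""Breast silhouette extraction and background/label removal.

A screening mammogram contains the breast, a dark background, and often a
bright film label or other artifacts.  The silhouette step binarizes the
equalized image, cleans it with morphological opening and closing, and
keeps only the largest connected component, which removes labels and
background clutter; the crop step then zeroes everything outside the
silhouette while leaving breast tissue bit-for-bit unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import morphology

from .core import BinaryMask, GrayImage
from .histogram import compute_histogram, equalize_global, otsu_multithreshold

__all__ = ["SilhouetteParams", "extract_silhouette", "crop_breast"]

# default disk radii are expressed at the 1024-px scale of screening-film
# digitizations and scaled proportionally to the actual image
_REFERENCE_SIZE = 1024
_DEFAULT_OPENING = 5
_DEFAULT_CLOSING = 10


@dataclass(frozen=True)
class SilhouetteParams:
    """Binarization and morphological clean-up settings.

    ``threshold_mode`` is ``"otsu"`` (single Otsu threshold on the
    equalized histogram) or ``"fixed"`` (use ``fixed_threshold``).  Radii
    of ``None`` scale the defaults (5 and 10 px at 1024-px image width)
    proportionally to the image.
    """

    threshold_mode: str = "otsu"
    fixed_threshold: float = 0.5
    opening_radius: Optional[int] = None
    closing_radius: Optional[int] = None
    fill_holes: bool = True
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold_mode must be 'otsu' or 'fixed'")
        if self.threshold_mode == "fixed" and not 0.0 < self.fixed_threshold < 1.0:
            raise ValueError("fixed_threshold must lie in (0, 1)")
        for r in (self.opening_radius, self.closing_radius):
            if r is not None and r < 0:
                raise ValueError("radii must be >= 0")


def _scaled_radius(base: int, shape: tuple[int, int]) -> int:
    return max(1, round(base * max(shape) / _REFERENCE_SIZE))


def extract_silhouette(
    img: GrayImage, params: SilhouetteParams = SilhouetteParams()
) -> BinaryMask:
    """Segment the breast silhouette of a unit mammogram.

    Pipeline: global equalization -> binarize (Otsu or fixed threshold) ->
    morphological opening then closing with disk structuring elements ->
    keep the largest 4-connected component -> optional hole fill.
    Raises ``ValueError`` ("no breast found") if nothing survives.
    """
    if not img.is_unit:
        raise ValueError("extract_silhouette expects a unit image")

    if params.threshold_mode == "otsu":
        # Otsu's split is not invariant under the histogram-flattening
        # equalization, so the threshold is chosen on the original
        # intensity scale where background and breast are bimodal
        hist = compute_histogram(img, params.n_bins)
        thr = float(otsu_multithreshold(hist, 1).values[0])
        binary = img.pixels >= thr
    else:
        # a fixed threshold is applied on the equalized (rank) scale,
        # where it acts as a quantile and transfers across exposures
        equalized = equalize_global(img, params.n_bins)
        binary = equalized.pixels >= params.fixed_threshold

    r_open = (
        params.opening_radius
        if params.opening_radius is not None
        else _scaled_radius(_DEFAULT_OPENING, img.shape)
    )
    r_close = (
        params.closing_radius
        if params.closing_radius is not None
        else _scaled_radius(_DEFAULT_CLOSING, img.shape)
    )
    if r_open > 0:
        binary = morphology.opening(binary, morphology.disk(r_open))
    if r_close > 0:
        binary = morphology.closing(binary, morphology.disk(r_close))

    labels, n_comp = ndimage.label(binary, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n_comp == 0:
        raise ValueError("no breast found: nothing remains after thresholding")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n_comp + 1))
    binary = labels == (int(np.argmax(sizes)) + 1)

    if params.fill_holes:
        binary = ndimage.binary_fill_holes(binary)
    return BinaryMask(binary.astype(np.uint8))


def crop_breast(img: GrayImage, mask: BinaryMask) -> GrayImage:
    """Zero out everything outside the silhouette; breast pixels are copied
    unchanged (bit-exact), with no resampling."""
    if mask.shape != img.shape:
        raise ValueError("mask shape must match image shape")
    out = img.pixels.copy()
    out[~mask.astype_bool()] = 0
    return GrayImage(out, img.depth)
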