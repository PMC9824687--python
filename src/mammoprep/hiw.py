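"""Histogram-based intensity windowing (HIW).

HIW segments a normalized mammogram into tissue regions with multilevel
Otsu thresholds (background, fatty tissue, dense tissue, and — at the
finest setting — masses and microcalcifications as separate classes), then
picks one of those thresholds as the lower bound of an intensity window
whose upper bound defaults to intensity 1.  The window is mapped linearly
onto the full [0, 1] contrast range; pixels below the window become black,
pixels above become white.  Enhancing the window that starts at the second
threshold stretches the densest and pathological structures.

Presets ``test1``..``test3`` name the three published parameterisations:

========  ============  =============  ===========================
preset    n_regions     lower_index    what gets the full contrast
========  ============  =============  ===========================
test1     5             2              dense tissue + pathology
test2     4             2              dense tissue + pathology
test3     4             1              fatty tissue upward
========  ============  =============  ===========================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GrayImage
from .histogram import ThresholdSet, compute_histogram, otsu_multithreshold

__all__ = [
    "IntensityWindow",
    "HiwParams",
    "HIW_PRESETS",
    "select_window",
    "apply_window",
    "enhance_hiw",
]


@dataclass(frozen=True)
class IntensityWindow:
    """The [lo, hi] input range granted full output contrast."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo < self.hi <= 1.0:
            raise ValueError(f"window must satisfy 0 <= lo < hi <= 1, got ({self.lo}, {self.hi})")


@dataclass(frozen=True)
class HiwParams:
    """Segmentation granularity and window choice for HIW.

    ``n_regions`` is the number of tissue classes requested from the
    threshold routine (which returns ``n_regions - 1`` thresholds);
    ``lower_index`` is the 1-based index of the threshold used as the
    window's lower bound; ``upper`` is the window's upper bound, fixed at
    intensity 1 in all published settings.
    """

    n_regions: int = 5
    lower_index: int = 2
    upper: float = 1.0
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if not 1 <= self.lower_index <= self.n_regions - 1:
            raise ValueError(
                f"lower_index must lie in [1, {self.n_regions - 1}], got {self.lower_index}"
            )
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


HIW_PRESETS: dict[str, HiwParams] = {
    "test1": HiwParams(n_regions=5, lower_index=2),
    "test2": HiwParams(n_regions=4, lower_index=2),
    "test3": HiwParams(n_regions=4, lower_index=1),
}


def select_window(thresholds: ThresholdSet, params: HiwParams) -> IntensityWindow:
    """Pick the window: lo = threshold number ``lower_index``, hi = ``params.upper``."""
    if params.lower_index > thresholds.values.size:
        raise ValueError(
            f"lower_index {params.lower_index} out of range for "
            f"{thresholds.values.size} thresholds"
        )
    lo = float(thresholds.values[params.lower_index - 1])
    if lo >= params.upper:
        raise ValueError(f"empty window: threshold {lo} >= upper bound {params.upper}")
    return IntensityWindow(lo, params.upper)


def apply_window(img: GrayImage, window: IntensityWindow) -> GrayImage:
    """Map [lo, hi] linearly onto [0, 1], saturating outside.

    p <= lo -> 0; p >= hi -> 1; otherwise (p - lo) / (hi - lo).  The map is
    weakly monotone and preserves the relative order of pixels inside the
    window exactly.
    """
    if not img.is_unit:
        raise ValueError("apply_window expects a unit image")
    out = (img.pixels - window.lo) / (window.hi - window.lo)
    return GrayImage(np.clip(out, 0.0, 1.0), "unit")


def enhance_hiw(img: GrayImage, params: HiwParams = HiwParams()) -> GrayImage:
    """Full HIW enhancement: histogram -> thresholds -> window -> linear map."""
    hist = compute_histogram(img, params.n_bins)
    thresholds = otsu_multithreshold(hist, params.n_regions - 1)
    window = select_window(thresholds, params)
    return apply_window(img, window)
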