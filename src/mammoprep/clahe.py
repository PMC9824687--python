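"""Contrast-limited adaptive histogram equalization (CLAHE).

The image is divided into an M x N grid of tiles.  Each tile's intensity
histogram is clipped at a limit derived from a normalized clip value, the
clipped-off excess is redistributed uniformly over the bins, and a
monotone grey-level transfer function is built from the resulting CDF
(uniform, Rayleigh-shaped or exponential-shaped target distribution, onto
either the full representable range or the input's original range).  Every
output pixel is then the bilinear blend of the transfer functions of its
(up to four) nearest tile centers, which removes the block artifacts of
naive per-tile equalization while the clip limit bounds noise
amplification.

Degenerate configuration check: a single tile with ``clip_norm = 1``,
uniform distribution and full range reduces CLAHE to plain global
histogram equalization — a useful correctness oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import GrayImage
from .histogram import Histogram

__all__ = [
    "ClaheParams",
    "TileMapping",
    "CLAHE_PRESETS",
    "compute_clip_limit",
    "clip_histogram",
    "make_transfer",
    "enhance_clahe",
]


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE parameter bundle.

    Parameters
    ----------
    tiles
        (M, N): number of tile rows and columns the image is divided into.
    clip_norm
        Normalized clip limit in [0, 1].  0 keeps only the uniform-histogram
        floor (strongest limiting); 1 disables clipping entirely.
    n_bins
        Number of histogram bins for the per-tile transfer functions.
    range_mode
        ``"full"``: output spans the full representable range of the image
        depth; ``"original"``: output limited to the input's [min, max].
    distribution
        Target histogram shape: ``"uniform"`` (flat), ``"rayleigh"``
        (bell-shaped) or ``"exponential"`` (curved).
    alpha
        Scale parameter of the rayleigh/exponential targets (unused for
        uniform).
    """

    tiles: tuple[int, int] = (8, 8)
    clip_norm: float = 0.01
    n_bins: int = 256
    range_mode: str = "full"
    distribution: str = "uniform"
    alpha: float = 0.4

    def __post_init__(self) -> None:
        m, n = self.tiles
        if m < 1 or n < 1:
            raise ValueError("tile grid must be at least 1 x 1")
        if not 0.0 <= self.clip_norm <= 1.0:
            raise ValueError("clip_norm must lie in [0, 1]")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.range_mode not in ("full", "original"):
            raise ValueError("range_mode must be 'full' or 'original'")
        if self.distribution not in ("uniform", "rayleigh", "exponential"):
            raise ValueError("distribution must be uniform, rayleigh or exponential")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


CLAHE_PRESETS: dict[str, ClaheParams] = {
    "test4": ClaheParams(tiles=(8, 8), clip_norm=0.01),
    "test5": ClaheParams(tiles=(3, 3), clip_norm=0.01),
    "test6": ClaheParams(tiles=(8, 8), clip_norm=0.05),
}


@dataclass(frozen=True)
class TileMapping:
    """Per-tile lookup table: bin index -> output grey level (monotone)."""

    levels: np.ndarray

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=np.float64)
        if lv.ndim != 1 or np.any(np.diff(lv) < 0):
            raise ValueError("mapping must be a 1-D monotone non-decreasing table")
        object.__setattr__(self, "levels", lv)


def compute_clip_limit(clip_norm: float, tile_pixels: int, n_bins: int) -> int:
    """Actual per-bin clip limit from the normalized clip value.

    ``max(ceil(tile_pixels / n_bins), floor(clip_norm * tile_pixels))``:
    the first term is the mean bin height of a perfectly uniform tile
    histogram (clipping below it would be meaningless), the second scales
    the user's normalized value by the tile size.  Always >= 1.
    """
    if tile_pixels < 1 or n_bins < 1:
        raise ValueError("tile_pixels and n_bins must be positive")
    floor_uniform = math.ceil(tile_pixels / n_bins)
    scaled = math.floor(clip_norm * tile_pixels)
    return max(1, floor_uniform, scaled)


def clip_histogram(hist: Histogram, limit: int) -> Histogram:
    """Clip bins at ``limit`` and redistribute the excess uniformly.

    The total excess E goes back as floor(E / B) to every bin plus one
    extra count to each of the first E mod B bins, so the total count is
    conserved exactly (single redistribution pass; bins may end slightly
    above the limit, which only weakens the limiting, never the
    conservation).
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    counts = hist.counts.copy()
    excess = int(np.sum(np.maximum(counts - limit, 0)))
    counts = np.minimum(counts, limit)
    if excess:
        b = counts.size
        counts += excess // b
        counts[: excess % b] += 1
    return Histogram(counts, hist.edges)


def make_transfer(
    hist: Histogram, params: ClaheParams, out_lo: float, out_hi: float
) -> TileMapping:
    """Build the monotone grey-level map from a clipped tile histogram.

    The empirical CDF c(b) is pushed through the inverse CDF of the target
    distribution.  For rayleigh/exponential the CDF is first scaled by the
    target's mass below intensity 1 (so a full-contrast tile maps exactly
    onto [out_lo, out_hi]) and clamped below 1 - 1/(2 * tile_pixels) to
    keep the logarithmic inverses finite; the uniform target uses the raw
    CDF directly.
    """
    if out_lo >= out_hi:
        raise ValueError("out_lo must be < out_hi")
    total = hist.total
    if total == 0:
        raise ValueError("cannot build a transfer from an empty histogram")
    c = np.cumsum(hist.counts) / total
    span = out_hi - out_lo
    if params.distribution == "uniform":
        levels = out_lo + c * span
    else:
        clamp = 1.0 - 1.0 / (2.0 * total)
        if params.distribution == "rayleigh":
            hconst = 2.0 * params.alpha**2
            vmax = 1.0 - math.exp(-1.0 / hconst)
            val = np.minimum(vmax * c, clamp)
            shape = np.sqrt(-hconst * np.log1p(-val))
        else:  # exponential
            vmax = 1.0 - math.exp(-params.alpha)
            val = np.minimum(vmax * c, clamp)
            shape = -np.log1p(-val) / params.alpha
        levels = out_lo + shape * span
    return TileMapping(np.minimum(levels, out_hi))


def _output_range(img: GrayImage, params: ClaheParams) -> tuple[float, float]:
    if params.range_mode == "full":
        return 0.0, img.max_value
    lo, hi = float(img.pixels.min()), float(img.pixels.max())
    if lo == hi:  # constant image: degenerate original range
        raise ValueError("original-range mode undefined for a constant image")
    return lo, hi


def enhance_clahe(img: GrayImage, params: ClaheParams = ClaheParams()) -> GrayImage:
    """Apply CLAHE to an image of any depth.

    The image is padded by symmetric reflection up to a multiple of the
    tile size, per-tile clipped transfer maps are built, each output pixel
    is bilinearly interpolated between the maps of its nearest tile
    centers (1 map at corners, 2 on edges, 4 in the interior), and the
    padding is cropped away.  Deterministic: fixed input and parameters
    give a bit-identical result.
    """
    m, n = params.tiles
    rows, cols = img.shape
    if m > rows or n > cols:
        raise ValueError(f"tile too large: {m}x{n} grid does not fit {rows}x{cols} image")

    th = -(-rows // m)  # ceil
    tw = -(-cols // n)
    padded = np.pad(
        img.pixels.astype(np.float64),
        ((0, m * th - rows), (0, n * tw - cols)),
        mode="symmetric",
    )
    p_rows, p_cols = padded.shape
    tile_pixels = th * tw

    norm = padded / img.max_value
    bins = np.clip((norm * params.n_bins).astype(np.int64), 0, params.n_bins - 1)

    out_lo, out_hi = _output_range(img, params)
    limit = compute_clip_limit(params.clip_norm, tile_pixels, params.n_bins)
    edges = np.linspace(0.0, 1.0, params.n_bins + 1)

    maps = np.empty((m, n, params.n_bins))
    for i in range(m):
        for j in range(n):
            tile_bins = bins[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            counts = np.bincount(tile_bins.ravel(), minlength=params.n_bins)
            clipped = clip_histogram(Histogram(counts, edges), limit)
            maps[i, j] = make_transfer(clipped, params, out_lo, out_hi).levels

    # bilinear weights relative to tile centers; indices clamp at the border
    # so corner pixels see one map and edge pixels two
    ry = (np.arange(p_rows) + 0.5) / th - 0.5
    cx = (np.arange(p_cols) + 0.5) / tw - 0.5
    iy0 = np.floor(ry).astype(np.int64)
    jx0 = np.floor(cx).astype(np.int64)
    wy = (ry - iy0)[:, None]
    wx = (cx - jx0)[None, :]
    iy0c = np.clip(iy0, 0, m - 1)[:, None]
    iy1c = np.clip(iy0 + 1, 0, m - 1)[:, None]
    jx0c = np.clip(jx0, 0, n - 1)[None, :]
    jx1c = np.clip(jx0 + 1, 0, n - 1)[None, :]

    out = (
        (1 - wy) * (1 - wx) * maps[iy0c, jx0c, bins]
        + (1 - wy) * wx * maps[iy0c, jx1c, bins]
        + wy * (1 - wx) * maps[iy1c, jx0c, bins]
        + wy * wx * maps[iy1c, jx1c, bins]
    )
    out = out[:rows, :cols]

    if img.is_unit:
        return GrayImage(np.clip(out, out_lo, out_hi), "unit")
    maxval = int(img.max_value)
    # round half up into the integer grey levels of the input depth
    quant = np.clip(np.floor(out + 0.5), 0, maxval).astype(np.int64)
    return GrayImage(quant, img.depth)
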