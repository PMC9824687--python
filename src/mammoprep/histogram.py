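"""Histogram computation, global equalization and multilevel Otsu thresholding.

The thresholding routine places ``k`` cuts on the bin edges of an intensity
histogram so as to maximize the between-class variance of the ``k + 1``
resulting classes (multilevel Otsu).  Ties are broken deterministically by
the lexicographically smallest cut tuple.  Both the intensity-windowing
enhancement and breast-silhouette extraction build on these primitives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .core import BinaryMask, GrayImage

__all__ = [
    "Histogram",
    "ThresholdSet",
    "compute_histogram",
    "equalize_global",
    "otsu_multithreshold",
    "label_regions",
]


@dataclass(frozen=True)
class Histogram:
    """Binned intensity counts over [0, 1] with equally spaced edges."""

    counts: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        edges = np.asarray(self.edges, dtype=np.float64)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if edges.shape != (counts.size + 1,) or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be B+1 strictly increasing cut points")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_csv(self, path: Union[str, Path]) -> None:
        """Export as two-column CSV (bin_center, count)."""
        import pandas as pd

        pd.DataFrame({"bin_center": self.centers, "count": self.counts}).to_csv(
            Path(path), index=False
        )


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered normalized thresholds t1 < ... < tk dividing [0, 1] into k+1 regions."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("at least one threshold required")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if vals[0] <= 0.0 or vals[-1] >= 1.0:
            raise ValueError("thresholds must lie strictly inside (0, 1)")
        object.__setattr__(self, "values", vals)

    @property
    def n_regions(self) -> int:
        return self.values.size + 1


def _bin_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    # half-open bins [i/B, (i+1)/B); intensity 1 joins the last (closed) bin
    idx = np.floor(values * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def compute_histogram(
    img: GrayImage, n_bins: int = 256, mask: Optional[BinaryMask] = None
) -> Histogram:
    """Histogram a unit image into ``n_bins`` equal bins spanning [0, 1].

    Pixel ``p`` falls in bin ``floor(p * B)``; ``p == 1`` is assigned to the
    last bin.  Pixels where ``mask == 0`` are excluded.
    """
    if not img.is_unit:
        raise ValueError("compute_histogram expects a unit image")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = img.pixels
    if mask is not None:
        if mask.shape != img.shape:
            raise ValueError("mask shape must match image shape")
        values = values[mask.astype_bool()]
        if values.size == 0:
            raise ValueError("empty region: mask selects no pixels")
    counts = np.bincount(_bin_indices(values.ravel(), n_bins), minlength=n_bins)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return Histogram(counts, edges)


def equalize_global(img: GrayImage, n_bins: int = 256) -> GrayImage:
    """Global histogram equalization on a unit image.

    Each output intensity is the empirical CDF of the input's binned
    intensity, so the transfer is monotone non-decreasing and the output
    histogram is at least as flat as the input's.
    """
    hist = compute_histogram(img, n_bins)
    cdf = np.cumsum(hist.counts) / hist.total
    out = cdf[_bin_indices(img.pixels, n_bins)]
    return GrayImage(out, "unit")


def otsu_multithreshold(hist: Histogram, k: int) -> ThresholdSet:
    """Place ``k`` cuts maximizing between-class variance (multilevel Otsu).

    The between-class variance sum(w_c * (mu_c - mu)^2) over the k+1 classes
    is maximized exactly by dynamic programming over cut positions; among
    ties the lexicographically smallest cut tuple wins.  Thresholds are
    reported as the normalized bin-edge values at the chosen cuts.

    Maximizing sum(w_c * (mu_c - mu)^2) is equivalent to maximizing
    sum(s_c^2 / w_c) with w_c the class count and s_c its first moment.
    With bin centers (2i+1)/(2B), the per-class terms are exact rationals
    after dropping the common 1/(4 B^2 N) factor, so the search is carried
    out in integer/Fraction arithmetic: ties are exact, never a float
    artifact, and the result matches exhaustive enumeration bit for bit.
    """
    from fractions import Fraction

    B = hist.n_bins
    if not 1 <= k <= B - 1:
        raise ValueError(f"k must satisfy 1 <= k <= {B - 1}")
    nonempty = int(np.count_nonzero(hist.counts))
    if nonempty < k + 1:
        raise ValueError(
            f"degenerate histogram: {nonempty} non-empty bins cannot form {k + 1} classes"
        )

    counts = hist.counts.tolist()
    # prefix sums: class over bins [a, b) has weight w[b]-w[a] and scaled
    # first moment s[b]-s[a] where the i-th bin contributes counts[i]*(2i+1)
    w = [0] * (B + 1)
    s = [0] * (B + 1)
    for i, c in enumerate(counts):
        w[i + 1] = w[i] + c
        s[i + 1] = s[i] + c * (2 * i + 1)

    zero = Fraction(0)

    def class_score(a: int, b: int) -> Fraction:
        wc = w[b] - w[a]
        if wc == 0:
            return zero
        sc = s[b] - s[a]
        return Fraction(sc * sc, wc)

    # f[c][b] = best score splitting bins [b, B) into c classes
    n_classes = k + 1
    f = [class_score(b, B) for b in range(B + 1)]
    nxt = [[0] * (B + 1) for _ in range(n_classes + 1)]
    for c in range(2, n_classes + 1):
        g: list = [zero] * (B + 1)
        for b in range(B - c + 1, -1, -1):
            best, best_t = None, -1
            for t in range(b + 1, B - c + 2):
                val = class_score(b, t) + f[t]
                if best is None or val > best:  # strict: smallest t wins ties
                    best, best_t = val, t
            g[b] = best
            nxt[c][b] = best_t
        f = g

    cuts = []
    b = 0
    for c in range(n_classes, 1, -1):
        t = nxt[c][b]
        cuts.append(t)
        b = t
    return ThresholdSet(hist.edges[np.asarray(cuts)])


def label_regions(img: GrayImage, thresholds: ThresholdSet) -> np.ndarray:
    """Label each pixel with the count of thresholds <= its intensity.

    Half-open intervals [t_i, t_{i+1}): a pixel exactly equal to t_1 gets
    label 1.  Labels run 0..k for k thresholds.
    """
    if not img.is_unit:
        raise ValueError("label_regions expects a unit image")
    return np.searchsorted(thresholds.values, img.pixels, side="right").astype(np.int64)
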