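"""Synthetic mammogram phantom with ground truth.

The phantom emulates the intensity structure of a digitized screening
mammogram: a dark background, a half-elliptical breast of fatty tissue,
brighter dense-tissue blobs, and pathology — soft-edged masses and
clustered microcalcification specks — at the top of the intensity range.
Its histogram therefore shows the characteristic modes (background, fatty,
dense, pathology) that the histogram-based enhancement methods key on,
while the generator also returns the exact silhouette, lesion mask and
per-pixel tissue labels, so every pipeline stage can be validated against
known truth without any external image collection.

The phantom is a geometric idealization: it does not simulate projection
physics, scatter, compression or film grain beyond additive Gaussian
noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .core import BinaryMask, GrayImage
from .tiling import ClassLabel

__all__ = ["Region", "PhantomSpec", "PhantomResult", "generate_phantom"]


class Region(IntEnum):
    """Per-pixel tissue label of the phantom, ordered by brightness."""

    BACKGROUND = 0
    FATTY = 1
    DENSE = 2
    MASS = 3
    CALC = 4


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom parameters.

    Intensity levels are unit intensities and must be strictly ordered
    background < fatty < dense < mass < calc <= 1; the defaults put the
    pathology levels between 0.6 and 1 where mammogram pathology pixels
    sit.  ``noise_sigma`` is the standard deviation of additive Gaussian
    noise (clipped to [0, 1] afterwards).
    """

    size: tuple[int, int] = (256, 256)
    seed: int = 0
    background_level: float = 0.05
    fatty_level: float = 0.35
    dense_level: float = 0.55
    mass_level: float = 0.68
    calc_level: float = 0.92
    noise_sigma: float = 0.01
    n_dense_blobs: int = 3
    n_masses: int = 1
    n_calc_clusters: int = 1
    lesion_class: ClassLabel = ClassLabel.MALIGNANT_MASS

    def __post_init__(self) -> None:
        levels = (
            self.background_level,
            self.fatty_level,
            self.dense_level,
            self.mass_level,
            self.calc_level,
        )
        if not all(a < b for a, b in zip(levels, levels[1:])) or self.calc_level > 1.0:
            raise ValueError(
                "levels must satisfy background < fatty < dense < mass < calc <= 1"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        rows, cols = self.size
        if rows < 64 or cols < 64:
            raise ValueError("phantom must be at least 64 x 64")
        for n in (self.n_dense_blobs, self.n_masses, self.n_calc_clusters):
            if n < 0:
                raise ValueError("structure counts must be >= 0")


@dataclass(frozen=True)
class PhantomResult:
    """Phantom image plus its ground truth."""

    image: GrayImage
    silhouette_truth: BinaryMask
    lesion_truth: BinaryMask
    region_labels: np.ndarray


def _breast_ellipse(rows: int, cols: int) -> np.ndarray:
    # half-ellipse attached to the left edge, like an MLO/CC breast contour;
    # semi-axes keep the breast area between 25% and 60% of the frame
    rr, cc = np.mgrid[0:rows, 0:cols]
    a = 0.46 * rows
    b = 0.70 * cols
    return ((rr - rows / 2.0) / a) ** 2 + (cc / b) ** 2 <= 1.0


def _sample_inside(rng: np.random.Generator, breast: np.ndarray, margin: int) -> tuple[int, int]:
    """Rejection-sample a point of the breast at least ``margin`` px from its edge."""
    from scipy import ndimage

    interior = ndimage.binary_erosion(breast, iterations=margin) if margin else breast
    idx = np.flatnonzero(interior)
    if idx.size == 0:
        idx = np.flatnonzero(breast)
    choice = idx[rng.integers(idx.size)]
    return np.unravel_index(choice, breast.shape)


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomResult:
    """Generate a phantom; the same spec (and seed) gives a bit-identical result."""
    rows, cols = spec.size
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)

    breast = _breast_ellipse(rows, cols)
    labels = np.full((rows, cols), int(Region.BACKGROUND), dtype=np.int64)
    labels[breast] = int(Region.FATTY)

    image = np.full((rows, cols), spec.background_level)

    # fatty base with smooth low-frequency texture (amplitude well below the
    # fatty-to-dense gap so the fatty histogram mode stays distinct)
    phase = rng.uniform(0, 2 * np.pi, size=4)
    freq = rng.uniform(1.0, 3.0, size=4)
    texture = 0.5 * (
        np.sin(2 * np.pi * freq[0] * rr / rows + phase[0])
        * np.sin(2 * np.pi * freq[1] * cc / cols + phase[1])
        + np.sin(2 * np.pi * freq[2] * rr / rows + phase[2])
        * np.sin(2 * np.pi * freq[3] * cc / cols + phase[3])
    )
    fatty = spec.fatty_level + 0.03 * texture
    image[breast] = fatty[breast]

    scale = min(rows, cols)

    def add_plateau(level: float, region: Region, center, radius: float, exponent: int) -> None:
        """Soft-edged plateau: super-Gaussian profile blended over the base."""
        r2 = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / radius**2
        profile = np.exp(-(r2**exponent))
        profile[~breast] = 0.0
        np.maximum(image, image + (level - image) * profile, out=image)
        labels[(profile > 0.5) & (labels < int(region))] = int(region)

    for _ in range(spec.n_dense_blobs):
        center = _sample_inside(rng, breast, margin=scale // 16)
        radius = rng.uniform(0.06, 0.11) * scale
        add_plateau(spec.dense_level, Region.DENSE, center, radius, exponent=2)

    for _ in range(spec.n_masses):
        center = _sample_inside(rng, breast, margin=scale // 8)
        radius = rng.uniform(0.05, 0.08) * scale
        add_plateau(spec.mass_level, Region.MASS, center, radius, exponent=3)

    for _ in range(spec.n_calc_clusters):
        center = _sample_inside(rng, breast, margin=scale // 8)
        n_specks = rng.integers(5, 11)
        for _ in range(n_specks):
            dr, dc = rng.integers(-scale // 32, scale // 32 + 1, size=2)
            r0 = int(np.clip(center[0] + dr, 0, rows - 1))
            c0 = int(np.clip(center[1] + dc, 0, cols - 1))
            side = int(rng.integers(1, 4))  # specks are 1-3 px across
            sl = (slice(r0, min(r0 + side, rows)), slice(c0, min(c0 + side, cols)))
            inside = breast[sl]
            image[sl][inside] = spec.calc_level
            labels[sl][inside] = int(Region.CALC)

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    lesion = np.isin(labels, (int(Region.MASS), int(Region.CALC)))
    return PhantomResult(
        image=GrayImage(image, "unit"),
        silhouette_truth=BinaryMask(breast.astype(np.uint8)),
        lesion_truth=BinaryMask(lesion.astype(np.uint8)),
        region_labels=labels,
    )
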