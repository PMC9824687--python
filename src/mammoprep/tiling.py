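"""Patch extraction and class balancing.

Enhanced mammograms are cut into non-overlapping square patches (32 x 32
by default) on a grid aligned to the image origin.  A window is kept only
if enough of it lies on breast tissue; a kept patch is labelled with the
lesion class when enough of it lies inside the radiologist lesion mask,
and as healthy tissue otherwise.  Because lesion patches are far rarer
than healthy ones, a seeded undersampling step equalizes the per-class
counts to the smallest class before the patches are handed to a
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .core import BinaryMask, GrayImage, write_gray

__all__ = ["ClassLabel", "Tile", "TileSet", "extract_tiles", "balance_classes"]

DEFAULT_TILE_SIZE = 32


class ClassLabel(str, Enum):
    """The five patch classes."""

    BENIGN_CALCIFICATION = "benign_calcification"
    BENIGN_MASS = "benign_mass"
    MALIGNANT_CALCIFICATION = "malignant_calcification"
    MALIGNANT_MASS = "malignant_mass"
    HEALTHY = "healthy"


@dataclass(frozen=True)
class Tile:
    """A square patch with its source origin (top-left row, col) and label."""

    pixels: np.ndarray
    origin: tuple[int, int]
    label: ClassLabel


@dataclass
class TileSet:
    """Patches grouped by class label."""

    groups: dict[ClassLabel, list[Tile]] = field(default_factory=dict)
    tile_size: int = DEFAULT_TILE_SIZE

    @property
    def counts(self) -> dict[ClassLabel, int]:
        return {label: len(tiles) for label, tiles in self.groups.items()}

    @property
    def n_tiles(self) -> int:
        return sum(len(t) for t in self.groups.values())

    def all_tiles(self) -> list[Tile]:
        return [t for tiles in self.groups.values() for t in tiles]

    def write(self, out_dir: Union[str, Path], depth: int = 8) -> "Path":
        """Write tiles as PNG into per-class directories plus a manifest CSV.

        Returns the manifest path.  Columns: path, origin_row, origin_col,
        label.
        """
        import pandas as pd

        from .core import denormalize

        out_dir = Path(out_dir)
        records = []
        for label, tiles in self.groups.items():
            class_dir = out_dir / label.value
            class_dir.mkdir(parents=True, exist_ok=True)
            for t in tiles:
                name = f"r{t.origin[0]:05d}_c{t.origin[1]:05d}.png"
                path = class_dir / name
                img = GrayImage(t.pixels, "unit")
                write_gray(denormalize(img, depth), path)
                records.append(
                    {
                        "path": str(path.relative_to(out_dir)),
                        "origin_row": t.origin[0],
                        "origin_col": t.origin[1],
                        "label": label.value,
                    }
                )
        manifest = out_dir / "manifest.csv"
        pd.DataFrame(records).to_csv(manifest, index=False)
        return manifest


def extract_tiles(
    img: GrayImage,
    silhouette: BinaryMask,
    lesion_mask: Optional[BinaryMask] = None,
    lesion_class: Optional[ClassLabel] = None,
    breast_frac: float = 0.75,
    lesion_frac: float = 0.5,
    tile_size: int = DEFAULT_TILE_SIZE,
) -> TileSet:
    """Cut the image into labelled non-overlapping patches.

    The grid is aligned to (0, 0) with stride equal to ``tile_size``; a
    window becomes a tile iff at least ``breast_frac`` of its pixels lie on
    the silhouette, and a kept tile gets ``lesion_class`` iff at least
    ``lesion_frac`` of its pixels lie in the lesion mask (healthy
    otherwise).  Deterministic; patches are bit-exact copies of the source
    window.
    """
    if silhouette.shape != img.shape:
        raise ValueError("silhouette shape must match image shape")
    if (lesion_mask is None) != (lesion_class is None):
        raise ValueError("lesion_class must be given iff lesion_mask is given")
    if lesion_mask is not None and lesion_mask.shape != img.shape:
        raise ValueError("lesion mask shape must match image shape")
    if not 0.0 < breast_frac <= 1.0 or not 0.0 < lesion_frac <= 1.0:
        raise ValueError("breast_frac and lesion_frac must lie in (0, 1]")
    rows, cols = img.shape
    if rows < tile_size or cols < tile_size:
        raise ValueError(f"image smaller than one {tile_size}x{tile_size} tile")

    area = tile_size * tile_size
    groups: dict[ClassLabel, list[Tile]] = {}
    sil = silhouette.pixels
    les = lesion_mask.pixels if lesion_mask is not None else None
    for r0 in range(0, rows - tile_size + 1, tile_size):
        for c0 in range(0, cols - tile_size + 1, tile_size):
            window = (slice(r0, r0 + tile_size), slice(c0, c0 + tile_size))
            if int(sil[window].sum()) < breast_frac * area:
                continue
            label = ClassLabel.HEALTHY
            if les is not None and int(les[window].sum()) >= lesion_frac * area:
                label = lesion_class
            tile = Tile(img.pixels[window].copy(), (r0, c0), label)
            groups.setdefault(label, []).append(tile)
    return TileSet(groups, tile_size)


def balance_classes(tiles: TileSet, seed: int) -> TileSet:
    """Undersample every class to the smallest class count, reproducibly.

    Each class is down-sampled without replacement with a generator seeded
    from ``seed``; the same seed always reproduces the same selection.
    Raises on a class with zero tiles.
    """
    if not tiles.groups:
        raise ValueError("empty class: no tiles to balance")
    for label, group in tiles.groups.items():
        if not group:
            raise ValueError(f"empty class: {label.value} has no tiles")
    n_min = min(len(g) for g in tiles.groups.values())
    rng = np.random.default_rng(seed)
    balanced: dict[ClassLabel, list[Tile]] = {}
    # iterate classes in a fixed order so the seed alone fixes the outcome
    for label in sorted(tiles.groups, key=lambda lb: lb.value):
        group = tiles.groups[label]
        keep = rng.choice(len(group), size=n_min, replace=False)
        balanced[label] = [group[i] for i in sorted(keep)]
    return TileSet(balanced, tiles.tile_size)
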