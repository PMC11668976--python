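"""Slide-to-patch tiling with a saturation-based tissue mask.

A slide image is cut into a non-overlapping grid of square patches anchored
at the top-left corner; only patches whose tissue fraction exceeds a
threshold are kept.  Coordinates are 0-based, x along columns, y along
rows, with half-open pixel bounds [x0, x1) x [y0, y1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = ["TileIndex", "TileSet", "compute_tissue_mask", "extract_tiles"]


@dataclass
class TileIndex:
    row: int
    col: int
    x0: int
    y0: int
    x1: int
    y1: int
    tissue_frac: float

    def __post_init__(self) -> None:
        if self.x1 - self.x0 != self.y1 - self.y0:
            raise ValueError("tiles must be square")
        if not (0.0 <= self.tissue_frac <= 1.0):
            raise ValueError("tissue_frac out of [0, 1]")


@dataclass
class TileSet:
    """Foreground tiles of one slide, row-major, unique (row, col)."""

    slide_id: str
    tile_size: int
    grid_rows: int
    grid_cols: int
    tiles: list[TileIndex] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(t.row, t.col) for t in self.tiles]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (row, col) in TileSet")

    def __len__(self) -> int:
        return len(self.tiles)

    def to_json(self) -> str:
        return json.dumps({
            "slide_id": self.slide_id,
            "tile_size": self.tile_size,
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "tiles": [asdict(t) for t in self.tiles],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TileSet":
        d = json.loads(text)
        return cls(slide_id=d["slide_id"], tile_size=d["tile_size"],
                   grid_rows=d["grid_rows"], grid_cols=d["grid_cols"],
                   tiles=[TileIndex(**t) for t in d["tiles"]])


def compute_tissue_mask(image: np.ndarray, min_object_frac: float = 1e-3) -> np.ndarray:
    """Binary tissue mask: Otsu threshold on the HSV saturation channel.

    White/gray background has near-zero saturation, stained tissue does not,
    so thresholding saturation separates them without a tuned constant.
    Connected foreground components smaller than ``min_object_frac`` of the
    image area are dropped as debris.  A saturation-flat image (e.g. an
    all-white slide) yields an all-false mask.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("compute_tissue_mask expects an RGB (H, W, 3) image")
    if image.size == 0:
        raise ValueError("empty image")
    sat = rgb2hsv(image)[:, :, 1]
    if np.ptp(sat) < 1e-9:
        return np.zeros(sat.shape, dtype=bool)
    mask = sat > threshold_otsu(sat)
    min_size = int(np.ceil(min_object_frac * mask.size))
    if min_size > 1:
        mask = remove_small_objects(mask, max_size=min_size - 1)
    return mask


def extract_tiles(image: np.ndarray, mask: np.ndarray, tile_size: int,
                  min_tissue_frac: float = 0.5, slide_id: str = "") -> TileSet:
    """Cut the image into a stride = tile_size grid and keep tissue tiles.

    Partial tiles at the right/bottom edge are discarded.  A tile is kept
    iff its fraction of mask-positive pixels is >= ``min_tissue_frac``;
    tiles are returned in row-major order.  An image smaller than one tile
    yields an empty TileSet.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if not (0.0 <= min_tissue_frac <= 1.0):
        raise ValueError("min_tissue_frac must lie in [0, 1]")
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape must match the image plane")
    H, W = mask.shape
    rows, cols = H // tile_size, W // tile_size
    tiles = []
    for r in range(rows):
        for c in range(cols):
            y0, x0 = r * tile_size, c * tile_size
            frac = float(mask[y0:y0 + tile_size, x0:x0 + tile_size].mean())
            if frac >= min_tissue_frac:
                tiles.append(TileIndex(row=r, col=c, x0=x0, y0=y0,
                                       x1=x0 + tile_size, y1=y0 + tile_size,
                                       tissue_frac=frac))
    return TileSet(slide_id=slide_id, tile_size=tile_size,
                   grid_rows=rows, grid_cols=cols, tiles=tiles)
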