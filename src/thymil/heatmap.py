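"""Multi-class patch heatmaps from the auxiliary patch classifier.

Unlike attention-score heatmaps, which can only shade a single predicted
class, the map here colors every foreground tile by its own predicted
patch category (one of the C subtypes or the background class C+1), so a
single slide can — and on heterogeneous slides does — show more than one
subtype color.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .tiling import TileSet

__all__ = ["PatchClassMap", "predict_patch_classes", "render_heatmap",
           "minority_focus", "DEFAULT_PALETTE", "NON_TISSUE"]

NON_TISSUE = 0   # sentinel in PatchClassMap.labels for tiles outside the mask

# colorblind-safe (Okabe-Ito) subtype colors + gray background class
DEFAULT_PALETTE = {
    1: (0, 114, 178),     # A
    2: (230, 159, 0),     # AB
    3: (0, 158, 115),     # B1
    4: (204, 121, 167),   # B2
    5: (213, 94, 0),      # B3
    6: (153, 153, 153),   # background class C+1
}


@dataclass
class PatchClassMap:
    """Grid of predicted patch labels; 0 marks non-tissue positions."""

    slide_id: str
    labels: np.ndarray          # (grid_rows, grid_cols) ints
    n_classes: int              # C (labels run 1..C+1)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        fg = self.labels[self.labels != NON_TISSUE]
        if fg.size and (fg.min() < 1 or fg.max() > self.n_classes + 1):
            raise ValueError("patch labels out of range 1..C+1")

    @property
    def foreground_count(self) -> int:
        return int((self.labels != NON_TISSUE).sum())


def predict_patch_classes(tiles: TileSet, features: np.ndarray,
                          patch_classifier, n_classes: int) -> PatchClassMap:
    """Classify every foreground tile; non-tissue grid cells stay sentinel.

    ``features`` is the (n_tiles, D) raw feature matrix aligned with
    ``tiles.tiles``.  Labels are argmax class scores, 1-based, ties
    resolving to the lower class index.
    """
    features = np.asarray(features, dtype=float)
    if len(features) != len(tiles):
        raise ValueError("one feature row per foreground tile required")
    grid = np.full((tiles.grid_rows, tiles.grid_cols), NON_TISSUE, dtype=int)
    if len(tiles):
        pred = patch_classifier.predict(features)    # 0-based over C+1 classes
        if pred.max(initial=0) > n_classes:
            raise ValueError("patch classifier emits more classes than expected")
        for t, p in zip(tiles.tiles, pred):
            grid[t.row, t.col] = int(p) + 1
    return PatchClassMap(slide_id=tiles.slide_id, labels=grid,
                         n_classes=n_classes)


def minority_focus(pmap: PatchClassMap) -> tuple[int, set]:
    """The slide's secondary tumor focus: largest connected region of the
    second-most-frequent subtype color.

    Heterogeneous slides show more than one subtype in their class map; the
    clinically meaningful signal is a spatially coherent minority region (a
    focus), as opposed to isolated single-tile speckle from per-patch
    classification noise.  Returns ``(label, tiles)`` — the minority subtype
    label and the (row, col) set of its largest 4-connected component — or
    ``(0, set())`` when the map shows a single subtype.
    """
    from scipy import ndimage

    fg = pmap.labels[(pmap.labels != NON_TISSUE)
                     & (pmap.labels <= pmap.n_classes)]
    counts = np.bincount(fg, minlength=pmap.n_classes + 1)
    order = np.argsort(counts)[::-1]
    subtypes = [int(l) for l in order if counts[l] > 0]
    if len(subtypes) < 2:
        return 0, set()
    minority = subtypes[1]
    comp, n = ndimage.label(pmap.labels == minority)
    if n == 0:
        return minority, set()
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
    best = 1 + int(np.argmax(sizes))
    rows, cols = np.nonzero(comp == best)
    return minority, {(int(r), int(c)) for r, c in zip(rows, cols)}


def render_heatmap(pmap: PatchClassMap, tile_size: int,
                   palette: dict | None = None,
                   base_image: np.ndarray | None = None,
                   alpha: float = 0.4):
    """Paint each foreground tile with its label color; RGBA output.

    Non-tissue tiles are fully transparent (or show the base image
    unblended when one is given).  Returns ``(rgba, legend)`` where legend
    maps label -> color.  Tiles are painted as flat blocks — no smoothing,
    so the colored area equals the foreground tile area exactly.
    """
    palette = DEFAULT_PALETTE if palette is None else palette
    present = np.unique(pmap.labels[pmap.labels != NON_TISSUE])
    missing = [int(l) for l in present if l not in palette]
    if missing:
        raise ValueError(f"palette missing labels: {missing}")
    H = pmap.labels.shape[0] * tile_size
    W = pmap.labels.shape[1] * tile_size
    rgba = np.zeros((H, W, 4), dtype=np.uint8)
    if base_image is not None:
        if base_image.shape[:2] != (H, W):
            raise ValueError("base image size does not match the tile grid")
        rgba[:, :, :3] = base_image[:, :, :3]
        rgba[:, :, 3] = 255
    for r in range(pmap.labels.shape[0]):
        for c in range(pmap.labels.shape[1]):
            lab = pmap.labels[r, c]
            if lab == NON_TISSUE:
                continue
            color = np.asarray(palette[int(lab)], dtype=float)
            y0, x0 = r * tile_size, c * tile_size
            block = rgba[y0:y0 + tile_size, x0:x0 + tile_size]
            if base_image is not None:
                blend = (1 - alpha) * block[:, :, :3] + alpha * color
                block[:, :, :3] = blend.astype(np.uint8)
            else:
                block[:, :, :3] = color.astype(np.uint8)
                block[:, :, 3] = 255
    legend = {int(l): list(palette[int(l)]) for l in palette}
    return rgba, legend


def write_heatmap(path, rgba: np.ndarray, legend: dict) -> None:
    """Write the heatmap PNG and a JSON legend sidecar."""
    import imageio.v3 as iio
    from pathlib import Path

    path = Path(path)
    iio.imwrite(path, rgba)
    path.with_suffix(".legend.json").write_text(json.dumps(legend, indent=1))
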