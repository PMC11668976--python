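"""Phantom slide cohorts with the statistical structure of thymoma WSIs.

Real cohorts of this kind are private, so the package ships a generator
that emulates what the method assumes: five subtypes {A, AB, B1, B2, B3}
with imbalanced slide counts, slides that are bags of foreground patches of
which only a fraction carry the subtype signal (the rest are non-tumoral
"background" patches, class C+1), occasional mixed-subtype slides with a
contiguous minority block, and per-cell morphology whose distributions
depend on the subtype (A and B3 lymphocyte-poor; B3 tumor nuclei larger
than A; A nuclei spindled, i.e. more elongated).

Patch features for truth class c are drawn from an isotropic Gaussian
centred on a class signature (orthogonal scaled basis vectors), so class
separability is controlled by a single scalar, ``signature_separation`` =
the Euclidean distance between any two class means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon

from .cellstats import CellRecord, cells_to_hovernet_json
from .mil import Bag
from .tiling import TileIndex, TileSet

__all__ = [
    "CellParams", "PhantomConfig", "PhantomSlide",
    "generate_slide", "generate_cohort", "split_cohort",
    "bags_from_slides", "class_signatures", "write_cohort", "null_config",
    "DEFAULT_CELL_PARAMS",
]


@dataclass
class CellParams:
    """Per-subtype cell mixture: lymphocyte share and tumor-nucleus shape."""

    lymphocyte_frac: float
    tumor_area_mean: float
    tumor_area_sd: float
    tumor_axis_ratio_mean: float
    tumor_axis_ratio_sd: float


# A and B3 are the lymphocyte-poor subtypes; B3 nuclei are the largest
# (greater atypia), A nuclei are spindled hence the highest axis ratio.
DEFAULT_CELL_PARAMS = {
    "A": CellParams(0.25, 90.0, 18.0, 2.30, 0.20),
    "AB": CellParams(0.60, 120.0, 22.0, 1.50, 0.12),
    "B1": CellParams(0.70, 110.0, 20.0, 1.40, 0.10),
    "B2": CellParams(0.55, 125.0, 22.0, 1.45, 0.10),
    "B3": CellParams(0.30, 140.0, 30.0, 1.60, 0.15),
}

# rendering palette for image mode (RGB); tissue saturation is kept well
# above white so a saturation threshold separates background cleanly
_TISSUE_RGB = (235, 170, 200)
_CELL_RGB = {"tumor": (150, 90, 160), "inflammatory": (60, 60, 140),
             "other": (120, 120, 120)}
_INTENSITY = {"tumor": (120.0, 10.0), "inflammatory": (60.0, 8.0),
              "other": (90.0, 10.0)}


@dataclass
class PhantomConfig:
    """Generator settings; the defaults mirror the study cohort layout.

    222 slides split 21/83/48/49/21 over the five subtypes; 8x8 tile grids
    at 64 px (256 px mirrors full scale); 64-dim feature bags with class
    means ``signature_separation`` apart and unit-ish noise; 60% of
    foreground patches carry the slide's subtype signal; 20% of slides host
    a contiguous minority block of a second subtype covering 5-15% of
    their patches.
    """

    class_labels: tuple = ("A", "AB", "B1", "B2", "B3")
    class_counts: tuple = (21, 83, 48, 49, 21)
    grid_rows: int = 8
    grid_cols: int = 8
    tile_size: int = 64
    feature_dim: int = 64
    signature_separation: float = 3.0
    tumor_patch_frac: float = 0.6
    contaminant_frac: float = 0.2
    foreground_frac: float = 0.85
    cells_per_patch: float = 8.0
    background_lymphocyte_frac: float = 0.9
    cell_params: dict = field(default_factory=lambda: dict(DEFAULT_CELL_PARAMS))
    noise_sd: float = 1.0
    seed: int = 0
    emit_cells: bool = True
    image_mode: bool = False

    def __post_init__(self) -> None:
        if len(self.class_counts) != len(self.class_labels):
            raise ValueError("class_counts must match class_labels")
        if any(c < 1 for c in self.class_counts):
            raise ValueError("all class counts must be >= 1")
        if not (0.0 < self.tumor_patch_frac <= 1.0):
            raise ValueError("tumor_patch_frac must lie in (0, 1]")
        if not (0.0 <= self.contaminant_frac < 1.0):
            raise ValueError("contaminant_frac must lie in [0, 1)")
        if self.feature_dim < len(self.class_labels) + 1:
            raise ValueError("feature_dim must be >= number of classes + 1")
        missing = set(self.class_labels) - set(self.cell_params)
        if missing:
            raise ValueError(f"cell_params missing subtypes: {sorted(missing)}")
        if {"A", "B3"} <= set(self.class_labels):
            lf = {s: self.cell_params[s].lymphocyte_frac for s in self.class_labels}
            cap = max(lf["A"], lf["B3"])
            if any(lf[s] < cap for s in self.class_labels if s not in ("A", "B3")):
                raise ValueError("cell_params must make A and B3 the lymphocyte-poorest")
            if (self.cell_params["B3"].tumor_area_mean
                    < self.cell_params["A"].tumor_area_mean):
                raise ValueError("cell_params must not give B3 smaller tumor nuclei than A")

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def background_label(self) -> int:
        """1-based patch label of the non-tumoral background class (C+1)."""
        return self.n_classes + 1


@dataclass
class PhantomSlide:
    """One generated slide: tiles, patch truth, features, optional image/cells."""

    slide_id: str
    subtype: str
    slide_label: int                 # 1-based subtype index Y in {1..C}
    tiles: TileSet
    patch_truth: np.ndarray          # per-tile truth in {1..C+1}
    features: np.ndarray             # (n_tiles, feature_dim)
    cells: list = field(default_factory=list)
    image: np.ndarray | None = None
    painted_pixels: int | None = None
    contaminant: dict | None = None  # {"subtype", "label", "tiles": set[(r,c)]}

    def __post_init__(self) -> None:
        self.patch_truth = np.asarray(self.patch_truth, dtype=int)
        if not np.any(self.patch_truth == self.slide_label):
            raise ValueError("MIL positivity violated: no patch of the slide class")
        if self.patch_truth.min(initial=1) < 1:
            raise ValueError("patch_truth labels must be >= 1")
        if len(self.features) != len(self.tiles):
            raise ValueError("one feature vector per foreground tile required")
        if len(self.patch_truth) != len(self.tiles):
            raise ValueError("one truth label per foreground tile required")

    def to_bag(self) -> Bag:
        return Bag(slide_id=self.slide_id, Z=self.features, Y=self.slide_label - 1)


def class_signatures(config: PhantomConfig) -> np.ndarray:
    """(C+1, D) class-mean matrix: scaled orthogonal basis vectors.

    Row c (0-based) is the mean of truth class c+1; the last row is the
    background signature.  The scale alpha = separation / sqrt(2) makes the
    distance between any two class means exactly ``signature_separation``.
    """
    alpha = config.signature_separation / np.sqrt(2.0)
    sigs = np.zeros((config.n_classes + 1, config.feature_dim))
    for c in range(config.n_classes + 1):
        sigs[c, c] = alpha
    return sigs


def _ellipse_contour(cx, cy, a, b, theta, n_points=24):
    phi = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    x = cx + a * np.cos(phi) * np.cos(theta) - b * np.sin(phi) * np.sin(theta)
    y = cy + a * np.cos(phi) * np.sin(theta) + b * np.sin(phi) * np.cos(theta)
    return np.column_stack([x, y])


def _sample_cells(config, rng, slide_id, tile, truth_label):
    """Cells of one tile; ellipses sized to stay strictly inside the tile."""
    ts = config.tile_size
    n = rng.poisson(config.cells_per_patch)
    cells = []
    background = truth_label == config.background_label
    if background:
        lymph_frac = config.background_lymphocyte_frac
        params = None
    else:
        params = config.cell_params[config.class_labels[truth_label - 1]]
        lymph_frac = params.lymphocyte_frac
    for j in range(n):
        u = rng.random()
        if u < lymph_frac:
            ctype = "inflammatory"
            area = max(10.0, rng.normal(35.0, 5.0))
            ratio = max(1.01, rng.normal(1.10, 0.05))
        elif background:
            ctype = "other"
            area = max(15.0, rng.normal(45.0, 8.0))
            ratio = max(1.01, rng.normal(1.20, 0.08))
        else:
            ctype = "tumor"
            area = max(20.0, rng.normal(params.tumor_area_mean, params.tumor_area_sd))
            ratio = max(1.0, rng.normal(params.tumor_axis_ratio_mean,
                                        params.tumor_axis_ratio_sd))
        a = np.sqrt(area * ratio / np.pi)
        b = np.sqrt(area / (ratio * np.pi))
        a = min(a, ts / 2.0 - 2.0)
        b = min(b, a)
        cx = tile.x0 + rng.uniform(a + 1.0, ts - a - 1.0)
        cy = tile.y0 + rng.uniform(a + 1.0, ts - a - 1.0)
        theta = rng.uniform(0.0, np.pi)
        mu, sd = _INTENSITY[ctype]
        cells.append(CellRecord(
            cell_id=f"{slide_id}_{tile.row}_{tile.col}_{j}",
            slide_id=slide_id, tile_row=tile.row, tile_col=tile.col,
            type=ctype, contour=_ellipse_contour(cx, cy, a, b, theta),
            centroid=(cx, cy),
            mean_intensity=float(np.clip(rng.normal(mu, sd), 0.0, 255.0)),
        ))
    return cells


def _render_image(config, rng, tiles, cells):
    ts = config.tile_size
    img = np.full((config.grid_rows * ts, config.grid_cols * ts, 3), 255,
                  dtype=np.uint8)
    for t in tiles:
        base = np.asarray(_TISSUE_RGB, float) + rng.normal(0.0, 4.0, 3)
        patch = np.clip(base + rng.normal(0.0, 3.0, (ts, ts, 3)), 0, 255)
        img[t.y0:t.y1, t.x0:t.x1] = patch.astype(np.uint8)
    for c in cells:
        rr, cc = draw_polygon(c.contour[:, 1], c.contour[:, 0], shape=img.shape[:2])
        color = np.asarray(_CELL_RGB[c.type], float)
        shade = np.clip(color * (c.mean_intensity / 120.0), 0, 255)
        img[rr, cc] = shade.astype(np.uint8)
    return img


def generate_slide(config: PhantomConfig, subtype: str, slide_id: str,
                   rng: np.random.Generator) -> PhantomSlide:
    """Generate one phantom slide of the given subtype.

    Foreground tiles are a random subset of the grid; ``tumor_patch_frac``
    of them carry the subtype signature, the rest the background class.
    With probability ``contaminant_frac`` a contiguous rectangular block of
    a second subtype (5-15% of foreground patches) is inserted.  Features
    are class-signature means plus isotropic Gaussian noise.
    """
    if subtype not in config.class_labels:
        raise ValueError(f"unknown subtype {subtype!r}; "
                         f"expected one of {config.class_labels}")
    label = config.class_labels.index(subtype) + 1
    ts, R, C = config.tile_size, config.grid_rows, config.grid_cols
    total = R * C
    n_fg = min(total, max(4, int(round(config.foreground_frac * total))))
    flat = rng.choice(total, size=n_fg, replace=False)
    flat.sort()
    positions = [(int(p) // C, int(p) % C) for p in flat]
    tiles = [TileIndex(row=r, col=c, x0=c * ts, y0=r * ts,
                       x1=(c + 1) * ts, y1=(r + 1) * ts, tissue_frac=1.0)
             for r, c in positions]

    n_tumor = max(1, int(round(config.tumor_patch_frac * n_fg)))
    tumor_idx = rng.choice(n_fg, size=n_tumor, replace=False)
    truth = np.full(n_fg, config.background_label, dtype=int)
    truth[tumor_idx] = label

    contaminant = None
    if config.n_classes > 1 and rng.random() < config.contaminant_frac:
        others = [s for s in config.class_labels if s != subtype]
        minority = others[rng.integers(len(others))]
        m_label = config.class_labels.index(minority) + 1
        share = rng.uniform(0.05, 0.15)
        m = max(1, int(round(share * n_fg)))
        h = int(np.ceil(np.sqrt(m)))
        w = int(np.ceil(m / h))
        h, w = min(h, R), min(w, C)
        r0 = int(rng.integers(R - h + 1))
        c0 = int(rng.integers(C - w + 1))
        block = {(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)}
        hit = [i for i, pos in enumerate(positions) if pos in block]
        if hit:
            truth[np.asarray(hit)] = m_label
            contaminant = {"subtype": minority, "label": m_label,
                           "tiles": {positions[i] for i in hit},
                           "rect": (r0, c0, r0 + h, c0 + w)}
    if not np.any(truth == label):      # restore MIL positivity
        truth[int(rng.integers(n_fg))] = label

    sigs = class_signatures(config)
    features = sigs[truth - 1] + rng.normal(0.0, config.noise_sd,
                                            (n_fg, config.feature_dim))

    tileset = TileSet(slide_id=slide_id, tile_size=ts, grid_rows=R,
                      grid_cols=C, tiles=tiles)
    cells = []
    if config.emit_cells:
        for tile, t_lab in zip(tiles, truth):
            cells.extend(_sample_cells(config, rng, slide_id, tile, int(t_lab)))
    image = painted = None
    if config.image_mode:
        image = _render_image(config, rng, tiles, cells)
        painted = n_fg * ts * ts
    return PhantomSlide(slide_id=slide_id, subtype=subtype, slide_label=label,
                        tiles=tileset, patch_truth=truth, features=features,
                        cells=cells, image=image, painted_pixels=painted,
                        contaminant=contaminant)


def generate_cohort(config: PhantomConfig) -> list[PhantomSlide]:
    """Generate the full cohort: ``class_counts[s]`` slides per subtype.

    Each slide draws from its own child generator spawned from the config
    seed, so the same seed reproduces the cohort bit-identically.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(sum(config.class_counts))
    slides, k = [], 0
    for subtype, count in zip(config.class_labels, config.class_counts):
        for i in range(count):
            rng = np.random.default_rng(children[k])
            slides.append(generate_slide(config, subtype,
                                         f"{subtype}_{i:03d}", rng))
            k += 1
    return slides


def split_cohort(cohort: list[PhantomSlide], fractions=(141 / 222, 42 / 222, 39 / 222),
                 seed: int = 0) -> tuple[list[str], list[str], list[str]]:
    """Stratified train/validation/test split of slide ids.

    Within each subtype, slide counts per split follow largest-remainder
    rounding of the fractions, so every subtype's share tracks the global
    share to within one slide.  The default fractions reproduce a
    141/42/39 split on the default 222-slide cohort.
    """
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_parts = int((fractions > 0).sum())
    rng = np.random.default_rng(seed)
    by_subtype: dict = {}
    for s in cohort:
        by_subtype.setdefault(s.subtype, []).append(s.slide_id)
    splits: tuple = ([], [], [])
    for subtype in by_subtype:
        ids = sorted(by_subtype[subtype])
        if len(ids) < n_parts:
            raise ValueError(f"subtype {subtype!r} has fewer slides "
                             f"({len(ids)}) than nonzero splits ({n_parts})")
        rng.shuffle(ids)
        quota = fractions * len(ids)
        base = np.floor(quota).astype(int)
        rem = len(ids) - base.sum()
        order = np.argsort(-(quota - base), kind="stable")
        for j in order[:rem]:
            base[j] += 1
        pos = 0
        for part, n in zip(splits, base):
            part.extend(ids[pos:pos + n])
            pos += n
    return splits


def bags_from_slides(slides: list[PhantomSlide]):
    """Feature bags plus 0-based labels for a slide list."""
    return [s.to_bag() for s in slides], [s.slide_label - 1 for s in slides]


def write_cohort(out_dir, slides: list[PhantomSlide]) -> None:
    """Write feature bags (.npz), a manifest, cell JSONs and PNG tiles."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in slides:
        np.savez(out / f"{s.slide_id}.npz", features=s.features,
                 patch_truth=s.patch_truth)
        manifest.append({
            "slide_id": s.slide_id, "subtype": s.subtype, "label": s.slide_label,
            "grid": [s.tiles.grid_rows, s.tiles.grid_cols],
            "tile_size": s.tiles.tile_size,
            "tiles": [[t.row, t.col, t.x0, t.y0, t.x1, t.y1] for t in s.tiles.tiles],
        })
        if s.cells:
            (out / f"{s.slide_id}_cells.json").write_text(
                json.dumps(cells_to_hovernet_json(s.cells)))
        if s.image is not None:
            for t in s.tiles.tiles:
                iio.imwrite(out / f"{s.slide_id}_{t.row}_{t.col}.png",
                            s.image[t.y0:t.y1, t.x0:t.x1])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def null_config(config: PhantomConfig | None = None, **overrides) -> PhantomConfig:
    """A copy of the config with all subtype cell effects switched off.

    Every subtype shares one cell parameter set (the average of the
    defaults), so any significant group difference downstream is a false
    positive.  Used to audit family-wise error control.
    """
    base = config or PhantomConfig()
    flat = CellParams(
        lymphocyte_frac=0.5, tumor_area_mean=115.0, tumor_area_sd=22.0,
        tumor_axis_ratio_mean=1.5, tumor_axis_ratio_sd=0.12)
    params = {s: flat for s in base.class_labels}
    return replace(base, cell_params=params, **overrides)
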