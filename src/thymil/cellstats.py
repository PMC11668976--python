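"""Cell-morphology statistics for interpretability validation.

Per-nucleus records (contour + type, in the HoverNet JSON dialect or a flat
CSV) are reduced to morphological features, summarised per slide, grouped
by (tumor subtype x cell type), and compared with a Kruskal-Wallis omnibus
test followed by Dunn's pairwise post hoc test with Benjamini-Hochberg
false-discovery-rate adjustment and star grading.  Instance-segmentation
quality metrics (Dice, fast AJI, AJI+, DQ/SQ/PQ, detection F1) are provided
to audit the upstream segmenter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import linear_sum_assignment
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon
from skimage.measure import regionprops, label as sk_label
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CellRecord", "CellFeatureRow", "SlideCellSummary", "GroupTable",
    "KWResult", "DunnResult",
    "morphology_features", "summarize_slide", "group_features",
    "select_tumor_groups", "kruskal_wallis", "dunn_posthoc", "star_grade",
    "seg_metrics", "violin_export",
    "cells_to_hovernet_json", "cells_from_hovernet_json",
    "cells_to_csv", "cells_from_csv",
    "SUMMARY_FEATURES", "CELL_TYPES",
]

CELL_TYPES = ("tumor", "inflammatory", "other")
TYPE_CODES = {"tumor": 1, "inflammatory": 2, "other": 3}
CODE_TYPES = {v: k for k, v in TYPE_CODES.items()}

# the 12 per-slide summary features: 2 cell types x 6 statistics
SUMMARY_FEATURES = ("proportion", "mean_area", "mean_eccentricity",
                    "mean_solidity", "mean_curvature", "mean_intensity")


# ---------------------------------------------------------------------------
# records


@dataclass
class CellRecord:
    """One segmented nucleus: closed contour polygon, centroid, type."""

    cell_id: str
    slide_id: str
    tile_row: int
    tile_col: int
    type: str
    contour: np.ndarray          # (K, 2) of (x, y) pixel coordinates
    centroid: tuple[float, float]
    mean_intensity: float = float("nan")

    def __post_init__(self) -> None:
        self.contour = np.asarray(self.contour, dtype=float)
        if self.contour.ndim != 2 or self.contour.shape[0] < 3:
            raise ValueError("contour needs at least 3 vertices")
        if self.type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.type!r}")
        x, y = self.centroid
        if not (self.contour[:, 0].min() - 1e-6 <= x <= self.contour[:, 0].max() + 1e-6
                and self.contour[:, 1].min() - 1e-6 <= y <= self.contour[:, 1].max() + 1e-6):
            raise ValueError("centroid outside contour bounding box")


@dataclass
class CellFeatureRow:
    """Morphology of one nucleus (pixel units).

    ``elongation_ratio`` is the axis-ratio eccentricity used in pathology
    morphometry: major axis length over minor axis length (>= 1),
    distinct from conic eccentricity.
    """

    area: float
    major_axis: float
    minor_axis: float
    elongation_ratio: float
    solidity: float
    mean_curvature: float
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.area <= 0 or self.minor_axis <= 0 or self.major_axis < self.minor_axis:
            raise ValueError("degenerate morphology row")


@dataclass
class SlideCellSummary:
    """Per-slide cell summary: 12 features = {tumor, inflammatory} x 6 stats.

    ``proportion`` follows the cohort convention: count of that cell type in
    this slide divided by the grand total cell count over the whole cohort,
    so proportions sum to 1 over all slides and types.
    """

    slide_id: str
    subtype: str
    features: dict = field(default_factory=dict)   # (cell_type, stat) -> value
    counts: dict = field(default_factory=dict)     # cell_type -> count


@dataclass
class GroupTable:
    """(subtype, cell type) -> per-slide values of one summary feature."""

    feature: str
    groups: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class KWResult:
    chi_squared: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.chi_squared < 0 or self.df < 1:
            raise ValueError("invalid Kruskal-Wallis result")


@dataclass
class DunnResult:
    group_i: object
    group_j: object
    Z: float
    p_unadj: float
    p_adj: float
    stars: str


# ---------------------------------------------------------------------------
# morphology


def _rasterize(contour: np.ndarray):
    """Interior pixel coordinates (rows, cols) of the filled polygon."""
    x, y = contour[:, 0], contour[:, 1]
    ox, oy = np.floor(x.min()) - 1, np.floor(y.min()) - 1
    w = int(np.ceil(x.max()) - ox) + 2
    h = int(np.ceil(y.max()) - oy) + 2
    rr, cc = draw_polygon(y - oy, x - ox, shape=(h, w))
    return rr, cc, int(oy), int(ox), (h, w)


def _mean_abs_curvature(contour: np.ndarray, window: int = 5) -> float:
    """Mean absolute turning angle per unit arc length on the smoothed contour.

    The closed contour is smoothed with a circular ``window``-point moving
    average; curvature is total |turning angle| divided by perimeter, which
    recovers 1/r on a circle of radius r.
    """
    k = len(contour)
    idx = (np.arange(k)[:, None] + np.arange(-(window // 2), window // 2 + 1)) % k
    pts = contour[idx].mean(axis=1)
    seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    keep = lengths > 1e-12
    seg, lengths = seg[keep], lengths[keep]
    ang = np.arctan2(seg[:, 1], seg[:, 0])
    turn = np.diff(np.concatenate([ang, ang[:1]]))
    turn = (turn + np.pi) % (2 * np.pi) - np.pi
    perim = lengths.sum()
    if perim <= 0:
        raise ValueError("degenerate contour (zero perimeter)")
    return float(np.abs(turn).sum() / perim)


def morphology_features(cell: CellRecord,
                        intensity_image: np.ndarray | None = None) -> CellFeatureRow:
    """Compute the morphological feature row of one nucleus.

    area = interior pixel count of the filled contour polygon; axis lengths
    follow the equivalent-ellipse convention, 4*sqrt(eigenvalues) of the
    second central moments of the filled region (the regionprops
    convention, computed directly from the interior pixels); solidity =
    polygon area over convex-hull area; curvature as in
    :func:`_mean_abs_curvature`.
    """
    poly = Polygon(cell.contour)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError(f"cell {cell.cell_id}: contour degenerate or self-intersecting")
    rr, cc, oy, ox, shape = _rasterize(cell.contour)
    if rr.size == 0:
        raise ValueError(f"cell {cell.cell_id}: empty rasterisation")
    dy = rr - rr.mean()
    dx = cc - cc.mean()
    mu20 = float(np.mean(dx * dx))
    mu02 = float(np.mean(dy * dy))
    mu11 = float(np.mean(dx * dy))
    half_tr = 0.5 * (mu20 + mu02)
    disc = np.sqrt(max(0.25 * (mu20 - mu02) ** 2 + mu11 * mu11, 0.0))
    major = 4.0 * np.sqrt(max(half_tr + disc, 0.0))
    minor = 4.0 * np.sqrt(max(half_tr - disc, 0.0))
    if minor <= 1e-9:
        raise ValueError(f"cell {cell.cell_id}: collinear contour")
    if intensity_image is not None:
        vals = intensity_image[rr + oy, cc + ox]
        intensity = float(vals.mean()) if vals.size else float("nan")
    else:
        intensity = cell.mean_intensity
    return CellFeatureRow(
        area=float(rr.size),
        major_axis=float(major),
        minor_axis=float(minor),
        elongation_ratio=float(major / minor),
        solidity=float(poly.area / poly.convex_hull.area),
        mean_curvature=_mean_abs_curvature(cell.contour),
        mean_intensity=intensity,
    )


# ---------------------------------------------------------------------------
# slide summaries and grouping


def summarize_slide(cells: list[CellRecord], grand_total: int,
                    subtype: str = "", slide_id: str | None = None,
                    feature_rows: list[CellFeatureRow] | None = None) -> SlideCellSummary:
    """Reduce a slide's cells to the 12 summary features.

    ``grand_total`` is the cohort-wide cell count used as the proportion
    denominator.  A cell type absent from the slide gets proportion 0 and
    NaN means.  Precomputed ``feature_rows`` (aligned with ``cells``) skip
    the per-cell morphology pass.
    """
    if grand_total <= 0:
        raise ValueError("grand_total must be positive")
    if slide_id is None:
        slide_id = cells[0].slide_id if cells else ""
    if feature_rows is None:
        feature_rows = [morphology_features(c) for c in cells]
    feats: dict = {}
    counts: dict = {}
    for ctype in ("tumor", "inflammatory"):
        rows = [r for c, r in zip(cells, feature_rows) if c.type == ctype]
        counts[ctype] = len(rows)
        feats[(ctype, "proportion")] = len(rows) / grand_total
        if rows:
            feats[(ctype, "mean_area")] = float(np.mean([r.area for r in rows]))
            feats[(ctype, "mean_eccentricity")] = float(np.mean([r.elongation_ratio for r in rows]))
            feats[(ctype, "mean_solidity")] = float(np.mean([r.solidity for r in rows]))
            feats[(ctype, "mean_curvature")] = float(np.mean([r.mean_curvature for r in rows]))
            intens = [r.mean_intensity for r in rows if not np.isnan(r.mean_intensity)]
            feats[(ctype, "mean_intensity")] = (float(np.mean(intens)) if intens
                                                else float("nan"))
        else:
            for stat in SUMMARY_FEATURES[1:]:
                feats[(ctype, stat)] = float("nan")
    return SlideCellSummary(slide_id=slide_id, subtype=subtype,
                            features=feats, counts=counts)


def group_features(summaries: list[SlideCellSummary], feature: str,
                   cell_types: tuple = ("tumor", "inflammatory"),
                   subtypes: tuple | None = None) -> GroupTable:
    """Form the (subtype x cell type) groups of one summary feature.

    Five subtypes and two cell types give the canonical ten groups; each
    group holds one value per slide of that subtype.
    """
    if feature not in SUMMARY_FEATURES:
        raise ValueError(f"unknown summary feature {feature!r}")
    if subtypes is None:
        subtypes = tuple(dict.fromkeys(s.subtype for s in summaries))
    groups = {}
    for st in subtypes:
        sel = [s for s in summaries if s.subtype == st]
        if not sel:
            raise ValueError(f"no slides for subtype {st!r}")
        for ct in cell_types:
            groups[(st, ct)] = np.asarray([s.features[(ct, feature)] for s in sel])
    return GroupTable(feature=feature, groups=groups)


def select_tumor_groups(table: GroupTable) -> dict:
    """The five tumor-cell groups used for inter-subtype comparison."""
    return {k: v for k, v in table.groups.items() if k[1] == "tumor"}


# ---------------------------------------------------------------------------
# nonparametric tests


def kruskal_wallis(groups) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with df = number of groups - 1.

    ``groups`` is a mapping name -> values or a sequence of arrays.  The
    p-value comes from the upper tail of the chi-squared distribution with
    df degrees of freedom.  All-identical data gives H = 0, p = 1.
    """
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise ValueError("need >= 2 nonempty groups")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size < 2:
        return KWResult(chi_squared=0.0, df=df, p_value=1.0)
    H, _ = stats.kruskal(*arrays)
    return KWResult(chi_squared=float(H), df=df,
                    p_value=float(stats.chi2.sf(H, df)))


def dunn_posthoc(groups: dict, adjust: str = "fdr_bh") -> list[DunnResult]:
    """Dunn's pairwise post hoc test on pooled ranks after Kruskal-Wallis.

    For each unordered pair (i, j), Z = (Rbar_i - Rbar_j) / SE with the
    tie-corrected pooled-rank standard error
    SE^2 = (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j), T = sum(t^3 - t) over
    tie groups.  Z > 0 means group i ranks (and in the intended reading,
    its median lies) above group j.  Two-sided normal p-values are adjusted
    over the g(g-1)/2 pairs by Benjamini-Hochberg step-up, capped at 1.
    """
    names = list(groups.keys())
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group in Dunn's test")
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    pos = 0
    for a in arrays:
        mean_ranks.append(ranks[pos:pos + a.size].mean())
        sizes.append(a.size)
        pos += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts ** 3 - counts))
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    pairs, zs, ps = [], [], []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            pairs.append((names[i], names[j]))
            zs.append(z)
            ps.append(2.0 * stats.norm.sf(abs(z)))
    p_adj = multipletests(ps, method=adjust)[1] if pairs else []
    return [DunnResult(group_i=a, group_j=b, Z=float(z),
                       p_unadj=float(p), p_adj=float(q), stars=star_grade(q))
            for (a, b), z, p, q in zip(pairs, zs, ps, p_adj)]


def star_grade(p_adj: float) -> str:
    """Significance stars: <0.05 *, <0.01 **, <0.001 ***, <0.0001 ****, else ns."""
    if not (0.0 <= p_adj <= 1.0):
        raise ValueError("p-value out of [0, 1]")
    if p_adj < 0.0001:
        return "****"
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"


def dunn_table(results: list[DunnResult], feature: str = "") -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": feature, "group_i": str(r.group_i), "group_j": str(r.group_j),
        "Z": r.Z, "p.unadj": r.p_unadj, "p.adj": r.p_adj, "stars": r.stars,
    } for r in results])


# ---------------------------------------------------------------------------
# segmentation / detection metrics


def _pair_intersections(true_map: np.ndarray, pred_map: np.ndarray):
    t_ids = np.unique(true_map[true_map > 0])
    p_ids = np.unique(pred_map[pred_map > 0])
    t_area = {int(t): int((true_map == t).sum()) for t in t_ids}
    p_area = {int(p): int((pred_map == p).sum()) for p in p_ids}
    inter: dict = {}
    both = (true_map > 0) & (pred_map > 0)
    pairs, counts = np.unique(
        np.stack([true_map[both], pred_map[both]]), axis=1, return_counts=True)
    for (t, p), c in zip(pairs.T, counts):
        inter[(int(t), int(p))] = int(c)
    return [int(t) for t in t_ids], [int(p) for p in p_ids], t_area, p_area, inter


def seg_metrics(pred_map: np.ndarray, true_map: np.ndarray,
                pred_types: dict | None = None, true_types: dict | None = None,
                match_radius: float = 12.0) -> dict:
    """Instance-segmentation and detection quality metrics.

    Maps are integer instance-label images (0 = background).  Returns
    pixel-level Dice on the binarised maps; fast AJI (greedy best-IoU
    matching in ground-truth label order, each prediction usable once);
    AJI+ (optimal one-to-one IoU matching); DQ, SQ and PQ = DQ*SQ at the
    IoU > 0.5 matching; and, when per-instance type maps are given,
    per-type and micro-average detection F1 with centroids matched within
    ``match_radius`` pixels.
    """
    pred_map = np.asarray(pred_map)
    true_map = np.asarray(true_map)
    if pred_map.shape != true_map.shape:
        raise ValueError("instance maps must share a shape")
    out: dict = {}

    tb, pb = true_map > 0, pred_map > 0
    denom = tb.sum() + pb.sum()
    out["dice"] = float(2.0 * (tb & pb).sum() / denom) if denom > 0 else 1.0

    t_ids, p_ids, t_area, p_area, inter = _pair_intersections(true_map, pred_map)

    def iou(t, p):
        i = inter.get((t, p), 0)
        return i / (t_area[t] + p_area[p] - i)

    # fast AJI: greedy, ground-truth order, predictions consumed once
    used, C, U = set(), 0, 0
    for t in t_ids:
        cands = [p for p in p_ids if (t, p) in inter and p not in used]
        if cands:
            best = max(cands, key=lambda p: iou(t, p))
            i = inter[(t, best)]
            C += i
            U += t_area[t] + p_area[best] - i
            used.add(best)
        else:
            U += t_area[t]
    U += sum(p_area[p] for p in p_ids if p not in used)
    out["fast_aji"] = float(C / U) if U > 0 else 1.0

    # AJI+: optimal one-to-one matching by IoU
    if t_ids and p_ids:
        M = np.zeros((len(t_ids), len(p_ids)))
        for a, t in enumerate(t_ids):
            for b, p in enumerate(p_ids):
                M[a, b] = iou(t, p)
        ri, ci = linear_sum_assignment(-M)
        C2 = U2 = 0
        matched_t, matched_p = set(), set()
        for a, b in zip(ri, ci):
            if M[a, b] > 0:
                t, p = t_ids[a], p_ids[b]
                i = inter[(t, p)]
                C2 += i
                U2 += t_area[t] + p_area[p] - i
                matched_t.add(t)
                matched_p.add(p)
        U2 += sum(t_area[t] for t in t_ids if t not in matched_t)
        U2 += sum(p_area[p] for p in p_ids if p not in matched_p)
        out["fast_aji_plus"] = float(C2 / U2) if U2 > 0 else 0.0
    else:
        out["fast_aji_plus"] = 1.0 if not t_ids and not p_ids else 0.0

    # panoptic quality at IoU > 0.5 (matches are provably unique)
    tp_pairs = [(t, p) for (t, p) in inter if iou(t, p) > 0.5]
    TP = len(tp_pairs)
    FP = len(p_ids) - TP
    FN = len(t_ids) - TP
    if TP + FP + FN == 0:
        out["dq"] = out["sq"] = out["pq"] = 1.0
    else:
        out["dq"] = TP / (TP + 0.5 * FP + 0.5 * FN)
        out["sq"] = float(np.mean([iou(t, p) for t, p in tp_pairs])) if TP else 0.0
        out["pq"] = out["dq"] * out["sq"]

    # typed detection F1 via centroid matching
    if pred_types is not None and true_types is not None:
        t_cent = {t: ndimage.center_of_mass(true_map == t) for t in t_ids}
        p_cent = {p: ndimage.center_of_mass(pred_map == p) for p in p_ids}
        pairs = []
        if t_ids and p_ids:
            D = np.full((len(t_ids), len(p_ids)), 1e9)
            for a, t in enumerate(t_ids):
                for b, p in enumerate(p_ids):
                    d = np.hypot(t_cent[t][0] - p_cent[p][0],
                                 t_cent[t][1] - p_cent[p][1])
                    if d <= match_radius:
                        D[a, b] = d
            ri, ci = linear_sum_assignment(D)
            pairs = [(t_ids[a], p_ids[b]) for a, b in zip(ri, ci) if D[a, b] <= match_radius]
        types = sorted(set(true_types.values()) | set(pred_types.values()),
                       key=str)
        per_type, agg = {}, [0, 0, 0]
        for ty in types:
            tp = sum(1 for t, p in pairs
                     if true_types.get(t) == ty and pred_types.get(p) == ty)
            fp = sum(1 for p in p_ids if pred_types.get(p) == ty) - tp
            fn = sum(1 for t in t_ids if true_types.get(t) == ty) - tp
            f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
            per_type[ty] = f1
            agg[0] += tp
            agg[1] += fp
            agg[2] += fn
        out["type_f1"] = per_type
        tp, fp, fn = agg
        out["micro_f1"] = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# tidy export


def violin_export(table: GroupTable):
    """Long-format values plus per-group median/quartile summaries.

    Returns ``(long, summary)`` DataFrames sufficient to regenerate
    violin-style group plots (median dot, quartiles, per-group n).
    """
    long_rows, sum_rows = [], []
    for (subtype, ctype), values in table.groups.items():
        values = np.asarray(values, dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise ValueError(f"group {(subtype, ctype)} has no finite values")
        for v in values:
            long_rows.append({"subtype": subtype, "cell_type": ctype,
                              "feature": table.feature, "value": float(v)})
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        sum_rows.append({"subtype": subtype, "cell_type": ctype,
                         "feature": table.feature, "median": float(med),
                         "q1": float(q1), "q3": float(q3), "n": int(values.size)})
    return pd.DataFrame(long_rows), pd.DataFrame(sum_rows)


# ---------------------------------------------------------------------------
# HoverNet-style JSON and CSV dialects


def cells_to_hovernet_json(cells: list[CellRecord]) -> dict:
    """Serialise cells to the HoverNet output dialect: a top-level 'nuc' map."""
    nuc = {}
    for c in cells:
        x, y = c.contour[:, 0], c.contour[:, 1]
        nuc[str(c.cell_id)] = {
            "bbox": [[float(y.min()), float(x.min())], [float(y.max()), float(x.max())]],
            "centroid": [float(c.centroid[0]), float(c.centroid[1])],
            "contour": [[float(px), float(py)] for px, py in c.contour],
            "type": TYPE_CODES[c.type],
            "type_prob": 1.0,
        }
    return {"nuc": nuc}


def cells_from_hovernet_json(data: dict | str, slide_id: str = "",
                             tile_size: int | None = None) -> list[CellRecord]:
    """Parse the HoverNet 'nuc' dialect into CellRecords.

    With ``tile_size`` given, tile row/col are derived from the centroid;
    otherwise they are 0.  Integer types map through the standard code
    table; unknown codes become 'other'.
    """
    if isinstance(data, str):
        data = json.loads(data)
    cells = []
    for cid, rec in data["nuc"].items():
        cx, cy = float(rec["centroid"][0]), float(rec["centroid"][1])
        row = int(cy // tile_size) if tile_size else 0
        col = int(cx // tile_size) if tile_size else 0
        cells.append(CellRecord(
            cell_id=str(cid), slide_id=slide_id, tile_row=row, tile_col=col,
            type=CODE_TYPES.get(int(rec["type"]), "other"),
            contour=np.asarray(rec["contour"], dtype=float),
            centroid=(cx, cy),
            mean_intensity=float(rec.get("mean_intensity", float("nan"))),
        ))
    return cells


def cells_to_csv(cells: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append({
            "cell_id": c.cell_id, "slide_id": c.slide_id,
            "tile_row": c.tile_row, "tile_col": c.tile_col, "type": c.type,
            "centroid_x": c.centroid[0], "centroid_y": c.centroid[1],
            "mean_intensity": c.mean_intensity,
            "contour": ";".join(f"{x:.2f} {y:.2f}" for x, y in c.contour),
        })
    return pd.DataFrame(rows)


def cells_from_csv(df: pd.DataFrame) -> list[CellRecord]:
    cells = []
    for _, r in df.iterrows():
        contour = np.asarray([[float(v) for v in pt.split()]
                              for pt in str(r["contour"]).split(";")])
        cells.append(CellRecord(
            cell_id=str(r["cell_id"]), slide_id=str(r["slide_id"]),
            tile_row=int(r["tile_row"]), tile_col=int(r["tile_col"]),
            type=str(r["type"]), contour=contour,
            centroid=(float(r["centroid_x"]), float(r["centroid_y"])),
            mean_intensity=float(r.get("mean_intensity", float("nan"))),
        ))
    return cells
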