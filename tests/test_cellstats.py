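"""Cell morphology, group statistics, segmentation metrics, I/O dialects."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from thymil import cellstats as cs


def cell(contour, ctype="tumor", cid="c0"):
    contour = np.asarray(contour, dtype=float)
    return cs.CellRecord(cell_id=cid, slide_id="s", tile_row=0, tile_col=0,
                         type=ctype, contour=contour,
                         centroid=tuple(contour.mean(axis=0)))


def ellipse(cx, cy, a, b, theta=0.0, n=24):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = cx + a * np.cos(phi) * np.cos(theta) - b * np.sin(phi) * np.sin(theta)
    y = cy + a * np.cos(phi) * np.sin(theta) + b * np.sin(phi) * np.cos(theta)
    return np.column_stack([x, y])


class TestMorphology:
    def test_square_features(self):
        # 10x10 pixel square: corners span rows/cols 0..9
        r = cs.morphology_features(cell([[0, 0], [9, 0], [9, 9], [0, 9]]))
        assert r.area == 100
        assert r.solidity == pytest.approx(1.0)
        assert r.elongation_ratio == pytest.approx(1.0)

    def test_rectangle_elongation_matches_moment_oracle(self):
        r = cs.morphology_features(cell([[0, 0], [39, 0], [39, 9], [0, 9]]))
        # brute-force oracle: second moments of the 40x10 pixel block
        xs, ys = np.meshgrid(np.arange(40), np.arange(10))
        vx = xs.var()
        vy = ys.var()
        assert r.elongation_ratio == pytest.approx(np.sqrt(vx / vy), rel=1e-6)
        assert abs(r.elongation_ratio - 4.0) / 4.0 < 0.05

    def test_circle_curvature_is_inverse_radius(self):
        r = cs.morphology_features(cell(ellipse(25, 25, 20, 20, n=64)))
        assert abs(r.mean_curvature - 1 / 20) / (1 / 20) < 0.10
        assert abs(r.area - np.pi * 400) / (np.pi * 400) < 0.05

    def test_ellipse_axes_recover_generator_parameters(self):
        r = cs.morphology_features(cell(ellipse(30, 30, 12, 6, theta=0.7)))
        assert r.elongation_ratio == pytest.approx(2.0, rel=0.08)

    def test_collinear_contour_rejected(self):
        with pytest.raises(ValueError, match="degenerate|collinear"):
            cs.morphology_features(cell([[0, 0], [5, 0], [10, 0]]))

    def test_self_intersecting_contour_rejected(self):
        bowtie = [[0, 0], [10, 10], [10, 0], [0, 10]]
        with pytest.raises(ValueError, match="self-intersecting|degenerate"):
            cs.morphology_features(cell(bowtie))

    def test_intensity_from_image_when_given(self):
        img = np.full((20, 20), 7.0)
        r = cs.morphology_features(cell([[2, 2], [9, 2], [9, 9], [2, 9]]),
                                   intensity_image=img)
        assert r.mean_intensity == pytest.approx(7.0)


class TestSummaries:
    def test_proportion_uses_cohort_grand_total(self):
        cells = [cell(ellipse(10, 10, 4, 3), "tumor", f"t{i}") for i in range(4)]
        cells += [cell(ellipse(10, 10, 3, 3), "inflammatory", f"i{i}")
                  for i in range(6)]
        s = cs.summarize_slide(cells, grand_total=10, subtype="A")
        assert s.features[("tumor", "proportion")] == pytest.approx(0.4)
        assert s.features[("inflammatory", "proportion")] == pytest.approx(0.6)

    def test_identical_cells_give_their_own_mean_area(self):
        c0 = cell(ellipse(15, 15, 5, 4), "tumor")
        area = cs.morphology_features(c0).area
        cells = [cell(ellipse(15, 15, 5, 4), "tumor", f"t{i}") for i in range(3)]
        s = cs.summarize_slide(cells, grand_total=3)
        assert s.features[("tumor", "mean_area")] == pytest.approx(area)

    def test_absent_type_gets_zero_proportion_and_nan_means(self):
        cells = [cell(ellipse(10, 10, 4, 3), "tumor")]
        s = cs.summarize_slide(cells, grand_total=5)
        assert s.features[("inflammatory", "proportion")] == 0.0
        assert np.isnan(s.features[("inflammatory", "mean_area")])

    def test_twelve_summary_features(self):
        cells = [cell(ellipse(10, 10, 4, 3), "tumor")]
        s = cs.summarize_slide(cells, grand_total=1)
        assert len(s.features) == 12

    def test_cohort_proportions_sum_to_one(self, cohort_summaries):
        summaries, _ = cohort_summaries
        total = sum(s.features[(t, "proportion")]
                    for s in summaries for t in ("tumor", "inflammatory"))
        # 'other' cells in background tiles also count toward the grand total
        assert total <= 1.0 + 1e-9
        counted = sum(s.counts["tumor"] + s.counts["inflammatory"]
                      for s in summaries)
        grand = cohort_summaries[1]
        assert total == pytest.approx(counted / grand, abs=1e-9)

    def test_phantom_recovers_generator_area_means(self, cohort_summaries,
                                                   default_cohort):
        """Per-subtype mean tumor area within 2 SE of the cohort estimate."""
        from thymil.synthetic import DEFAULT_CELL_PARAMS
        summaries, _ = cohort_summaries
        for subtype in ("A", "B3"):
            vals = np.array([s.features[("tumor", "mean_area")]
                             for s in summaries if s.subtype == subtype])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            target = DEFAULT_CELL_PARAMS[subtype].tumor_area_mean
            # rasterised polygon area is within a few pixels of pi*a*b
            assert abs(vals.mean() - target) < max(2 * se, 0.03 * target)

    def test_zero_grand_total_rejected(self):
        with pytest.raises(ValueError, match="grand_total"):
            cs.summarize_slide([], grand_total=0)


class TestGrouping:
    def test_five_subtypes_two_types_give_ten_groups(self, cohort_summaries):
        summaries, _ = cohort_summaries
        table = cs.group_features(summaries, "mean_area")
        assert table.n_groups == 10

    def test_tumor_selection_gives_five_groups(self, cohort_summaries):
        summaries, _ = cohort_summaries
        tumor = cs.select_tumor_groups(cs.group_features(summaries, "mean_area"))
        assert len(tumor) == 5
        assert all(ct == "tumor" for _, ct in tumor)

    def test_group_sizes_equal_subtype_slide_counts(self, cohort_summaries):
        summaries, _ = cohort_summaries
        table = cs.group_features(summaries, "proportion")
        assert len(table.groups[("AB", "tumor")]) == 83
        assert len(table.groups[("A", "inflammatory")]) == 21

    def test_two_subtypes_two_types_give_four_groups(self, cohort_summaries):
        summaries, _ = cohort_summaries
        sub = [s for s in summaries if s.subtype in ("A", "B3")]
        assert cs.group_features(sub, "mean_area").n_groups == 4

    def test_empty_subtype_rejected(self, cohort_summaries):
        summaries, _ = cohort_summaries
        with pytest.raises(ValueError, match="no slides"):
            cs.group_features(summaries, "mean_area",
                              subtypes=("A", "missing"))

    def test_unknown_feature_rejected(self, cohort_summaries):
        summaries, _ = cohort_summaries
        with pytest.raises(ValueError, match="unknown summary feature"):
            cs.group_features(summaries, "perimeter")


class TestKruskalWallis:
    def test_df_is_groups_minus_one(self):
        groups = [np.arange(4) + i for i in range(5)]
        assert cs.kruskal_wallis(groups).df == 4

    def test_identical_groups_give_null_result(self):
        res = cs.kruskal_wallis([np.ones(5), np.ones(4)])
        assert res.chi_squared == 0.0
        assert res.p_value == 1.0

    def test_p_value_matches_permutation_oracle(self):
        """Chi-squared p within Monte-Carlo error of a permutation null."""
        rng = np.random.default_rng(0)
        groups = [np.array([1.2, 3.4, 0.5, 2.2]),
                  np.array([2.9, 4.1, 3.3, 5.0]),
                  np.array([0.1, 1.0, 2.5, 0.7])]
        res = cs.kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        sizes = [len(g) for g in groups]
        n = len(pooled)

        def h_stat(r):
            pos, h = 0, 0.0
            for m in sizes:
                h += r[pos:pos + m].sum() ** 2 / m
                pos += m
            return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)

        perms = 100_000
        mat = np.tile(ranks, (perms, 1))
        mat = rng.permuted(mat, axis=1)
        h_obs = h_stat(ranks)
        h_null = np.apply_along_axis(h_stat, 1, mat)
        p_perm = float(np.mean(h_null >= h_obs - 1e-12))
        assert abs(res.p_value - p_perm) < 0.02

    def test_matches_scipy_on_the_h_statistic(self):
        groups = [np.array([1.0, 2, 2, 3]), np.array([2.0, 3, 4]),
                  np.array([5.0, 6, 6])]
        res = cs.kruskal_wallis(groups)
        h, _ = stats.kruskal(*groups)
        assert res.chi_squared == pytest.approx(h)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            cs.kruskal_wallis([np.ones(3)])


def bh_stepup_oracle(pvals):
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestDunn:
    def test_five_groups_give_ten_pairs(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(i, 1, 8) for i in range(5)}
        assert len(cs.dunn_posthoc(groups)) == 10

    def test_z_sign_positive_when_first_group_ranks_higher(self):
        res = cs.dunn_posthoc({"hi": np.arange(10) + 100,
                               "lo": np.arange(10)})
        assert res[0].group_i == "hi"
        assert res[0].Z > 0

    def test_adjustment_matches_independent_bh_oracle(self):
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.normal(0.3 * i, 1, 6) for i in range(4)}
        res = cs.dunn_posthoc(groups)
        adj = bh_stepup_oracle([r.p_unadj for r in res])
        np.testing.assert_allclose([r.p_adj for r in res], adj, atol=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=20))
    def test_bh_is_a_monotone_capped_stepup_transform(self, pvals):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(pvals, method="fdr_bh")[1]
        oracle = bh_stepup_oracle(pvals)
        np.testing.assert_allclose(adj, oracle, atol=1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)

    def test_z_matches_hand_computation_without_ties(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0, 7.0])
        res = cs.dunn_posthoc({"a": a, "b": b})[0]
        n = 7
        se = np.sqrt(n * (n + 1) / 12 * (1 / 3 + 1 / 4))
        z = (2.0 - 5.5) / se
        assert res.Z == pytest.approx(z)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            cs.dunn_posthoc({"a": np.array([]), "b": np.ones(3)})


class TestStarGrade:
    @pytest.mark.parametrize("p,grade", [
        (0.03, "*"), (0.0005, "***"), (0.05, "ns"), (0.2, "ns"),
        (0.009, "**"), (0.00005, "****"), (0.0001, "***"), (0.01, "*"),
    ])
    def test_threshold_brackets(self, p, grade):
        assert cs.star_grade(p) == grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.star_grade(1.5)


def toy_maps():
    """3 truth vs 3 pred instances with one half-overlap, on a 10x10 grid."""
    t = np.zeros((10, 10), int)
    p = np.zeros((10, 10), int)
    t[0:3, 0:3] = 1          # matched exactly by pred 1
    p[0:3, 0:3] = 1
    t[5:9, 0:4] = 2          # half-overlapped by pred 2
    p[7:9, 0:4] = 2
    t[0:2, 6:8] = 3          # missed; pred 3 is spurious elsewhere
    p[8:10, 8:10] = 3
    return p, t


def seg_oracle(pred, true):
    """Exhaustive matching oracle for <= 5 instances per map."""
    t_ids = sorted(set(true[true > 0].ravel()))
    p_ids = sorted(set(pred[pred > 0].ravel()))
    area_t = {t: int((true == t).sum()) for t in t_ids}
    area_p = {p: int((pred == p).sum()) for p in p_ids}

    def inter(t, p):
        return int(((true == t) & (pred == p)).sum())

    def iou(t, p):
        i = inter(t, p)
        return i / (area_t[t] + area_p[p] - i)

    # fast AJI: greedy in truth order, preds used once
    used, C, U = set(), 0, 0
    for t in t_ids:
        cands = [p for p in p_ids if inter(t, p) > 0 and p not in used]
        if cands:
            best = max(cands, key=lambda p: iou(t, p))
            C += inter(t, best)
            U += area_t[t] + area_p[best] - inter(t, best)
            used.add(best)
        else:
            U += area_t[t]
    U += sum(area_p[p] for p in p_ids if p not in used)
    fast_aji = C / U

    # AJI+: best one-to-one assignment over all permutations
    best_score = None
    k = min(len(t_ids), len(p_ids))
    for perm in itertools.permutations(p_ids, k):
        C2 = U2 = 0
        matched_p = set()
        for t, p in zip(t_ids, perm):
            if iou(t, p) > 0:
                C2 += inter(t, p)
                U2 += area_t[t] + area_p[p] - inter(t, p)
                matched_p.add(p)
            else:
                U2 += area_t[t]
        for t in t_ids[k:]:
            U2 += area_t[t]
        U2 += sum(area_p[p] for p in p_ids if p not in matched_p)
        score = C2 / U2
        if best_score is None or score > best_score:
            best_score = score
    # the greedy truth-order loop above under-counts unmatched truths when
    # k < len(t_ids); handled by the slice, so best_score is the oracle
    tp_pairs = [(t, p) for t in t_ids for p in p_ids if iou(t, p) > 0.5]
    TP = len(tp_pairs)
    FP, FN = len(p_ids) - TP, len(t_ids) - TP
    dq = TP / (TP + 0.5 * FP + 0.5 * FN)
    sq = np.mean([iou(t, p) for t, p in tp_pairs]) if TP else 0.0
    tb, pb = true > 0, pred > 0
    dice = 2 * (tb & pb).sum() / (tb.sum() + pb.sum())
    return {"dice": dice, "fast_aji": fast_aji, "fast_aji_plus": best_score,
            "dq": dq, "sq": sq, "pq": dq * sq}


class TestSegMetrics:
    def test_identical_maps_are_perfect(self):
        m = np.zeros((8, 8), int)
        m[0:3, 0:3] = 1
        m[5:8, 5:8] = 2
        out = cs.seg_metrics(m, m)
        for key in ("dice", "fast_aji", "fast_aji_plus", "dq", "sq", "pq"):
            assert out[key] == pytest.approx(1.0), key

    def test_disjoint_instances_score_zero(self):
        t = np.zeros((8, 8), int)
        p = np.zeros((8, 8), int)
        t[0:2, 0:2] = 1
        p[5:7, 5:7] = 1
        out = cs.seg_metrics(p, t)
        assert out["dice"] == 0.0
        assert out["fast_aji"] == 0.0
        assert out["pq"] == 0.0

    def test_toy_maps_match_exhaustive_oracle(self):
        p, t = toy_maps()
        out = cs.seg_metrics(p, t)
        oracle = seg_oracle(p, t)
        for key, val in oracle.items():
            assert out[key] == pytest.approx(val), key

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share a shape"):
            cs.seg_metrics(np.zeros((4, 4), int), np.zeros((5, 5), int))

    def test_typed_detection_f1(self):
        t = np.zeros((12, 12), int)
        p = np.zeros((12, 12), int)
        t[0:3, 0:3] = 1          # tumor, detected
        p[0:3, 0:3] = 1
        t[8:11, 8:11] = 2        # inflammatory, missed
        p[8:11, 0:3] = 2         # spurious tumor detection
        out = cs.seg_metrics(p, t, pred_types={1: "tumor", 2: "tumor"},
                             true_types={1: "tumor", 2: "inflammatory"})
        assert out["type_f1"]["tumor"] == pytest.approx(2 / 3)
        assert out["type_f1"]["inflammatory"] == 0.0
        # micro: TP=1, FP=1, FN=1
        assert out["micro_f1"] == pytest.approx(0.5)


class TestViolinExport:
    def test_row_counts(self):
        groups = {(s, t): np.arange(3) + 1.0
                  for s in ("A", "AB", "B1", "B2", "B3")
                  for t in ("tumor", "inflammatory")}
        table = cs.GroupTable(feature="mean_area", groups=groups)
        long, summary = cs.violin_export(table)
        assert len(long) == 30
        assert len(summary) == 10

    def test_median_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=11)
        table = cs.GroupTable(feature="mean_area",
                              groups={("A", "tumor"): vals})
        _, summary = cs.violin_export(table)
        assert summary["median"][0] == pytest.approx(sorted(vals)[5])

    def test_empty_group_rejected(self):
        table = cs.GroupTable(feature="mean_area",
                              groups={("A", "tumor"): np.array([np.nan])})
        with pytest.raises(ValueError, match="no finite"):
            cs.violin_export(table)


class TestCellIO:
    def test_hovernet_json_round_trip(self):
        cells = [cell(ellipse(20, 30, 5, 3), "tumor", "1"),
                 cell(ellipse(40, 10, 3, 3), "inflammatory", "2")]
        data = cs.cells_to_hovernet_json(cells)
        assert set(data["nuc"]) == {"1", "2"}
        back = cs.cells_from_hovernet_json(json.dumps(data), slide_id="s",
                                           tile_size=64)
        assert back[0].type == "tumor"
        assert back[1].type == "inflammatory"
        np.testing.assert_allclose(back[0].contour, cells[0].contour)

    def test_csv_round_trip(self):
        cells = [cell(ellipse(20, 30, 5, 3), "tumor", "a")]
        df = cs.cells_to_csv(cells)
        back = cs.cells_from_csv(df)
        assert back[0].cell_id == "a"
        np.testing.assert_allclose(back[0].contour, cells[0].contour,
                                   atol=0.01)

    def test_record_validation(self):
        with pytest.raises(ValueError, match="3 vertices"):
            cs.CellRecord(cell_id="x", slide_id="s", tile_row=0, tile_col=0,
                          type="tumor", contour=np.zeros((2, 2)),
                          centroid=(0, 0))
        with pytest.raises(ValueError, match="unknown cell type"):
            cell(ellipse(5, 5, 2, 2), ctype="stromal")
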