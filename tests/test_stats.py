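"""Chi-square p-values, Bonferroni/cluster thresholding, table summaries."""

import numpy as np
import pytest
from scipy import stats as sps

import mslight as m
from mslight.stats import threshold_regime


class TestAccuracyPvalue:
    def test_chance_symmetric_table_gives_p_one(self):
        assert m.accuracy_pvalue(m.ConfusionCounts(10, 10, 13, 13)) == pytest.approx(1.0)

    def test_high_accuracy_table_matches_reported_magnitude(self):
        """Sensitivity 39/41, specificity 26/26 at N=67: chi-square ~59.2,
        far below the 1e-13 tail."""
        p = m.accuracy_pvalue(m.ConfusionCounts(39, 2, 26, 0))
        assert p < 1e-13

    def test_matches_contingency_oracle(self, rng):
        for _ in range(50):
            tp, fn = rng.integers(0, 20), rng.integers(0, 20)
            tn, fp = rng.integers(0, 20), rng.integers(0, 20)
            c = m.ConfusionCounts(int(tp), int(fn), int(tn), int(fp))
            table = np.array([[tp, fn], [fp, tn]])
            if c.n_ms == 0 or c.n_hc == 0 or min(table.sum(axis=0)) == 0:
                continue
            stat, p_ref, _, _ = sps.chi2_contingency(table, correction=False)
            assert m.accuracy_pvalue(c) == pytest.approx(p_ref, rel=1e-10)

    def test_degenerate_margin_gives_p_one(self):
        # every subject predicted patient: no association testable
        assert m.accuracy_pvalue(m.ConfusionCounts(41, 0, 0, 26)) == 1.0

    def test_monotone_in_accuracy_with_fixed_margins(self):
        ps = [m.accuracy_pvalue(m.ConfusionCounts(tp, 41 - tp, 26, 0))
              for tp in range(21, 42)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBonferroni:
    def test_single_test_threshold_is_alpha(self):
        p = np.full((3, 3, 3), np.nan)
        p[1, 1, 1] = 0.04
        assert m.bonferroni(p, 0.05)[1, 1, 1]
        p[1, 1, 1] = 0.06
        assert not m.bonferroni(p, 0.05).any()

    def test_uniform_sub_threshold_all_significant(self):
        p = np.full((4, 4, 4), np.nan)
        p[:2] = 0.05 / (33)  # m = 32 defined centers
        sig = m.bonferroni(p, 0.05)
        assert sig[:2].all() and not sig[2:].any()

    def test_no_defined_centers_rejected(self):
        with pytest.raises(ValueError):
            m.bonferroni(np.full((2, 2, 2), np.nan), 0.05)


def flood_fill_components(mask, connectivity):
    """Independent BFS connected-components oracle."""
    offsets = []
    for d in np.ndindex(3, 3, 3):
        d = np.array(d) - 1
        if not d.any():
            continue
        order = int(np.abs(d).sum())
        if (connectivity == 6 and order == 1) or \
           (connectivity == 18 and order <= 2) or connectivity == 26:
            offsets.append(d)
    seen = np.zeros_like(mask, bool)
    comps = []
    for start in np.argwhere(mask):
        if seen[tuple(start)]:
            continue
        comp, queue = [], [start]
        seen[tuple(start)] = True
        while queue:
            v = queue.pop()
            comp.append(tuple(v))
            for off in offsets:
                w = v + off
                if np.all((w >= 0) & (w < mask.shape)) and mask[tuple(w)] \
                        and not seen[tuple(w)]:
                    seen[tuple(w)] = True
                    queue.append(w)
        comps.append(frozenset(comp))
    return set(comps)


class TestClusterFilter:
    def test_isolated_center_removed_at_k5(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[4, 4, 4] = True
        assert m.cluster_filter(mask, k=5) == []

    def test_five_center_component_survives_at_k5(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:7, 4, 4] = True
        clusters = m.cluster_filter(mask, k=5)
        assert len(clusters) == 1 and len(clusters[0]) == 5

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        mask = rng.random((10, 10, 10)) < 0.2
        got = {frozenset(map(tuple, c)) for c in m.cluster_filter(mask, 1, connectivity)}
        assert got == flood_fill_components(mask, connectivity)


class TestTContrast:
    def test_identical_group_means_give_zero(self, pre_unc):
        # remove each group's mean so the two group means coincide exactly
        X = pre_unc.data.copy()
        for g in (0, 1):
            rows = pre_unc.labels == g
            X[rows] -= X[rows].mean(axis=0)
        from dataclasses import replace

        sym = replace(pre_unc, data=X)
        t = m.voxelwise_t_contrast(sym, pre_unc.voxel_coords[:10])
        assert np.allclose(np.nan_to_num(t), 0.0, atol=1e-10)

    def test_label_swap_negates_t(self, pre_unc):
        from dataclasses import replace

        vox = pre_unc.voxel_coords[:30]
        t = m.voxelwise_t_contrast(pre_unc, vox)
        swapped = replace(pre_unc, labels=1 - pre_unc.labels)
        assert np.allclose(m.voxelwise_t_contrast(swapped, vox), -t, atol=1e-10)

    def test_matches_pooled_t_oracle(self, pre_unc):
        vox = pre_unc.voxel_coords[:50]
        t = m.voxelwise_t_contrast(pre_unc, vox)
        X = pre_unc.data[:, [pre_unc.column_of(tuple(v)) for v in vox]]
        ref = sps.ttest_ind(X[pre_unc.labels == 1], X[pre_unc.labels == 0],
                            equal_var=True).statistic
        assert np.allclose(t, ref, atol=1e-10)


def _toy_accuracy_map(shape=(9, 9, 9), radius=1):
    acc = np.full(shape, np.nan)
    nvox = np.zeros(shape, np.int64)
    tp = np.full(shape, -1, np.int64)
    fn = np.full(shape, -1, np.int64)
    tn = np.full(shape, -1, np.int64)
    fp = np.full(shape, -1, np.int64)
    return acc, nvox, tp, fn, tn, fp


class TestClusterSummary:
    def _map(self, centers, accs, counts):
        acc, nvox, tp, fn, tn, fp = _toy_accuracy_map()
        for c, a, (t1, f1, t2, f2) in zip(centers, accs, counts):
            acc[c] = a
            tp[c], fn[c], tn[c], fp[c] = t1, f1, t2, f2
            nvox[c] = 1
        return m.AccuracyMap(
            accuracy_pct=acc, n_voxels=nvox, tp=tp, fn=fn, tn=tn, fp=fp,
            spec=m.sphere_offsets(1), variant="uncorrected", space="lesion",
            voxel_size_mm=np.array([2.0, 2.0, 2.0]),
        )

    def test_zero_t_underlying_voxels(self):
        centers = [(4, 4, 4), (4, 4, 5)]
        amap = self._map(centers, [80.0, 70.0],
                         [(8, 2, 7, 1), (7, 3, 6, 2)])
        t_map = np.zeros((9, 9, 9))
        row = m.cluster_summary(np.array(centers), amap.spec, amap, t_map,
                                alpha_vox=0.001, data_df=16)
        assert row.vox_star_pct == 0.0 and row.mean_t == 0.0
        assert row.cs == 2
        assert row.peak_voxel == (4, 4, 4)
        assert row.peak_mm == (8.0, 8.0, 8.0)
        assert row.da_pct == 80.0

    def test_all_voxels_above_threshold(self):
        centers = [(4, 4, 4)]
        amap = self._map(centers, [90.0], [(9, 1, 8, 0)])
        t_map = np.full((9, 9, 9), 50.0)
        row = m.cluster_summary(np.array(centers), amap.spec, amap, t_map,
                                alpha_vox=0.001, data_df=16)
        assert row.vox_star_pct == 100.0
        assert row.mean_t == 50.0

    def test_tie_broken_lexicographically(self):
        centers = [(4, 4, 5), (4, 4, 4)]
        amap = self._map(centers, [80.0, 80.0],
                         [(8, 2, 7, 1), (8, 2, 7, 1)])
        row = m.cluster_summary(np.array(centers), amap.spec, amap,
                                np.zeros((9, 9, 9)), 0.001, 16)
        assert row.peak_voxel == (4, 4, 4)

    def test_matches_union_count_oracle(self, rng):
        centers = [(4, 4, 4), (4, 5, 4), (5, 4, 4)]
        amap = self._map(centers, [75.0, 85.0, 65.0],
                         [(7, 3, 7, 1)] * 3)
        space = amap.center_mask
        t_map = rng.normal(size=(9, 9, 9)) * 6
        alpha, df = 0.01, 20
        row = m.cluster_summary(np.array(centers), amap.spec, amap, t_map,
                                alpha, df, space_mask=space)
        underlying = set()
        for c in centers:
            for v in m.searchlight_voxels(c, amap.spec, space):
                underlying.add(tuple(v))
        ts = np.array([t_map[v] for v in sorted(underlying)])
        crit = sps.t.ppf(1 - alpha / 2, df)
        assert row.vox_star_pct == pytest.approx(100 * (np.abs(ts) > crit).mean())
        assert row.mean_t == pytest.approx(ts.mean())


class TestThresholdRegimes:
    def test_presets_follow_reporting_rules(self):
        cfg = m.SignificanceConfig()
        r = threshold_regime("lesion", "uncorrected", cfg)
        assert (r.alpha_fwe, r.cluster_k, r.trend) == (0.05, 5, False)
        r = threshold_regime("lesion", "corrected", cfg)
        assert (r.alpha_fwe, r.cluster_k, r.trend) == (0.05, 1, False)
        r = threshold_regime("nawm", "uncorrected", cfg)
        assert (r.alpha_fwe, r.cluster_k, r.trend) == (0.05, 1, False)
        r = threshold_regime("nagm", "corrected", cfg)
        assert (r.alpha_fwe, r.cluster_k, r.trend) == (0.1, 1, True)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            m.SignificanceConfig(alpha_fwe=1.5)
        with pytest.raises(ValueError):
            m.SignificanceConfig(cluster_k=0)
        with pytest.raises(ValueError):
            m.SignificanceConfig(connectivity=10)


class TestLesionPresenceBound:
    @pytest.mark.parametrize("n_with,n_pat,expected", [(19, 41, 73), (13, 41, 66), (0, 7, 50), (41, 41, 100)])
    def test_bound_values(self, n_with, n_pat, expected):
        assert round(m.lesion_presence_bound(n_with, n_pat)) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            m.lesion_presence_bound(5, 4)
        with pytest.raises(ValueError):
            m.lesion_presence_bound(-1, 4)


class TestSummarizeSpace:
    def test_planted_effect_detected_and_summarized(self, pre_unc, spaces, effect_cfg):
        acc = m.map_searchlights(pre_unc, spaces.lesion_space, m.sphere_offsets(3),
                                 space="lesion")
        cfg = m.SignificanceConfig(cluster_k=1)
        summary = m.summarize_space(acc, pre_unc, cfg, space_mask=spaces.lesion_space)
        assert summary.p_map.shape == spaces.lesion_space.shape
        # significant centers must be above chance after the sign filter
        if summary.rows:
            assert all(r.da_pct > 50 for r in summary.rows)
            site = np.asarray(effect_cfg.lesion_sites[0].center)
            d = min(np.linalg.norm(np.asarray(r.peak_voxel) - site)
                    for r in summary.rows)
            assert d <= 3.0

    def test_table_columns(self, pre_unc, spaces):
        acc = m.map_searchlights(pre_unc, spaces.lesion_space, m.sphere_offsets(3),
                                 space="lesion")
        cfg = m.SignificanceConfig(cluster_k=1)
        rows = m.summarize_space(acc, pre_unc, cfg, space_mask=spaces.lesion_space).rows
        df = m.cluster_table(rows)
        assert list(df.columns) == ["space", "variant", "CS", "x", "y", "z",
                                    "DA(%)", "p", "Mn t", "Vox*(%)", "trend"]
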