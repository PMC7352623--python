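"""Habitat composition, tumor exclusion, and the statistical comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tumorhab.composition import (compare_between_groups,
                                  compare_habitat_parameter_means,
                                  compare_within_group, composition_table,
                                  exclude_large_tumors, percent_tumor_volume,
                                  rank_sum_test)


class TestPercentVolume:
    def test_simple_counts(self):
        m = np.repeat([1, 2, 3], [50, 30, 20])
        pct = percent_tumor_volume(m)
        assert pct == {1: 50.0, 2: 30.0, 3: 20.0}

    def test_single_habitat_is_100(self):
        assert percent_tumor_volume(np.ones((5, 5), int)) == {1: 100.0}

    def test_unassigned_excluded_from_denominator(self):
        m = np.array([0, 0, 1, 1, 2, 2])
        pct = percent_tumor_volume(m)
        assert pct[1] == pytest.approx(50.0)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            percent_tumor_volume(np.zeros((3, 3), int))

    def test_rim_phantom_percents_match_generator_targets(self):
        from tumorhab.synth import generate_habitat_geometry

        g = generate_habitat_geometry(shape=(32, 32, 10),
                                      fractions=(0.33, 0.33, 0.34), seed=1)
        pct = percent_tumor_volume(g.label_volume)
        for h, target in zip((1, 2, 3), (33.0, 33.0, 34.0)):
            assert abs(pct[h] - target) <= 5.0


def _records(spec):
    """spec: iterable of (tumor, day, group, volume)."""
    rows = []
    for tumor, day, group, vol in spec:
        rows.append({"tumor": tumor, "day": day, "group": group,
                     "habitat": "HV-HC", "percent": 50.0, "volume_mm3": vol})
    return composition_table(rows)


class TestExclusion:
    def test_strict_500_boundary(self):
        t = _records([("a", 0, "c", 501.0), ("b", 0, "c", 500.0)])
        out, excluded = exclude_large_tumors(t)
        assert excluded == ["a"]
        assert set(out["tumor"]) == {"b"}

    def test_empty_cohort(self):
        out, excluded = exclude_large_tumors(_records([]))
        assert out.empty and excluded == []

    def test_missing_baseline_flagged_retained(self):
        t = _records([("a", 4, "c", 300.0)])
        out, excluded = exclude_large_tumors(t)
        assert ("a", "no-baseline") in excluded
        assert set(out["tumor"]) == {"a"}

    def test_synthetic_cohort_bookkeeping(self, rng):
        spec = [(f"t{i}", 0, "c", v) for i, v in
                enumerate([300, 700, 450, 800, 200])]
        out, excluded = exclude_large_tumors(_records(spec))
        assert sorted(excluded) == ["t1", "t3"]


class TestRankSum:
    def test_identical_samples_p_one(self):
        assert rank_sum_test([5, 5, 5], [5, 5, 5]) == 1.0

    def test_fully_separated_exact_p(self):
        p = rank_sum_test([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert p == pytest.approx(2.0 / 252.0)

    def test_matches_exhaustive_enumeration_small_n(self):
        x = np.array([1.0, 4.0, 6.0])
        y = np.array([2.0, 3.0, 9.0])
        p = rank_sum_test(x, y)
        # enumerate all assignments of ranks to the first sample
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1
        obs = ranks[:3].sum()
        n = len(pooled)
        stats_all = [sum(c) for c in itertools.combinations(ranks, 3)]
        mu = np.mean(stats_all)
        p_exact = np.mean([abs(s - mu) >= abs(obs - mu) - 1e-9
                           for s in stats_all])
        assert p == pytest.approx(p_exact)


class TestGroupComparisons:
    def _table(self, groups, day=4, rng=None):
        rows = []
        for g, values in groups.items():
            for i, v in enumerate(values):
                rows.append({"tumor": f"{g}{i}", "day": day, "group": g,
                             "habitat": "LV-HC", "percent": v,
                             "volume_mm3": 300.0})
        return composition_table(rows)

    def test_within_group_requires_three_per_arm(self):
        rows = []
        for day, vals in ((0, [30, 31]), (4, [10, 11])):
            for i, v in enumerate(vals):
                rows.append({"tumor": f"t{i}", "day": day, "group": "tx",
                             "habitat": "LV-HC", "percent": v,
                             "volume_mm3": 300.0})
        with pytest.raises(ValueError):
            compare_within_group(composition_table(rows), "tx", "LV-HC", 4)

    def test_two_groups_route_to_rank_sum(self):
        t = self._table({"a": [30, 31, 33, 29], "b": [10, 12, 11, 9]})
        res = compare_between_groups(t, "LV-HC", 4)
        assert res["test"] == "rank-sum"
        assert res["omnibus_p"] < 0.05

    def test_three_identical_groups_anova_f_near_zero(self, rng):
        base = list(rng.normal(30, 1, 6))
        t = self._table({"a": base, "b": base, "c": base})
        res = compare_between_groups(t, "LV-HC", 4)
        assert res["test"] == "anova+tukey"
        assert res["omnibus_p"] > 0.99

    def test_separated_third_group_drives_significance(self, rng):
        t = self._table({"a": rng.normal(0, 1, 10),
                         "b": rng.normal(0, 1, 10),
                         "c": rng.normal(10, 1, 10)})
        res = compare_between_groups(t, "LV-HC", 4)
        assert res["omnibus_p"] < 1e-6
        assert res["pairwise"][("a", "b")] > 0.05
        assert res["pairwise"][("a", "c")] < 1e-4
        assert res["pairwise"][("b", "c")] < 1e-4


class TestParameterMeans:
    def test_identical_clusters_nonsignificant(self, rng):
        X = np.tile(rng.normal(size=(40, 2)), (2, 1))
        labels = np.repeat([0, 1], 40)
        res = compare_habitat_parameter_means(X, labels, ("f1", "f2"))
        assert all(v["omnibus_p"] > 0.99 for v in res.values())

    def test_generator_default_habitats_all_significant(self, small_geometry,
                                                        truth_maps):
        sel = small_geometry.tumor_mask
        X = np.column_stack([truth_maps[p][sel]
                             for p in ("ktrans", "ve", "kep", "adc")])
        labels = small_geometry.label_volume[sel]
        res = compare_habitat_parameter_means(X, labels,
                                              ("ktrans", "ve", "kep", "adc"))
        for feature, r in res.items():
            assert r["omnibus_p"] < 0.01
            assert all(p < 0.01 for p in r["pairwise"].values())

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_habitat_parameter_means(rng.normal(size=(10, 2)),
                                            np.zeros(10), ("a", "b"))


class TestCalibrationAndPower:
    def test_type_one_error_calibrated(self, rng):
        hits_rs = hits_anova = 0
        n_sim = 500
        from scipy import stats
        for _ in range(n_sim):
            a = rng.normal(30, 8, 10)
            b = rng.normal(30, 8, 10)
            c = rng.normal(30, 8, 10)
            hits_rs += rank_sum_test(a, b) < 0.05
            hits_anova += stats.f_oneway(a, b, c).pvalue < 0.05
        assert abs(hits_rs / n_sim - 0.05) <= 0.02
        assert abs(hits_anova / n_sim - 0.05) <= 0.02

    def test_power_for_20pp_shift(self, rng):
        detected = 0
        for _ in range(200):
            base = rng.normal(37, 8, 10)
            post = rng.normal(17, 8, 10)
            detected += rank_sum_test(base, post) < 0.05
        assert detected / 200 >= 0.80
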