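"""Pooled scaling, Ward clustering, gap selection, and habitat labelling."""

import itertools

import numpy as np
import pytest

from tumorhab.habitats import (HabitatClusterer, agglomerative_cluster,
                               gap_statistic, label_habitats_mri,
                               map_labels_to_volumes, pool_and_scale)
from tumorhab.qmri.maps import ParameterMapSet


def make_param_set(values, tumor="t0", timepoint=0, shape=None):
    """ParameterMapSet holding the given (n, 4) feature rows as a flat volume."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    shape = shape or (n, 1, 1)
    maps, validity = {}, {}
    for i, p in enumerate(("ktrans", "ve", "kep", "adc")):
        maps[p] = values[:, i].reshape(shape)
        validity[p] = np.ones(shape, dtype=bool)
    return ParameterMapSet(maps=maps, validity=validity,
                           provenance={"tumor": tumor, "timepoint": timepoint})


def random_rows(rng, n):
    kt = rng.uniform(0.01, 0.3, n)
    ve = rng.uniform(0.1, 0.9, n)
    return np.column_stack([kt, ve, kt / ve, rng.uniform(4e-4, 1.5e-3, n)])


class TestPooling:
    def test_row_count_pools_all_scans(self, rng):
        sets = [make_param_set(random_rows(rng, 100), tumor=t, timepoint=d)
                for t in ("a", "b") for d in (0, 4)]
        table = pool_and_scale(sets)
        assert table.n_rows == 400

    def test_scaled_columns_standardized(self, rng):
        table = pool_and_scale([make_param_set(random_rows(rng, 500))])
        X = table.X
        assert np.all(np.abs(X.mean(axis=0)) < 1e-8)
        assert np.all(np.abs(X.std(axis=0) - 1.0) < 1e-8)

    def test_single_voxel_rejected(self, rng):
        with pytest.raises(ValueError):
            pool_and_scale([make_param_set(random_rows(rng, 1))])

    def test_constant_column_rejected(self, rng):
        rows = random_rows(rng, 50)
        rows[:, 3] = 1e-3
        with pytest.raises(ValueError, match="constant"):
            pool_and_scale([make_param_set(rows)])


def ward_oracle_two_clusters(X):
    """Exhaustive minimum total-within-SSQ bipartition at tiny n."""
    n = X.shape[0]
    best, best_val = None, np.inf
    for size in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), size):
            a = np.zeros(n, dtype=bool)
            a[list(combo)] = True
            w = ((X[a] - X[a].mean(0)) ** 2).sum() + \
                ((X[~a] - X[~a].mean(0)) ** 2).sum()
            if w < best_val:
                best, best_val = a.copy(), w
    return best


class TestWard:
    def test_two_points_two_singletons(self):
        labels, _ = agglomerative_cluster(np.array([[0.0], [1.0]]), k=2)
        assert set(labels) == {1, 2}

    def test_recovers_tight_triads_and_matches_exhaustive_oracle(self, rng):
        a = rng.normal(0, 0.01, (3, 2))
        b = rng.normal(5, 0.01, (3, 2))
        X = np.vstack([a, b])
        labels, _ = agglomerative_cluster(X, k=2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        oracle = ward_oracle_two_clusters(X)
        assert np.array_equal(labels == labels[0], oracle == oracle[0])

    def test_merge_heights_non_decreasing(self, rng):
        X = rng.normal(size=(40, 4))
        _, Z = agglomerative_cluster(X, k=3)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            agglomerative_cluster(np.zeros((3, 2)), k=4)


class TestGap:
    def test_three_well_separated_gaussians_select_three(self, rng):
        centers = np.array([[0, 0, 0, 0], [10, 3, 0, 2], [3, 10, 8, 6]]) / np.sqrt(2)
        X = np.vstack([c + rng.standard_normal((167, 4)) for c in centers])
        Z = (X - X.mean(0)) / X.std(0)
        gap = gap_statistic(Z, n_refs=20, seed=1)
        assert gap.k_one_se == 3
        # direct recomputation of log within-dispersion at the selected k
        from tumorhab.habitats import agglomerative_cluster, _within_dispersion
        labels, _ = agglomerative_cluster(Z, 3)
        assert np.isclose(gap.log_w[1], np.log(_within_dispersion(Z, labels)))

    def test_single_gaussian_selects_range_minimum(self, rng):
        X = rng.standard_normal((300, 4)) * 0.1
        gap = gap_statistic(X, n_refs=20, seed=2)
        assert gap.k_one_se == 2

    def test_gap_curve_length_matches_k_range(self, rng):
        gap = gap_statistic(rng.standard_normal((60, 3)), k_range=(2, 6),
                            n_refs=5, seed=3)
        assert gap.gap.shape == (5,)

    def test_degenerate_identical_rows_rejected(self):
        with pytest.raises(ValueError):
            gap_statistic(np.ones((50, 3)))


class TestLabeling:
    # feature order: ktrans, ve, kep, adc
    def test_printed_centroid_worked_examples(self):
        bt474 = [[0.18, 0.27, 0.84, 6.9e-4],
                 [0.05, 0.18, 0.31, 6.2e-4],
                 [0.04, 0.78, 0.08, 1.2e-3]]
        assert label_habitats_mri(np.array(bt474), ("ktrans", "ve", "kep", "adc")) \
            == ["HV-HC", "LV-HC", "LV-LC"]

    def test_ve_precedence_when_adc_disagrees(self):
        # low ADC says HC, near-unity ve says LC: ve decides
        row = [[0.01, 0.99, 0.01, 5.7e-4]]
        assert label_habitats_mri(np.array(row), ("ktrans", "ve", "kep", "adc")) \
            == ["LV-LC"]

    def test_boundary_equality_labels_low(self):
        row = [[0.1, 0.3, 0.5, 1e-3]]
        assert label_habitats_mri(np.array(row), ("ktrans", "ve", "kep", "adc")) \
            == ["LV-LC"]

    @pytest.mark.parametrize("axis,col,delta,flip", [
        ("vascularity", 0, +0.02, "HV"),   # ktrans crosses 0.1
        ("vascularity", 2, +0.02, "HV"),   # kep crosses 0.5
    ])
    def test_threshold_crossing_flips_exactly_one_axis(self, axis, col, delta, flip):
        base = np.array([[0.09, 0.5, 0.49, 1.1e-3]])  # LV-LC, agreeing LC
        lab0 = label_habitats_mri(base, ("ktrans", "ve", "kep", "adc"))[0]
        pert = base.copy()
        pert[0, col] += delta
        lab1 = label_habitats_mri(pert, ("ktrans", "ve", "kep", "adc"))[0]
        assert lab0 == "LV-LC"
        assert lab1 == f"{flip}-LC"


class TestMapping:
    def test_round_trip_preserves_coordinates(self, rng):
        sets = []
        for t in ("a", "b"):
            rows = random_rows(rng, 60)
            sets.append(make_param_set(rows, tumor=t, shape=(5, 4, 3)))
        table = pool_and_scale(sets)
        labels = rng.integers(0, 3, table.n_rows)
        vols = map_labels_to_volumes(table, labels)
        assert set(vols) == {("a", 0), ("b", 0)}
        back = np.concatenate([vols[("a", 0)].ravel(), vols[("b", 0)].ravel()])
        np.testing.assert_array_equal(back - 1, labels)

    def test_unassigned_count_matches_removals(self, rng):
        rows = random_rows(rng, 60)
        ps = make_param_set(rows, shape=(5, 4, 3))
        ps.validity["adc"].ravel()[:10] = False
        table = pool_and_scale([ps])
        assert table.n_rows == 50
        vols = map_labels_to_volumes(table, np.zeros(50, dtype=int))
        assert (vols[("t0", 0)] == 0).sum() == 10

    def test_label_length_mismatch_rejected(self, rng):
        table = pool_and_scale([make_param_set(random_rows(rng, 30))])
        with pytest.raises(ValueError):
            map_labels_to_volumes(table, np.zeros(10, dtype=int))


class TestClusterer:
    def test_permutation_stability_up_to_renaming(self, rng):
        centers = np.array([[0, 0], [6, 0], [0, 6]])
        X = np.vstack([c + rng.normal(0, 0.3, (50, 2)) for c in centers])
        cl = HabitatClusterer(k=3).fit(X)
        perm = rng.permutation(X.shape[0])
        cl2 = HabitatClusterer(k=3).fit(X[perm])
        # map labels via centroids
        from scipy.optimize import linear_sum_assignment
        conf = np.zeros((3, 3))
        for a, b in zip(cl.labels_[perm], cl2.labels_):
            conf[a, b] += 1
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() == X.shape[0]

    def test_predict_assigns_nearest_centroid(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(5, 0.1, (30, 2))])
        cl = HabitatClusterer(k=2).fit(X)
        pred = cl.predict(np.array([[0.0, 0.0], [5.0, 5.0]]))
        assert pred[0] != pred[1]

    def test_sklearn_get_set_params_round_trip(self):
        cl = HabitatClusterer(k=4, n_refs=7)
        params = cl.get_params()
        cl2 = HabitatClusterer().set_params(**params)
        assert cl2.k == 4 and cl2.n_refs == 7

    def test_subsample_cap_assigns_remainder(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (300, 2)), rng.normal(8, 0.2, (300, 2))])
        cl = HabitatClusterer(k=2, subsample_cap=100, random_state=0).fit(X)
        assert cl.labels_.shape == (600,)
        assert len(set(cl.labels_[:300])) == 1
        assert len(set(cl.labels_[300:])) == 1
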