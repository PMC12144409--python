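"""Normalization, clustering and ROC-scan behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from hemaflux.stratify import (
    FeatureMatrix,
    WithinIndividualScaler,
    auc_threshold_sweep,
    hclust_complete,
    kmeans_groups,
    normalize_chimerism_matrix,
    normalize_influx_matrix,
    ratio_feature_scan,
)


def _influx_records(data):
    """data: dict individual -> dict quantity -> dict week -> value."""
    rows = []
    for iid, quantities in data.items():
        for q, weeks in quantities.items():
            for w, v in weeks.items():
                rows.append((iid, float(w), q, float(v)))
    return pd.DataFrame(rows, columns=["individual_id", "week", "quantity", "value"])


def _chim_obs(values):
    """values: dict individual -> dict (lineage, week) -> value."""
    rows = []
    for iid, entries in values.items():
        for (lin, w), v in entries.items():
            rows.append((iid, "young", "single_LT", lin, float(w), "chimerism", float(v), False, 0.001))
    return pd.DataFrame(rows, columns=["individual_id", "age_group", "scenario", "lineage",
                                       "week", "kind", "value", "censored", "limit"])


class TestNormalization:
    def test_max_scaling_brings_quantities_to_unit_range(self):
        recs = _influx_records({
            "a": {"q1": {1: 2.0, 2: 4.0}, "q2": {1: 10.0, 2: 30.0}},
            "b": {"q1": {1: 1.0, 2: 3.0}, "q2": {1: 20.0, 2: 40.0}},
        })
        wide = recs.pivot_table(index="individual_id", columns=["quantity", "week"], values="value")
        for q in ("q1", "q2"):
            scaled = wide[q] / wide[q].to_numpy().max()
            assert scaled.to_numpy().max() == pytest.approx(1.0)

    def test_rows_are_standardized(self):
        recs = _influx_records({
            "a": {"q1": {1: 2.0, 2: 4.0}, "q2": {1: 10.0, 2: 30.0}},
            "b": {"q1": {1: 1.0, 2: 3.0}, "q2": {1: 20.0, 2: 40.0}},
        })
        fm = normalize_influx_matrix(recs)
        assert np.allclose(fm.values.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(fm.values.var(axis=1), 1.0, atol=1e-9)

    def test_constant_row_maps_to_zeros(self):
        X = np.array([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]])
        out = WithinIndividualScaler().fit_transform(X)
        assert np.all(out[0] == 0.0)

    def test_all_zero_quantity_dropped_with_warning(self):
        recs = _influx_records({
            "a": {"q1": {1: 1.0, 2: 2.0}, "dead": {1: 0.0, 2: 0.0}},
            "b": {"q1": {1: 2.0, 2: 1.0}, "dead": {1: 0.0, 2: 0.0}},
        })
        fm = normalize_influx_matrix(recs)
        assert "dead" in fm.excluded
        assert all(q != "dead" for q, _ in fm.col_labels)

    def test_chimerism_scale_invariance_of_rows(self):
        base = {("N", 2): 1.0, ("E", 2): 2.0, ("P", 2): 4.0, ("B", 2): 8.0}
        obs = _chim_obs({"a": base, "b": {k: 10 * v for k, v in base.items()}})
        fm = normalize_chimerism_matrix(obs, weeks=[2.0])
        np.testing.assert_allclose(fm.values[0], fm.values[1], atol=1e-12)

    def test_incomplete_individuals_excluded_and_reported(self):
        full = {(l, w): 1.0 * (i + 1) for i, (l, w) in enumerate([("N", 2), ("E", 2), ("P", 2), ("B", 2)])}
        partial = dict(list(full.items())[:3])
        obs = _chim_obs({"a": full, "b": partial})
        fm = normalize_chimerism_matrix(obs, weeks=[2.0])
        assert fm.row_labels == ["a"]
        assert fm.excluded == ["b"]


class TestClustering:
    def _blobs(self, k, n_per, sep, seed=0, d=4):
        rng = np.random.default_rng(seed)
        X = np.concatenate([rng.normal(sep * j, 1.0, size=(n_per, d)) for j in range(k)])
        labels = np.repeat(np.arange(k), n_per)
        return X, labels

    def test_duplicated_rows_merge_first_at_height_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]])
        _, Z = hclust_complete(FeatureMatrix(X, ["a", "b", "c"], [("q", 1.0), ("q", 2.0)]))
        assert Z[0, 2] == pytest.approx(0.0)
        assert set(Z[0, :2]) == {0.0, 1.0}

    def test_separated_blobs_recovered(self):
        X, truth = self._blobs(2, 10, sep=10.0)
        fm = FeatureMatrix(X, [str(i) for i in range(len(X))], [("q", float(j)) for j in range(X.shape[1])])
        labels, _ = hclust_complete(fm, k=2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_row_is_one_cluster(self):
        fm = FeatureMatrix(np.array([[1.0, 2.0]]), ["a"], [("q", 1.0), ("q", 2.0)])
        labels, Z = hclust_complete(fm, k=1)
        assert list(labels) == [1]

    def test_kmeans_recovers_three_blobs(self):
        X, truth = self._blobs(3, 8, sep=12.0, seed=3)
        fm = FeatureMatrix(X, [str(i) for i in range(len(X))], [("q", float(j)) for j in range(X.shape[1])])
        labels = kmeans_groups(fm, k=3, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_kmeans_single_cluster_and_determinism(self):
        X, _ = self._blobs(2, 5, sep=3.0, seed=1)
        fm = FeatureMatrix(X, [str(i) for i in range(len(X))], [("q", float(j)) for j in range(X.shape[1])])
        assert len(set(kmeans_groups(fm, k=1, seed=0))) == 1
        a = kmeans_groups(fm, k=2, seed=7)
        b = kmeans_groups(fm, k=2, seed=7)
        assert np.array_equal(a, b)

    def test_row_permutation_consistency(self):
        X, truth = self._blobs(2, 6, sep=8.0, seed=5)
        fm = FeatureMatrix(X, [str(i) for i in range(len(X))], [("q", float(j)) for j in range(X.shape[1])])
        perm = np.random.default_rng(0).permutation(len(X))
        fmp = FeatureMatrix(X[perm], [str(i) for i in perm], fm.col_labels)
        la, _ = hclust_complete(fm, k=2)
        lb, _ = hclust_complete(fmp, k=2)
        assert adjusted_rand_score(la[perm], lb) == 1.0


class TestAucSweep:
    def test_perfect_separation_gives_auc_one(self):
        r = auc_threshold_sweep([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert r.auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        r = auc_threshold_sweep([5.0] * 6, [True, False] * 3)
        assert r.auc == pytest.approx(0.5)

    def test_curve_anchored_and_monotone(self):
        rng = np.random.default_rng(1)
        r = auc_threshold_sweep(rng.normal(size=30), rng.random(30) > 0.4)
        assert tuple(r.curve[0]) == (0.0, 0.0)
        assert tuple(r.curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.curve[:, 0]) >= 0)
        assert np.all(np.diff(r.curve[:, 1]) >= 0)

    def test_matches_mann_whitney_on_random_instances(self):
        """Threshold-sweep AUC == U / (n1 n2), exactly, on 200 random instances."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 200:
            n = int(rng.integers(4, 21))
            y = rng.random(n) > rng.uniform(0.2, 0.8)
            if y.all() or not y.any():
                continue
            scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties on purpose
            r = auc_threshold_sweep(scores, y)
            u = mannwhitneyu(scores[y], scores[~y]).statistic / (y.sum() * (~y).sum())
            assert r.auc == pytest.approx(float(u), abs=1e-12)
            assert r.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)
            checked += 1

    def test_score_negation_complements_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=25)  # continuous: tie-free
        y = rng.random(25) > 0.5
        a = auc_threshold_sweep(scores, y).auc
        b = auc_threshold_sweep(-scores, y).auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_threshold_sweep([1.0, 2.0], [True, True])


class TestRatioFeatureScan:
    def _cohort_obs(self, rng, n_stable=10, n_dropped=10, ratio_boost=10.0):
        """Week-8 P:E ratio elevated for stable mice; other features noise."""
        values = {}
        classes = {}
        weeks = (2.0, 3.0, 4.0, 8.0, 12.0, 16.0, 24.0)
        for i in range(n_stable + n_dropped):
            iid = f"m{i:02d}"
            stable = i < n_stable
            classes[iid] = "stable" if stable else "dropped"
            entries = {}
            for lin in "NEPB":
                for w in weeks:
                    entries[(lin, w)] = float(np.exp(rng.normal(1.0, 0.6)))
            if stable and ratio_boost != 1.0:
                # split the boost between a platelet rise and an erythrocyte
                # drop so the P:E ratio is the sharpest signal
                entries[("P", 8.0)] *= np.sqrt(ratio_boost)
                entries[("E", 8.0)] /= np.sqrt(ratio_boost)
            values[iid] = entries
        return _chim_obs(values), classes

    def test_constructed_separation_ranks_p_to_e_week8_first(self):
        rng = np.random.default_rng(5)
        obs, classes = self._cohort_obs(rng)
        results = ratio_feature_scan(obs, classes)
        assert results[0].feature == ("P", "E", 8.0)
        assert results[0].auc > 0.95

    def test_feature_count_is_ordered_pairs_times_weeks(self):
        rng = np.random.default_rng(6)
        obs, classes = self._cohort_obs(rng)
        results = ratio_feature_scan(obs, classes)
        assert len(results) == 4 * 3 * 7  # 12 ordered pairs x 7 weeks

    def test_permuted_labels_give_chance_level_aucs(self):
        rng = np.random.default_rng(7)
        obs, classes = self._cohort_obs(rng, ratio_boost=1.0)
        ids = list(classes)
        best = []
        for _ in range(20):
            perm = rng.permutation(len(ids))
            permuted = {ids[i]: classes[ids[j]] for i, j in enumerate(perm)}
            results = ratio_feature_scan(obs, permuted, weeks=[8.0])
            best.append(max(r.auc for r in results))
        # the max over 12 chance-level features sits well below a real signal
        assert 0.5 < np.mean(best) < 0.85

    def test_scan_is_reproducible(self):
        rng = np.random.default_rng(8)
        obs, classes = self._cohort_obs(rng)
        a = ratio_feature_scan(obs, classes)
        b = ratio_feature_scan(obs, classes)
        assert [(r.feature, r.auc) for r in a] == [(r.feature, r.auc) for r in b]
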