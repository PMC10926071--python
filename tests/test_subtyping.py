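import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netmarker.subtyping import (
    ClusterAssignment,
    SubtypeFeatures,
    build_features,
    competitive_fit,
    evaluate,
    hierarchical_fit,
    kmeans_samples,
    map_clusters_to_labels,
    repeat_experiment,
    som_fit,
)
from tests.conftest import make_expression


def features_from(x, labels):
    x = np.asarray(x, dtype=float)
    idx = [f"s{i}" for i in range(len(x))]
    return SubtypeFeatures(
        X=pd.DataFrame(x, index=idx), labels=pd.Series(list(labels), index=idx)
    )


def three_blob_features(rng, spread=0.1):
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    labels = ["incipient"] * 7 + ["moderate"] * 8 + ["severe"] * 7
    x = np.vstack(
        [centers[i] + rng.normal(0, spread, (n, 2)) for i, n in enumerate((7, 8, 7))]
    )
    return features_from(x, labels)


class TestEvaluate:
    def test_worked_confusion_example(self):
        # class "a": TP=5 FP=2 FN=3 TN=12 in a 22-sample cohort
        truth = pd.Series(["a"] * 5 + ["b"] * 2 + ["a"] * 3 + ["b"] * 12)
        pred = pd.Series(["a"] * 5 + ["a"] * 2 + ["b"] * 3 + ["b"] * 12)
        rep = evaluate(pred, truth)
        row = rep.per_class.loc["a"]
        assert (row.TP, row.FP, row.FN, row.TN) == (5, 2, 3, 12)
        assert row.precision == pytest.approx(5 / 7)
        assert row.recall == pytest.approx(5 / 8)
        assert row.f1 == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(17 / 22)

    def test_perfect_prediction_is_all_ones(self):
        truth = pd.Series(["incipient", "moderate", "severe"] * 4)
        rep = evaluate(truth.copy(), truth)
        assert (rep.per_class[["precision", "recall", "f1"]] == 1.0).all().all()
        assert rep.accuracy == 1.0

    def test_empty_predicted_class_flagged(self):
        truth = pd.Series(["a", "a", "b", "b"])
        pred = pd.Series(["a", "a", "a", "a"])
        rep = evaluate(pred, truth)
        assert rep.per_class.loc["b", "undefined_precision"]
        assert rep.per_class.loc["b", "precision"] == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
                    min_size=2, max_size=40))
    def test_f1_harmonic_identity_and_count_sums(self, pairs):
        truth = pd.Series([t for t, _ in pairs])
        pred = pd.Series([p for _, p in pairs])
        rep = evaluate(pred, truth)
        n = len(pairs)
        for _, row in rep.per_class.iterrows():
            assert row.TP + row.FP + row.FN + row.TN == n
            if row.precision + row.recall > 0:
                expected = 2 * row.precision * row.recall / (row.precision + row.recall)
                assert row.f1 == pytest.approx(expected)

    def test_random_predictions_hit_frequency_baseline(self):
        rng = np.random.default_rng(0)
        truth = pd.Series(["a"] * 60 + ["b"] * 40)
        accs = []
        for _ in range(300):
            pred = pd.Series(rng.permutation(truth.to_numpy()))
            accs.append(evaluate(pred, truth).accuracy)
        # E[acc] for a permuted assignment = sum of squared class frequencies
        assert np.mean(accs) == pytest.approx(0.6**2 + 0.4**2, abs=0.02)


class TestClusterLabelMapping:
    def _assign(self, clusters):
        idx = [f"s{i}" for i in range(len(clusters))]
        return ClusterAssignment(
            assignments=pd.Series(clusters, index=idx), algorithm="test"
        )

    def test_plurality_vote(self):
        a = self._assign([0, 0, 0])
        truth = pd.Series(["incipient", "incipient", "moderate"],
                          index=a.assignments.index)
        pred = map_clusters_to_labels(a, truth)
        assert (pred == "incipient").all()

    def test_five_clusters_collapse_to_three_classes(self):
        a = self._assign([0, 0, 1, 1, 2, 2, 3, 3, 4, 4])
        truth = pd.Series(
            ["incipient"] * 4 + ["moderate"] * 4 + ["severe"] * 2,
            index=a.assignments.index,
        )
        pred = map_clusters_to_labels(a, truth)
        assert set(pred) <= set(truth)
        assert pred.nunique() <= truth.nunique()

    def test_exact_tie_goes_to_rarer_class(self):
        a = self._assign([0, 0, 1, 1, 1])
        truth = pd.Series(["incipient", "moderate", "moderate", "moderate", "moderate"],
                          index=a.assignments.index)
        pred = map_clusters_to_labels(a, truth)
        assert pred.iloc[0] == "incipient"  # rarer overall


class TestClusteringAlgorithms:
    def test_som_two_clouds_perfect_split(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.2, (8, 3)), rng.normal(8, 0.2, (8, 3))])
        f = features_from(x, ["incipient"] * 8 + ["severe"] * 8)
        assign = som_fit(f, rows=1, cols=2, seed=1)
        units = assign.assignments.to_numpy()
        assert len(set(units[:8])) == 1 and len(set(units[8:])) == 1
        assert units[0] != units[-1]
        # oracle: each sample maps with its own cloud
        pred = map_clusters_to_labels(assign, f.labels)
        assert evaluate(pred, f.labels).accuracy == 1.0

    def test_som_identical_samples_single_unit(self):
        f = features_from(np.ones((6, 2)), ["incipient"] * 6)
        assign = som_fit(f, rows=1, cols=2, seed=0)
        assert assign.assignments.nunique() == 1

    def test_som_2x3_occupies_at_most_six_units(self):
        rng = np.random.default_rng(5)
        f = features_from(rng.normal(size=(22, 5)),
                          ["incipient"] * 7 + ["moderate"] * 8 + ["severe"] * 7)
        assign = som_fit(f, rows=2, cols=3, seed=2)
        assert assign.assignments.nunique() <= 6

    def test_som_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        f = features_from(rng.normal(size=(10, 4)), ["incipient"] * 10)
        a1 = som_fit(f, 2, 3, seed=9).assignments
        a2 = som_fit(f, 2, 3, seed=9).assignments
        pd.testing.assert_series_equal(a1, a2)

    @pytest.mark.parametrize("algorithm", ["kmeans", "som", "competitive", "hierarchical"])
    def test_three_separated_blobs_recovered_by_all_algorithms(self, algorithm):
        f = three_blob_features(np.random.default_rng(3))
        if algorithm == "kmeans":
            assign = kmeans_samples(f, 3, seed=0)
        elif algorithm == "som":
            assign = som_fit(f, rows=1, cols=3, seed=0)
        elif algorithm == "competitive":
            assign = competitive_fit(f, 3, seed=0)
        else:
            assign = hierarchical_fit(f, 3)
        pred = map_clusters_to_labels(assign, f.labels)
        assert evaluate(pred, f.labels).accuracy == 1.0

    def test_hierarchical_two_pairs(self):
        f = features_from([[0, 0], [0.1, 0], [5, 5], [5.1, 5]], ["incipient"] * 4)
        assign = hierarchical_fit(f, 2)
        a = assign.assignments
        assert a.iloc[0] == a.iloc[1] and a.iloc[2] == a.iloc[3]
        assert a.iloc[0] != a.iloc[2]

    def test_k_above_sample_count_rejected(self):
        f = features_from(np.eye(3), ["incipient"] * 3)
        with pytest.raises(ValueError):
            kmeans_samples(f, 5, seed=0)


class TestRepeatExperiment:
    def test_deterministic_algorithm_has_zero_sd(self):
        f = three_blob_features(np.random.default_rng(4))
        out = repeat_experiment(f, "hierarchical", {"k": 3}, n_runs=10, base_seed=0)
        assert out["accuracy_sd"] == 0.0

    def test_separable_fixture_mean_one_sd_zero(self):
        f = three_blob_features(np.random.default_rng(5))
        out = repeat_experiment(f, "som", {"rows": 2, "cols": 3}, n_runs=10, base_seed=3)
        assert out["accuracy_mean"] == 1.0
        assert out["accuracy_sd"] == 0.0

    def test_per_run_values_recorded(self):
        f = three_blob_features(np.random.default_rng(6), spread=3.0)
        out = repeat_experiment(f, "kmeans", {"k": 3}, n_runs=5, base_seed=1)
        assert len(out["per_run_accuracy"]) == 5


class TestBuildFeatures:
    def make_expr(self):
        rng = np.random.default_rng(0)
        return make_expression(
            rng.uniform(1, 100, size=(4, 6)),
            gene_ids=["r1", "r2", "r3", "other"],
            groups=["healthy", "healthy", "incipient", "incipient",
                    "moderate", "severe"],
        )

    def test_healthy_excluded_and_columns_standardized(self):
        expr = self.make_expr()
        f = build_features(expr, ["r1", "r2", "r3"])
        assert len(f.X) == 4
        assert "healthy" not in set(f.labels)
        np.testing.assert_allclose(f.X.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(f.X.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_missing_representative_gene_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            build_features(self.make_expr(), ["r1", "nope"])

    def test_empty_representative_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_features(self.make_expr(), [])

    def test_zero_variance_feature_is_an_error(self):
        expr = self.make_expr()
        expr.values.loc["r1"] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            build_features(expr, ["r1", "r2"])
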