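"""Normalization, labeling, classification/regression, importance, overlaps."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from tfocc.models import (FeatureTable, VennSummary, cross_predict,
                          feature_importance, label_strong_weak, normalize,
                          recursive_feature_elimination, train_classifier,
                          train_regressor, venn_overlap_summary)
from tfocc.pwm import SiteList


def make_table(features: dict, target) -> FeatureTable:
    frame = pd.DataFrame(features)
    frame["target"] = target
    frame.index = [f"s{i}" for i in range(len(frame))]
    return FeatureTable(frame)


@pytest.fixture
def planted_table(rng):
    """Target is a monotone function of f1 plus small noise."""
    n = 500
    f1 = rng.normal(size=n)
    table = make_table(
        {"f1": f1, "n1": rng.normal(size=n), "n2": rng.normal(size=n)},
        3 * f1 + 0.3 * rng.normal(size=n) + 10)
    return normalize(table)


class TestNormalize:
    def test_hand_computed_column(self):
        table = make_table({"x": [1.0, 2.0, 3.0]}, [0, 0, 1])
        normalized = normalize(table)
        assert np.allclose(normalized.features["x"], [-1, 0, 1])
        assert normalized.means["x"] == 2.0 and normalized.stds["x"] == 1.0

    def test_idempotent(self, planted_table):
        again = normalize(planted_table)
        assert np.allclose(again.features, planted_table.features)

    def test_zero_variance_dropped_with_warning(self):
        table = make_table({"x": [1.0, 2, 3, 4], "const": [5.0] * 4},
                           [0, 0, 1, 1])
        with pytest.warns(UserWarning, match="const"):
            normalized = normalize(table)
        assert normalized.feature_names == ["x"]


class TestLabeling:
    def test_counts_at_fraction(self):
        table = make_table({"x": np.arange(10.0)}, np.arange(10.0))
        labels, subset = label_strong_weak(table, 0.2)
        assert (labels == 1).sum() == 2 and (labels == 0).sum() == 2
        assert len(subset) == 4

    def test_sort_oracle(self):
        rng = np.random.default_rng(5)
        targets = rng.permutation(100).astype(float)
        table = make_table({"x": np.zeros(100) + rng.normal(size=100)},
                           targets)
        labels, subset = label_strong_weak(table, 0.2)
        strong = set(subset.frame.index[labels == 1])
        weak = set(subset.frame.index[labels == 0])
        order = np.argsort(targets)
        assert strong == {f"s{i}" for i in order[-20:]}
        assert weak == {f"s{i}" for i in order[:20]}

    def test_too_few_sites_raises(self):
        table = make_table({"x": [1.0, 2.0]}, [0.0, 1.0])
        with pytest.raises(ValueError):
            label_strong_weak(table, 0.2)


class TestClassifier:
    def test_separable_signal_perfect_holdout(self, planted_table):
        labels, subset = label_strong_weak(planted_table, 0.2)
        report = train_classifier(subset, labels, seed=3)
        assert report.holdout_metric == pytest.approx(1.0)
        assert report.cv_metric >= 0.95
        assert report.hyperparameters["C"] in (0.25, 0.5, 1, 2, 4, 8, 16, 32)

    @pytest.mark.parametrize("method", ["svm-poly", "rf"])
    def test_other_methods_learn_planted_signal(self, planted_table,
                                                method):
        labels, subset = label_strong_weak(planted_table, 0.2)
        report = train_classifier(subset, labels, method=method, seed=3)
        assert report.cv_metric >= 0.95

    def test_permuted_labels_chance_level(self, planted_table, rng):
        labels, subset = label_strong_weak(planted_table, 0.2)
        permuted = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
        report = train_classifier(subset, permuted, holdout=0.0, seed=7)
        assert report.cv_metric == pytest.approx(0.5, abs=0.08)

    def test_single_class_rejected(self, planted_table):
        labels, subset = label_strong_weak(planted_table, 0.2)
        with pytest.raises(ValueError):
            train_classifier(subset, labels * 0, seed=0)


class TestRegressor:
    def test_exact_linear_function_near_perfect(self, rng):
        n = 300
        x = rng.normal(size=(n, 2))
        table = make_table({"a": x[:, 0], "b": x[:, 1]},
                           2 * x[:, 0] - x[:, 1] + 5)
        report = train_regressor(normalize(table), seed=2)
        assert report.cv_metric >= 0.97

    def test_cv_pcc_matches_closed_form(self, rng):
        """With target = w.x + noise, the population PCC between target
        and the best prediction is sqrt(SNR / (1 + SNR))."""
        n, snr = 1000, 4.0
        x = rng.normal(size=n)
        noise_sd = 1.0 / np.sqrt(snr)
        table = make_table({"x": x}, x + noise_sd * rng.normal(size=n))
        report = train_regressor(normalize(table), seed=4)
        expected = np.sqrt(snr / (1 + snr))
        assert report.cv_metric == pytest.approx(expected, abs=0.05)

    def test_zero_target_variance_rejected(self):
        table = make_table({"x": [1.0, 2, 3, 4]}, [1.0] * 4)
        with pytest.raises(ValueError):
            train_regressor(table)


class TestCrossPredict:
    def test_training_table_reproduces_resubstitution(self, planted_table):
        report = train_regressor(planted_table, seed=1)
        assert cross_predict(report, planted_table) == pytest.approx(
            report.resubstitution_metric)

    def test_missing_feature_listed(self, planted_table):
        report = train_regressor(planted_table, seed=1)
        other = make_table({"f1": [0.1, 0.2, 0.3]}, [1.0, 2, 3])
        with pytest.raises(ValueError, match="n1"):
            cross_predict(report, other)

    def test_shared_vs_dataset_specific_rule(self, rng):
        """Transfer holds when two datasets share the occupancy function
        and degrades when the second uses different weights."""
        def dataset(weights, seed):
            gen = np.random.default_rng(seed)
            x = gen.normal(size=(600, 3))
            y = x @ weights + 0.3 * gen.normal(size=600) + 8
            return make_table({"f1": x[:, 0], "f2": x[:, 1],
                               "f3": x[:, 2]}, y)

        w = np.array([2.0, 1.0, 0.0])
        train = normalize(dataset(w, 1))
        report = train_regressor(train, seed=1)
        same_rule = cross_predict(report, dataset(w, 2))
        other_rule = cross_predict(report,
                                   dataset(np.array([0.0, 0.5, 2.0]), 2))
        assert same_rule == pytest.approx(report.cv_metric, abs=0.05)
        assert other_rule < same_rule - 0.2


class TestImportance:
    def test_planted_weights_ordering(self, rng):
        n = 400
        x = rng.normal(size=(n, 3))
        table = normalize(make_table(
            {"f1": x[:, 0], "f2": x[:, 1], "f3": x[:, 2]},
            3 * x[:, 0] + 1 * x[:, 1] + 0.2 * rng.normal(size=n) + 10))
        report = train_regressor(table, seed=0)
        imp = feature_importance(report, table, seed=0)
        assert imp["f1"] > imp["f2"] > imp["f3"]
        assert imp["f3"] == pytest.approx(0.0, abs=0.05)
        assert imp.sum() == pytest.approx(1.0)

    def test_spearman_recovery_over_replicates(self):
        """Recovered importances track planted |weights| across seeds."""
        weights = np.array([3.0, 1.0, 0.5, 0.0])
        rhos = []
        for seed in range(10):
            gen = np.random.default_rng(100 + seed)
            x = gen.normal(size=(300, 4))
            table = normalize(make_table(
                {f"f{j}": x[:, j] for j in range(4)},
                x @ weights + 0.3 * gen.normal(size=300) + 10))
            report = train_regressor(table, seed=seed)
            imp = feature_importance(report, table, n_permutations=10,
                                     seed=seed)
            rhos.append(spearmanr(np.abs(weights), imp.to_numpy())[0])
        assert np.mean(rhos) >= 0.8


class TestRFE:
    def test_informative_feature_eliminated_last(self, rng):
        n = 300
        f1 = rng.normal(size=n)
        table = normalize(make_table(
            {"f1": f1, **{f"noise{j}": rng.normal(size=n)
                          for j in range(4)}},
            3 * f1 + 0.3 * rng.normal(size=n) + 10))
        labels, subset = label_strong_weak(table, 0.2)
        order, curve = recursive_feature_elimination(subset, labels, seed=2)
        assert order[-1] == "f1"
        assert len(curve) == 5 and curve["n_features"].tolist() == \
            [5, 4, 3, 2, 1]

    def test_full_set_curve_matches_classifier_cv(self, planted_table):
        labels, subset = label_strong_weak(planted_table, 0.2)
        order, curve = recursive_feature_elimination(subset, labels, c=1.0,
                                                     seed=5)
        report = train_classifier(subset, labels, holdout=0.0,
                                  c_grid=[1.0], seed=5)
        assert curve["cv_auroc"].iloc[0] == pytest.approx(report.cv_metric)


class TestVenn:
    def test_identical_lists_fully_common(self):
        sites = SiteList.from_records(
            [("chr1", 1000 * i, "+", 0.0, f"s{i}") for i in range(1, 6)])
        other = SiteList(sites.frame.assign(id=[f"o{i}" for i in range(5)]))
        summary = venn_overlap_summary({"a": sites, "b": other})
        assert summary.percent_common == 100.0

    def test_printed_count_arithmetic(self):
        assert VennSummary.from_counts(30_073, 161_438).percent_common \
            == 18.6
        assert VennSummary.from_counts(1_680, 189_459).percent_common == 0.9

    def test_three_list_partition_counts(self):
        a = SiteList.from_records(
            [("chr1", 100, "+", 0.0, "a1"), ("chr1", 5000, "+", 0.0, "a2"),
             ("chr1", 9000, "+", 0.0, "a3")])
        b = SiteList.from_records(
            [("chr1", 150, "+", 0.0, "b1"), ("chr1", 5050, "+", 0.0, "b2")])
        c = SiteList.from_records(
            [("chr1", 120, "+", 0.0, "c1"), ("chr2", 70, "+", 0.0, "c2")])
        summary = venn_overlap_summary({"a": a, "b": b, "c": c},
                                       match_distance=100)
        assert summary.region_counts[frozenset("abc")] == 1   # ~100-150
        assert summary.region_counts[frozenset("ab")] == 1    # ~5000
        assert summary.region_counts[frozenset("a")] == 1     # 9000
        assert summary.region_counts[frozenset("c")] == 1     # chr2
        assert summary.union_total == 4
        assert summary.percent_common == 25.0

    def test_requires_two_or_three_lists(self):
        sites = SiteList.from_records([("chr1", 1, "+", 0.0, "x")])
        with pytest.raises(ValueError):
            venn_overlap_summary({"a": sites})
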