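"""Cross-validated multi-class identification, subsets and importances."""

import numpy as np
import pandas as pd
import pytest

from nanogapid.classify import (
    STANDARD_SUBSETS,
    ClassifierSpec,
    cross_validate,
    feature_importance,
    feature_subset_experiment,
    pairwise_discrimination,
)
from nanogapid.features import FEATURE_NAMES


def test_separable_classes_fill_the_diagonal(separable_features):
    cm, report = cross_validate(separable_features, k=5)
    assert np.all(cm.diagonal() >= 0.99)
    assert report.macro_f >= 0.99
    np.testing.assert_allclose(cm.ratios.sum(axis=1), 1.0, atol=1e-9)


def test_ten_fold_protocol_runs_ten_rounds(four_class_features):
    cm, report = cross_validate(four_class_features, k=10)
    assert report.n_folds == 10
    assert len(report.fold_macro_f) == 10
    assert set(report.per_class_f) == {"ADP", "AMP", "ATP", "cAMP"}
    assert 0.0 <= report.macro_f <= 1.0


def test_confusion_rows_normalized_and_labeled(four_class_features):
    cm, _ = cross_validate(four_class_features, k=5)
    np.testing.assert_allclose(cm.ratios.sum(axis=1), 1.0, atol=1e-9)
    assert cm.labels == sorted(cm.labels)
    assert cm.to_frame().shape == (4, 4)


def test_label_permutation_sits_at_chance():
    from nanogapid.synthetic import DEFAULT_PROFILES, generate_labeled_feature_dataset

    data = generate_labeled_feature_dataset(DEFAULT_PROFILES, 400, seed=23)
    rng = np.random.default_rng(17)
    data["label"] = rng.permutation(data["label"].to_numpy())
    cm, report = cross_validate(data, k=5)
    assert np.all(np.abs(cm.diagonal() - 0.25) < 0.08)
    assert abs(report.macro_f - 0.25) < 0.08


def test_determinism_under_seed(four_class_features):
    cm1, r1 = cross_validate(four_class_features, spec=ClassifierSpec(seed=3), k=5)
    cm2, r2 = cross_validate(four_class_features, spec=ClassifierSpec(seed=3), k=5)
    np.testing.assert_array_equal(cm1.ratios, cm2.ratios)
    assert r1.macro_f == r2.macro_f


def test_validation_errors(four_class_features):
    too_few = four_class_features.groupby("label", group_keys=False).head(5)
    with pytest.raises(ValueError, match="at least k"):
        cross_validate(too_few, k=10)
    with pytest.raises(ValueError, match="algorithm"):
        ClassifierSpec(algorithm="perceptron")
    with pytest.raises(ValueError, match="label"):
        cross_validate(four_class_features.drop(columns=["label"]))


def test_xgboost_backend_runs(separable_features):
    cm, report = cross_validate(separable_features, spec=ClassifierSpec("xgboost"), k=5)
    assert report.macro_f >= 0.97


class TestPairwise:
    def test_disjoint_pair_is_perfect(self, separable_features):
        report = pairwise_discrimination(separable_features, ("a", "d"), k=5)
        assert report.macro_f >= 0.99

    def test_identical_distribution_pair_is_chance(self, rng):
        x = rng.normal(0, 1, (400, 2))
        table = pd.DataFrame(x, columns=["i_p", "t_d"])
        table["label"] = ["u"] * 200 + ["v"] * 200
        report = pairwise_discrimination(table, ("u", "v"), k=5)
        assert report.macro_f == pytest.approx(0.5, abs=0.1)

    def test_pair_order_irrelevant(self, separable_features):
        r1 = pairwise_discrimination(separable_features, ("a", "b"), k=5)
        r2 = pairwise_discrimination(separable_features, ("b", "a"), k=5)
        assert r1.macro_f == r2.macro_f

    def test_missing_class_rejected(self, separable_features):
        with pytest.raises(ValueError, match="absent"):
            pairwise_discrimination(separable_features, ("a", "nope"), k=5)


class TestSubsets:
    def test_duplicate_subset_scores_identically(self, four_class_features):
        table = feature_subset_experiment(
            four_class_features, [("i_p", "t_d"), ("i_p", "t_d")], k=5
        )
        assert table["macro_f"].iloc[0] == table["macro_f"].iloc[1]

    def test_constant_feature_scores_at_chance_and_below_full_set(self, four_class_features):
        # a constant feature carries no signal: the classifier degenerates to a
        # fixed guess (macro F far below any informative subset)
        data = four_class_features.copy()
        data["flat"] = 1.0
        table = feature_subset_experiment(data, [("flat",), tuple(FEATURE_NAMES)], k=5)
        chance, full = table["macro_f"].iloc[0], table["macro_f"].iloc[1]
        assert chance <= 0.3
        assert full > chance

    def test_standard_subset_battery_runs(self, four_class_features):
        table = feature_subset_experiment(four_class_features, STANDARD_SUBSETS, k=5)
        assert len(table) == 4
        assert table["macro_f"].between(0, 1).all()
        # the full 13-feature set is at least as good as amplitude-only
        assert table["macro_f"].iloc[3] >= table["macro_f"].iloc[0] - 0.02

    def test_unknown_feature_rejected(self, four_class_features):
        with pytest.raises(ValueError, match="unknown feature"):
            feature_subset_experiment(four_class_features, [("i_q",)], k=5)


class TestImportance:
    def test_importances_normalized_and_ranked(self, rng):
        # one separating feature, one pure-noise feature
        n = 300
        table = pd.DataFrame(
            {
                "i_p": np.concatenate([rng.normal(0, 1, n), rng.normal(5, 1, n)]),
                "noise": rng.normal(0, 1, 2 * n),
            }
        )
        table["label"] = ["a"] * n + ["b"] * n
        imp = feature_importance(table)
        assert imp.sum() == pytest.approx(1.0)
        assert (imp >= 0).all()
        assert imp.idxmax() == "i_p"

    def test_permutation_importance_of_uninformative_feature_near_zero(self, rng):
        n = 300
        table = pd.DataFrame(
            {
                "i_p": np.concatenate([rng.normal(0, 1, n), rng.normal(5, 1, n)]),
                "noise": rng.normal(0, 1, 2 * n),
            }
        )
        table["label"] = ["a"] * n + ["b"] * n
        imp = feature_importance(table, mode="permutation", n_repeats=5, seed=1)
        assert abs(imp["noise"]) < 0.02
        assert imp["i_p"] > 0.1

    def test_impurity_mode_requires_tree_ensemble(self, four_class_features):
        with pytest.raises(ValueError, match="tree-ensemble"):
            feature_importance(four_class_features, spec=ClassifierSpec("svm"))
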