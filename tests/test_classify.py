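"""Comparison schemes, the metric panel against printed worked examples and
a brute-force oracle, and the cross-validation contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import reference_metrics_2x2

from eegfd.classify import (
    build_comparisons,
    cross_validate,
    metrics_from_confusion,
    round_half_up,
    train_mlp,
    train_svm,
)

ALL_GROUPS_CM = np.array([[15, 1, 2, 1], [1, 26, 1, 1], [2, 0, 28, 1], [1, 3, 2, 29]])
ALL_GROUPS_CLASSES = ("addict", "second", "first", "normal")


class TestBuildComparisons:
    def test_four_groups_give_eleven_schemes(self):
        schemes = build_comparisons(("addict", "first", "second", "normal"))
        assert len(schemes) == 11
        assert schemes[0].name == "All"
        ovr = [s for s in schemes if "Others" in s.name]
        assert len(ovr) == 4
        pairwise = schemes[5:]
        assert len(pairwise) == 6
        for s in pairwise:
            assert len(s.mapping) == 2

    def test_three_groups_give_seven_schemes(self):
        assert len(build_comparisons(("a", "b", "c"))) == 7

    def test_excluded_groups_contribute_no_instances(self):
        schemes = build_comparisons(("a", "b", "c", "d"))
        pair = next(s for s in schemes if s.name == "A vs B")
        mask, mapped = pair.apply(np.array(["a", "b", "c", "d", "a"]))
        assert mask.sum() == 3 and set(mapped) == {"a", "b"}

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            build_comparisons(("a",))


class TestMetricsFromConfusion:
    def test_all_groups_published_panel(self):
        """The printed four-class worked example reproduces at 2 decimals."""
        panel = metrics_from_confusion(ALL_GROUPS_CM, ALL_GROUPS_CLASSES)
        pc = panel.per_class
        assert round_half_up(pc.loc["addict", "precision"]) == 0.79
        assert round_half_up(pc.loc["addict", "tp_rate"]) == 0.79
        assert round_half_up(pc.loc["addict", "mcc"]) == 0.75
        assert round_half_up(pc.loc["second", "tp_rate"]) == 0.90
        assert round_half_up(pc.loc["second", "mcc"]) == 0.84
        assert round_half_up(pc.loc["first", "tp_rate"]) == 0.90
        assert round_half_up(pc.loc["normal", "precision"]) == 0.91
        assert round_half_up(panel.weighted["f_measure"]) == 0.86
        assert round_half_up(panel.weighted["mcc"]) == 0.81

    def test_two_class_published_weighted_f(self):
        panel = metrics_from_confusion(np.array([[18, 1], [1, 30]]))
        assert round_half_up(panel.weighted["f_measure"]) == 0.96

    def test_perfect_classifier_all_ones(self):
        panel = metrics_from_confusion(np.array([[10, 0], [0, 10]]))
        for col in ("tp_rate", "precision", "recall", "f_measure", "mcc"):
            assert (panel.per_class[col] == 1.0).all()
        assert (panel.per_class["fp_rate"] == 0.0).all()

    def test_no_association_mcc_zero(self):
        panel = metrics_from_confusion(np.array([[5, 5], [5, 5]]))
        assert (panel.per_class["mcc"] == 0.0).all()

    @pytest.mark.parametrize("cm", [np.array([[1, 2, 3]]), -np.eye(2)])
    def test_malformed_matrix_rejected(self, cm):
        with pytest.raises(ValueError):
            metrics_from_confusion(cm)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=4, max_size=4))
    def test_matches_closed_form_oracle_on_2x2(self, entries):
        cm = np.array(entries).reshape(2, 2)
        if cm.sum() == 0:
            return
        panel = metrics_from_confusion(cm)
        oracle = reference_metrics_2x2(cm)
        for i, cls in enumerate(panel.classes):
            row = panel.per_class.loc[cls]
            assert row["precision"] == pytest.approx(oracle[i]["precision"], abs=1e-12)
            assert row["recall"] == pytest.approx(oracle[i]["recall"], abs=1e-12)
            assert row["fp_rate"] == pytest.approx(oracle[i]["fp_rate"], abs=1e-12)
            assert row["f_measure"] == pytest.approx(oracle[i]["f"], abs=1e-12)
            assert row["mcc"] == pytest.approx(oracle[i]["mcc"], abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_weighted_average_is_convex_combination(self, seed):
        rng = np.random.default_rng(seed)
        c = int(rng.integers(2, 5))
        cm = rng.integers(0, 30, (c, c))
        if (cm.sum(axis=1) == 0).any():
            return
        panel = metrics_from_confusion(cm)
        for col in ("precision", "recall", "f_measure"):
            vals = panel.per_class[col]
            assert vals.min() - 1e-12 <= panel.weighted[col] <= vals.max() + 1e-12


def separated_blobs(rng, n=60, gap=6.0):
    X = np.vstack([rng.normal(0, 1, (n // 2, 3)),
                   rng.normal(gap, 1, (n // 2, 3))])
    y = np.repeat(["a", "b"], n // 2)
    return X, y


class TestTrainers:
    def test_both_models_fit_separable_data_perfectly(self):
        rng = np.random.default_rng(0)
        X, y = separated_blobs(rng)
        for trainer in (train_mlp, train_svm):
            clf = trainer(X, y, seed=1)
            assert (clf.predict(X) == y).mean() == 1.0

    def test_mlp_learns_xor_where_linear_svm_cannot(self):
        rng = np.random.default_rng(1)
        centers = [(0, 0, "a"), (4, 4, "a"), (0, 4, "b"), (4, 0, "b")]
        X = np.vstack([rng.normal((cx, cy), 0.3, (30, 2)) for cx, cy, _ in centers])
        y = np.repeat([c for _, _, c in centers], 30)
        mlp = train_mlp(X, y, seed=2)
        assert (mlp.predict(X) == y).mean() >= 0.95
        lin = train_svm(X, y, seed=2, kernel="linear")
        assert (lin.predict(X) == y).mean() <= 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_mlp(np.zeros((10, 2)), np.zeros(10))

    def test_non_finite_features_rejected(self):
        X = np.zeros((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_svm(X, np.repeat(["a", "b"], 5))


class TestCrossValidate:
    def _scheme(self):
        return build_comparisons(("a", "b", "c", "d"))[0]

    def test_separable_two_class_high_weighted_f(self):
        rng = np.random.default_rng(3)
        X, y = separated_blobs(rng, n=60)
        scheme = next(s for s in build_comparisons(("a", "b", "c", "d"))
                      if s.name == "A vs B")
        panel = cross_validate(X, y, scheme, model="mlp", k=5, seed=0)
        assert panel.weighted["f_measure"] >= 0.95
        assert panel.confusion.sum() == 60

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(4)
        X, y = separated_blobs(rng, n=80)
        y_perm = rng.permutation(y)
        scheme = next(s for s in build_comparisons(("a", "b", "c", "d"))
                      if s.name == "A vs B")
        panel = cross_validate(X, y_perm, scheme, model="svm", k=5, seed=0)
        chance = 0.5  # balanced classes
        assert abs(panel.weighted["f_measure"] - chance) <= 0.15

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (48, 4))
        y = np.tile(["a", "b", "c", "d"], 12)
        p1 = cross_validate(X, y, self._scheme(), model="mlp", k=4, seed=9,
                            transform="crisp")
        p2 = cross_validate(X, y, self._scheme(), model="mlp", k=4, seed=9,
                            transform="crisp")
        np.testing.assert_array_equal(p1.confusion, p2.confusion)
        np.testing.assert_allclose(p1.per_class["roc_area"],
                                   p2.per_class["roc_area"], atol=1e-9)

    def test_small_class_reduces_folds_with_warning(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (24, 3))
        y = np.array(["a"] * 20 + ["b"] * 4)
        scheme = next(s for s in build_comparisons(("a", "b", "c", "d"))
                      if s.name == "A vs B")
        with pytest.warns(UserWarning, match="folds"):
            panel = cross_validate(X, y, scheme, model="svm", k=10, seed=0)
        assert panel.confusion.sum() == 24

    def test_pooled_confusion_total_equals_scheme_instances(self, feature_like_table):
        X, y = feature_like_table
        scheme = next(s for s in build_comparisons(("addict", "first", "second",
                                                    "normal"))
                      if s.name == "Addict vs Others")
        panel = cross_validate(X, y, scheme, model="svm", k=5, seed=1)
        assert panel.confusion.sum() == len(y)
        assert panel.confusion[0].sum() == 20  # addict instances
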