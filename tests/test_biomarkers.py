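import itertools

import numpy as np
import pandas as pd
import pytest

from cpttrial.biomarkers import (
    RFSettings,
    class_summaries,
    feature_table,
    rf_pairwise,
    roc_curve,
    scrambled_control,
    select_predictors,
    spearman_matrix,
)

FAST = RFSettings(repeats=10, cv_folds=5, n_estimators=100)


# ---------------------------------------------------------------------------
# oracles


def brute_ranks(x):
    """Average ranks computed by direct position counting."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        equal = np.sum(x == xi)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def brute_spearman(x, y):
    rx, ry = brute_ranks(x), brute_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def brute_auc(scores, labels):
    """Pairwise concordance count over all (positive, negative) pairs."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------


class TestSpearmanMatrix:
    def test_perfect_positive(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [10, 20, 30, 40]})
        assert spearman_matrix(df).loc["x", "y"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [4, 3, 2, 1]})
        assert spearman_matrix(df).loc["x", "y"] == pytest.approx(-1.0)

    def test_worked_example(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [3, 1, 2, 5, 4]})
        assert spearman_matrix(df).loc["x", "y"] == pytest.approx(0.6)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((20, 4)), columns=list("abcd"))
        mat = spearman_matrix(df)
        np.testing.assert_allclose(mat.values, mat.values.T)
        np.testing.assert_allclose(np.diag(mat.values), 1.0)
        assert ((mat.values >= -1) & (mat.values <= 1)).all()

    def test_constant_column_is_nan_not_zero(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "c": [5, 5, 5, 5]})
        mat = spearman_matrix(df)
        assert np.isnan(mat.loc["x", "c"])
        assert np.isnan(mat.loc["c", "c"])

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"x": [1, 2], "y": [2, 1]}))

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            x = rng.integers(0, 4, n).astype(float)  # heavy ties
            y = rng.integers(0, 4, n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            df = pd.DataFrame({"x": x, "y": y})
            assert spearman_matrix(df).loc["x", "y"] == pytest.approx(
                brute_spearman(x, y), abs=1e-12
            )


class TestRfPairwise:
    def test_separable_fixture(self, separable_fixture):
        X, y = separable_fixture
        res = rf_pairwise(X, y, settings=FAST, seed=0)
        assert res.mean_accuracy >= 0.95
        assert res.mean_importances["f3"] >= 90
        assert "f3" in res.selected_predictors

    def test_importance_scaling(self, separable_fixture):
        X, y = separable_fixture
        res = rf_pairwise(X, y, settings=RFSettings(repeats=3, cv_folds=5, n_estimators=50), seed=1)
        assert max(res.mean_importances.values()) <= 100.0
        assert min(res.mean_importances.values()) >= 0.0

    def test_deterministic(self, separable_fixture):
        X, y = separable_fixture
        s = RFSettings(repeats=3, cv_folds=5, n_estimators=50)
        a = rf_pairwise(X, y, settings=s, seed=5)
        b = rf_pairwise(X, y, settings=s, seed=5)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        assert a.mean_importances == b.mean_importances

    def test_single_class_rejected(self, separable_fixture):
        X, _ = separable_fixture
        with pytest.raises(ValueError, match="two classes"):
            rf_pairwise(X, ["A"] * len(X), settings=FAST)

    def test_small_class_rejected_by_name(self, separable_fixture):
        X, _ = separable_fixture
        y = np.array(["A"] * (len(X) - 3) + ["tiny"] * 3)
        with pytest.raises(ValueError, match="tiny"):
            rf_pairwise(X, y, settings=FAST)

    def test_zero_repeats_rejected(self, separable_fixture):
        X, y = separable_fixture
        with pytest.raises(ValueError, match="repeats"):
            rf_pairwise(X, y, settings=RFSettings(repeats=0))


class TestSelectPredictors:
    def test_single_dominant(self):
        imp = {"Pmc": 100.0, "Y11": 30.0, "Af0": 5.0}
        assert select_predictors(imp) == ["Pmc"]

    def test_all_below_threshold(self):
        assert select_predictors({"a": 50.0, "b": 12.0}) == []

    def test_two_above_sorted(self):
        imp = {"Y3cb": 61.0, "Pmc": 78.0, "A_f0": 12.0}
        assert select_predictors(imp) == ["Pmc", "Y3cb"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            select_predictors({"a": 120.0})


class TestScrambledControl:
    def test_chance_accuracy_and_no_predictors(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.random((80, 8)), columns=[f"f{i}" for i in range(8)])
        y = np.array(["A"] * 40 + ["B"] * 40)
        res = scrambled_control(
            X, y, settings=RFSettings(repeats=20, cv_folds=5, n_estimators=100), seed=13
        )
        assert 0.45 <= res.mean_accuracy <= 0.55
        assert res.selected_predictors == []

    def test_deterministic(self, separable_fixture):
        X, y = separable_fixture
        s = RFSettings(repeats=3, cv_folds=5, n_estimators=50)
        a = scrambled_control(X, y, settings=s, seed=9)
        b = scrambled_control(X, y, settings=s, seed=9)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_real_beats_scrambled(self, separable_fixture):
        X, y = separable_fixture
        s = RFSettings(repeats=10, cv_folds=5, n_estimators=100)
        real = rf_pairwise(X, y, settings=s, seed=2)
        null = scrambled_control(X, y, settings=s, seed=2)
        assert real.mean_accuracy - null.mean_accuracy >= 0.2


class TestRocCurve:
    def test_perfect_ranking(self):
        _, _, auc = roc_curve([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)

    def test_constant_scores(self):
        _, _, auc = roc_curve([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0])
        assert auc == pytest.approx(0.5)

    def test_swapped_pair(self):
        # brute-force pair counting: only (0.8, 0.4) is concordant -> 1/4
        _, _, auc = roc_curve([0.3, 0.8, 0.4, 0.9], [1, 1, 0, 0])
        assert auc == pytest.approx(brute_auc([0.3, 0.8, 0.4, 0.9], [1, 1, 0, 0]))
        assert auc == pytest.approx(0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 15))
            scores = rng.integers(0, 5, n) / 4.0  # ties included
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            _, _, auc = roc_curve(scores, labels)
            assert auc == pytest.approx(brute_auc(scores, labels), abs=1e-12)


class TestClassSummaries:
    def test_fractions_and_counts(self, small_stratified):
        out = class_summaries(small_stratified.table)
        total = sum(v["n"] for v in out.values())
        assert total == len(small_stratified.table)
        for v in out.values():
            if v.get("missing"):
                continue
            assert 0 <= v["nonunion_fraction_treated"] <= 1
            q = v["fibrous_day49_treated"]
            assert q["q1"] <= q["median"] <= q["q3"]

    def test_empty_class_flagged(self, small_trial):
        table = small_trial.copy()
        table["manual_class"] = "asymptomatic"
        out = class_summaries(table)
        assert out["responder"] == {"n": 0, "missing": True}

    def test_all_union_class_zero_fraction(self, small_stratified):
        table = small_stratified.table
        asym = table[table["manual_class"] == "asymptomatic"]
        if len(asym) and (asym["union_t"] == 1).all():
            out = class_summaries(table)
            assert out["asymptomatic"]["nonunion_fraction_treated"] == 0.0


class TestFeatureTable:
    def test_contains_params_and_fractions(self, small_trial):
        ft = feature_table(small_trial)
        assert "P_mc" in ft.columns
        assert "fib_d49_t" in ft.columns
        assert "ci_u" in ft.columns
        assert ft.select_dtypes(include=[np.number]).shape == ft.shape
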