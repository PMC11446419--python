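"""Repeated-CV harness: balancing, feature elimination, bookkeeping, determinism."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from phenospec import (
    FEATURE_NAMES,
    ClassifierSpec,
    FeatureVector,
    LabeledCohort,
    aggregate_scores,
    feature_frequency,
    rfecv_select,
    run_repeated_cv,
    undersample,
)
from phenospec.cv import CVResult, FitRecord, default_grid
from phenospec.errors import ConfigurationError, ValidationError

NB_SPEC = ClassifierSpec(family="gaussian_naive_bayes", grid={"var_smoothing": [1e-9]})


def _feature_vectors(X, ids):
    return [
        FeatureVector(sample_id=i, **dict(zip(FEATURE_NAMES, row)))
        for i, row in zip(ids, X)
    ]


def _toy_cohort(rng, n=60, informative=3, signal=3.0):
    """Balanced labels; the first `informative` features carry the signal."""
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, len(FEATURE_NAMES)))
    for j in range(informative):
        X[:, j] += signal * y
    ids = [f"s{i}" for i in range(n)]
    labels = LabeledCohort(
        labels={i: (30.0 if yi else 20.0, int(yi)) for i, yi in zip(ids, y)},
        threshold=25.0,
    )
    return _feature_vectors(X, ids), labels, y


class TestClassifierSpec:
    def test_default_grids_populated(self):
        for family in ("feedforward_nn", "gradient_boosted_trees",
                       "random_forest", "gaussian_naive_bayes"):
            assert default_grid(family)

    def test_nn_grid_matches_tuned_value_sets(self):
        grid = default_grid("feedforward_nn")
        assert grid["hidden_width"] == [20, 40, 60]
        assert grid["epochs"] == [50, 100, 150]
        assert grid["batch_size"] == [16, 32, 64]

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassifierSpec(family="support_vector_machine")

    def test_empty_grid_values_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassifierSpec(family="random_forest", grid={"n_estimators": []})


class TestUndersample:
    def test_138_vs_91_becomes_91_vs_91(self, rng):
        idx = np.arange(229)
        by_class = {1: idx[:138], 0: idx[138:]}
        balanced = undersample(by_class, seed=1)
        assert len(balanced) == 182
        assert np.sum(np.isin(balanced, by_class[0])) == 91
        assert np.sum(np.isin(balanced, by_class[1])) == 91

    def test_already_balanced_unchanged(self):
        by_class = {0: np.arange(10), 1: np.arange(10, 20)}
        assert np.array_equal(undersample(by_class, seed=5), np.arange(20))

    def test_same_seed_same_subsample(self):
        by_class = {0: np.arange(50), 1: np.arange(50, 80)}
        a = undersample(by_class, seed=9)
        b = undersample(by_class, seed=9)
        assert np.array_equal(a, b)


class TestRfecv:
    def test_planted_features_recovered(self):
        """Three individually weak, jointly informative features all survive."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fvs, labels, y = _toy_cohort(rng, n=120, signal=1.0)
            X = np.vstack([fv.as_array() for fv in fvs])
            selected = rfecv_select(X, y, inner_folds=3, seed=seed)
            if {"s_mean", "s_var", "s_sd"} <= set(selected):
                hits += 1
        assert hits >= 9

    def test_duplicate_informative_feature_still_selects_usefully(self, rng):
        n = 80
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, len(FEATURE_NAMES)))
        X[:, 0] += 3.0 * y
        X[:, 1] = X[:, 0]  # exact copy
        selected = rfecv_select(X, y, seed=0)
        assert selected
        mask = np.array([name in selected for name in FEATURE_NAMES])
        cv = StratifiedKFold(3, shuffle=True, random_state=0)
        acc_sel = cross_val_score(LogisticRegression(max_iter=2000), X[:, mask], y, cv=cv).mean()
        acc_full = cross_val_score(LogisticRegression(max_iter=2000), X, y, cv=cv).mean()
        assert acc_sel >= acc_full - 1e-9

    def test_single_feature_returned(self, rng):
        X = rng.normal(size=(30, 1))
        y = np.array([0, 1] * 15)
        assert rfecv_select(X, y, feature_names=("only",), seed=0) == ("only",)

    def test_too_small_class_rejected(self, rng):
        X = rng.normal(size=(5, 4))
        y = np.array([0, 0, 0, 1, 1])
        with pytest.raises(ValidationError):
            rfecv_select(X, y, inner_folds=3, seed=0)


class TestRunRepeatedCV:
    def test_score_and_fit_bookkeeping(self, rng):
        fvs, labels, _ = _toy_cohort(rng)
        res = run_repeated_cv(fvs, labels, NB_SPEC, R=2, K=3, seed=4)
        assert len(res.fits) == 2 * 3
        for sid in res.sample_ids:
            scores = res.scores[sid]
            assert len(scores) == 2
            assert all(0.0 <= s <= 1.0 for s in scores)

    def test_test_fold_purity(self, rng):
        """Each sample appears in exactly one test fold per repetition."""
        fvs, labels, _ = _toy_cohort(rng)
        res = run_repeated_cv(fvs, labels, NB_SPEC, R=3, K=4, seed=4)
        for r in range(3):
            seen = [sid for f in res.fits if f.repetition == r for sid in f.test_ids]
            assert sorted(seen) == sorted(res.sample_ids)

    def test_leave_one_out_scores_each_sample_once(self, rng):
        fvs, labels, _ = _toy_cohort(rng, n=14)
        res = run_repeated_cv(fvs, labels, NB_SPEC, R=1, K=14, seed=0)
        assert all(len(s) == 1 for s in res.scores.values())

    def test_deterministic_for_fixed_seed(self, rng):
        fvs, labels, _ = _toy_cohort(rng)
        a = run_repeated_cv(fvs, labels, NB_SPEC, R=2, K=3, seed=11)
        b = run_repeated_cv(fvs, labels, NB_SPEC, R=2, K=3, seed=11)
        assert a.scores == b.scores
        assert [f.selected_features for f in a.fits] == [f.selected_features for f in b.fits]

    def test_single_class_cohort_rejected(self, rng):
        fvs, labels, _ = _toy_cohort(rng, n=20)
        all_one = LabeledCohort(
            labels={i: (30.0, 1) for i in labels.labels}, threshold=25.0
        )
        with pytest.raises(ValidationError):
            run_repeated_cv(fvs, all_one, NB_SPEC, R=1, K=2, seed=0)

    def test_grid_search_picks_from_grid(self, rng):
        fvs, labels, _ = _toy_cohort(rng, n=40)
        spec = ClassifierSpec(
            family="gaussian_naive_bayes",
            grid={"var_smoothing": [1e-9, 1e-3]},
        )
        res = run_repeated_cv(fvs, labels, spec, R=1, K=2, seed=0)
        for fit in res.fits:
            assert fit.hyperparameters["var_smoothing"] in (1e-9, 1e-3)


class TestAggregation:
    def _result(self, scores):
        ids = list(scores)
        return CVResult(
            sample_ids=ids,
            scores=scores,
            fits=[FitRecord(0, 0, ("s_mean",), {}, 1, tuple(ids))],
            R=len(next(iter(scores.values()))),
            K=1,
            seed=0,
        )

    def test_odd_count_median(self):
        res = self._result({"a": [0.2, 0.4, 0.9]})
        assert aggregate_scores(res)["a"] == pytest.approx(0.4)

    def test_even_count_midpoint(self):
        res = self._result({"a": [0.2, 0.8]})
        assert aggregate_scores(res)["a"] == pytest.approx(0.5)

    def test_identical_scores_unchanged(self):
        res = self._result({"a": [0.7, 0.7, 0.7]})
        assert aggregate_scores(res)["a"] == pytest.approx(0.7)

    def test_missing_scores_rejected(self):
        res = self._result({"a": [0.2]})
        res.scores["b"] = []
        res.sample_ids.append("b")
        with pytest.raises(ValidationError, match="b"):
            aggregate_scores(res)


class TestFeatureFrequency:
    def test_counts_and_conservation(self, rng):
        fvs, labels, _ = _toy_cohort(rng)
        res = run_repeated_cv(fvs, labels, NB_SPEC, R=2, K=3, seed=2)
        freq = feature_frequency(res)
        assert sum(freq.values()) == sum(len(f.selected_features) for f in res.fits)
        assert max(freq.values()) <= res.R * res.K
        assert freq["s_kurt"] >= 0  # absent features simply count 0

    def test_always_selected_feature_counts_every_fit(self):
        fits = [FitRecord(r, k, ("s_skew",), {}, 0, ()) for r in range(10) for k in range(5)]
        res = CVResult(sample_ids=[], scores={}, fits=fits, R=10, K=5, seed=0)
        assert feature_frequency(res)["s_skew"] == 50
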