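"""Repeated k-fold cross-validation with per-fold undersampling, recursive
feature elimination and grid search, over pluggable probabilistic classifiers.

The harness mirrors an imbalance-aware evaluation protocol: in each of R
repetitions the cohort is randomly partitioned into K folds; for every
training fold the majority class is undersampled to the minority count,
feature standardization is fitted on the balanced fold, recursive feature
elimination with cross-validation (RFECV, logistic-regression estimator,
3-fold inner CV) picks the feature subset, a hyperparameter grid is searched
with 3-fold inner CV on accuracy, and the final classifier scores the
untouched test fold.  Each sample therefore receives exactly R out-of-fold
probability scores; the per-sample median is its aggregate score.

Classifier families sit behind a uniform contract (``fit`` /
``predict_proba``): a feedforward neural network (two ReLU hidden layers of
equal width, sigmoid output), gradient-boosted trees, random forest, and
Gaussian naive Bayes.

Seeding is counter-based: the master seed fans out per (repetition, fold,
stage) through ``numpy.random.SeedSequence`` spawn keys, so any single fit
is reproducible in isolation.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from statistics import median

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score

from .errors import ConfigurationError, ValidationError
from .features import FEATURE_NAMES, FeatureVector, feature_matrix, fit_scaler
from .labeling import LabeledCohort

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "FitRecord",
    "default_grid",
    "run_repeated_cv",
    "undersample",
    "rfecv_select",
    "aggregate_scores",
    "feature_frequency",
]

FAMILIES = (
    "feedforward_nn",
    "gradient_boosted_trees",
    "random_forest",
    "gaussian_naive_bayes",
)

_DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    # hidden width shared by both hidden layers; epochs/batch grids as tuned
    "feedforward_nn": {
        "hidden_width": [20, 40, 60],
        "epochs": [50, 100, 150],
        "batch_size": [16, 32, 64],
    },
    # the five gradient-boosting knobs: tree count, child weight, split gain,
    # row subsampling, depth
    "gradient_boosted_trees": {
        "n_estimators": [100, 200],
        "min_child_weight": [1, 3],
        "gamma": [0.0, 0.1],
        "subsample": [0.8, 1.0],
        "max_depth": [3, 6],
    },
    "random_forest": {
        "n_estimators": [100, 200],
        "max_depth": [None, 10],
        "min_samples_split": [2, 5],
        "min_samples_leaf": [1, 2],
    },
    "gaussian_naive_bayes": {
        "var_smoothing": [1e-9, 1e-8, 1e-7],
    },
}


def default_grid(family: str) -> dict[str, list]:
    """The default hyperparameter grid for a classifier family."""
    if family not in _DEFAULT_GRIDS:
        raise ConfigurationError(f"unknown classifier family {family!r}; choose from {FAMILIES}")
    return {k: list(v) for k, v in _DEFAULT_GRIDS[family].items()}


@dataclass
class ClassifierSpec:
    """A classifier family plus its hyperparameter grid and inner-CV settings."""

    family: str = "feedforward_nn"
    grid: dict[str, list] = field(default_factory=dict)
    inner_cv_folds: int = 3
    scoring: str = "accuracy"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown classifier family {self.family!r}; choose from {FAMILIES}"
            )
        if not self.grid:
            self.grid = default_grid(self.family)
        for name, values in self.grid.items():
            if not values:
                raise ConfigurationError(f"empty value list for hyperparameter {name!r}")
        if self.scoring != "accuracy":
            raise ConfigurationError("scoring is fixed to accuracy")


@dataclass(frozen=True)
class FitRecord:
    """Provenance of one (repetition, fold) fit."""

    repetition: int
    fold: int
    selected_features: tuple[str, ...]
    hyperparameters: dict
    seed: int
    test_ids: tuple[str, ...] = ()


@dataclass
class CVResult:
    """Out-of-fold scores and per-fit selections from repeated CV."""

    sample_ids: list[str]
    scores: dict[str, list[float]]
    fits: list[FitRecord]
    R: int
    K: int
    seed: int
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def mean_selected_count(self) -> float:
        """Average number of features selected per fit."""
        return float(np.mean([len(f.selected_features) for f in self.fits]))


def _child_seed(master: int, *key: int) -> int:
    """Counter-based child seed below 2**31, reproducible in isolation."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def build_estimator(family: str, params: dict, seed: int, n_train: int | None = None):
    """Instantiate a classifier behind the uniform fit/predict_proba contract."""
    if family == "feedforward_nn":
        from sklearn.neural_network import MLPClassifier

        batch = int(params.get("batch_size", 32))
        if n_train is not None:
            batch = min(batch, n_train)
        return MLPClassifier(
            hidden_layer_sizes=(int(params.get("hidden_width", 40)),) * 2,
            activation="relu",
            solver="adam",
            max_iter=int(params.get("epochs", 100)),
            batch_size=batch,
            random_state=seed,
        )
    if family == "gradient_boosted_trees":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=int(params.get("n_estimators", 100)),
            min_child_weight=params.get("min_child_weight", 1),
            gamma=params.get("gamma", 0.0),
            subsample=params.get("subsample", 1.0),
            max_depth=int(params.get("max_depth", 6)),
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
        )
    if family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 100)),
            max_depth=params.get("max_depth", None),
            min_samples_split=params.get("min_samples_split", 2),
            min_samples_leaf=params.get("min_samples_leaf", 1),
            random_state=seed,
            n_jobs=1,
        )
    if family == "gaussian_naive_bayes":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB(var_smoothing=params.get("var_smoothing", 1e-9))
    raise ConfigurationError(f"unknown classifier family {family!r}")


def undersample(indices_by_class: dict[int, np.ndarray], seed: int) -> np.ndarray:
    """Subsample the majority class without replacement to the minority size.

    Returns the sorted union of retained indices; already-balanced input is
    returned unchanged (up to ordering).
    """
    if len(indices_by_class) != 2:
        raise ValidationError("undersampling requires exactly 2 classes present")
    rng = np.random.default_rng(seed)
    sizes = {c: len(idx) for c, idx in indices_by_class.items()}
    minority_n = min(sizes.values())
    kept: list[np.ndarray] = []
    for c, idx in sorted(indices_by_class.items()):
        idx = np.asarray(idx)
        if len(idx) > minority_n:
            idx = rng.choice(idx, size=minority_n, replace=False)
        kept.append(idx)
    return np.sort(np.concatenate(kept))


def rfecv_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    inner_folds: int = 3,
    seed: int = 0,
) -> tuple[str, ...]:
    """Recursive feature elimination with cross-validated subset size.

    Drops the lowest-weight feature one at a time under a logistic-regression
    estimator, keeping the feature count that maximizes inner-CV accuracy.
    A single-feature input is returned as-is.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        return tuple(feature_names[: X.shape[1]])
    counts = Counter(y.tolist())
    if min(counts.values()) < inner_folds:
        raise ValidationError(
            f"fewer than {inner_folds} samples in a class: cannot run {inner_folds}-fold RFECV"
        )
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    selector = RFECV(
        estimator=LogisticRegression(max_iter=2000),
        step=1,
        cv=cv,
        scoring="accuracy",
        min_features_to_select=1,
        n_jobs=1,
    )
    selector.fit(X, y)
    return tuple(name for name, keep in zip(feature_names, selector.support_) if keep)


def _grid_combinations(grid: dict[str, list]) -> list[dict]:
    names = sorted(grid)
    return [dict(zip(names, values)) for values in itertools.product(*(grid[n] for n in names))]


def _grid_search(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    seed: int,
) -> dict:
    """Pick the grid combination maximizing inner-CV accuracy.

    A one-combination grid skips the search.  Ties break to the first
    combination in deterministic (sorted-name, product) order.
    """
    combos = _grid_combinations(spec.grid)
    if len(combos) == 1:
        return combos[0]
    cv = StratifiedKFold(n_splits=spec.inner_cv_folds, shuffle=True, random_state=seed)
    best_params, best_score = combos[0], -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for params in combos:
            est = build_estimator(spec.family, params, seed, n_train=len(y))
            score = float(cross_val_score(est, X, y, cv=cv, scoring=spec.scoring).mean())
            if score > best_score:
                best_params, best_score = params, score
    return best_params


def run_repeated_cv(
    features: list[FeatureVector],
    labels: LabeledCohort,
    spec: ClassifierSpec,
    R: int = 10,
    K: int = 5,
    seed: int = 0,
    stratified: bool = False,
) -> CVResult:
    """R repetitions of K-fold CV with per-fold balancing and selection.

    Every sample lands in the test fold exactly once per repetition, so the
    result carries exactly R probability scores per sample and R*K fit
    records.  Fold partitions are shuffled (unstratified) by default.
    """
    X_all, ids = feature_matrix(features)
    missing = [i for i in ids if i not in labels.labels]
    if missing:
        raise ValidationError(f"no label for samples: {missing[:5]}")
    y_all = np.array([labels.label_of(i) for i in ids])
    n = len(ids)
    class_counts = Counter(y_all.tolist())
    if len(class_counts) < 2:
        raise ValidationError("both classes must be present in the cohort")
    if min(class_counts.values()) < 2:
        raise ValidationError(
            f"minority class has {min(class_counts.values())} sample(s); need at least 2"
        )
    if K < 2 or K > n:
        raise ValidationError(f"K={K} must be in [2, n={n}]")

    scores: dict[str, list[float]] = {i: [] for i in ids}
    fits: list[FitRecord] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for r in range(R):
            rep_seed = _child_seed(seed, r)
            splitter = (
                StratifiedKFold(n_splits=K, shuffle=True, random_state=rep_seed)
                if stratified
                else KFold(n_splits=K, shuffle=True, random_state=rep_seed)
            )
            split_iter = splitter.split(X_all, y_all) if stratified else splitter.split(X_all)
            for k, (train_idx, test_idx) in enumerate(split_iter):
                fit_seed = _child_seed(seed, r, k)
                y_train = y_all[train_idx]
                by_class = {
                    c: train_idx[y_train == c] for c in sorted(set(y_train.tolist()))
                }
                if len(by_class) < 2:
                    raise ValidationError(
                        f"repetition {r} fold {k}: training fold lost a class"
                    )
                balanced_idx = undersample(by_class, seed=_child_seed(seed, r, k, 1))
                Xb, yb = X_all[balanced_idx], y_all[balanced_idx]

                scaler = fit_scaler(Xb)
                Zb = scaler.transform(Xb)

                selected = rfecv_select(
                    Zb, yb, feature_names=FEATURE_NAMES,
                    inner_folds=spec.inner_cv_folds,
                    seed=_child_seed(seed, r, k, 2),
                )
                if not selected:
                    selected = (FEATURE_NAMES[0],)
                sel_mask = np.array([name in selected for name in FEATURE_NAMES])

                params = _grid_search(Zb[:, sel_mask], yb, spec, _child_seed(seed, r, k, 3))
                est = build_estimator(spec.family, params, fit_seed, n_train=len(yb))
                est.fit(Zb[:, sel_mask], yb)

                Zt = scaler.transform(X_all[test_idx])[:, sel_mask]
                prob = est.predict_proba(Zt)
                pos_col = int(np.flatnonzero(est.classes_ == 1)[0])
                for i, p in zip(test_idx, prob[:, pos_col]):
                    scores[ids[i]].append(float(np.clip(p, 0.0, 1.0)))
                fits.append(
                    FitRecord(
                        repetition=r,
                        fold=k,
                        selected_features=selected,
                        hyperparameters=dict(params),
                        seed=fit_seed,
                        test_ids=tuple(ids[i] for i in test_idx),
                    )
                )

    bad = [i for i, s in scores.items() if len(s) != R]
    if bad:
        raise ValidationError(f"samples without exactly {R} scores: {bad[:5]}")
    return CVResult(sample_ids=ids, scores=scores, fits=fits, R=R, K=K, seed=seed)


def aggregate_scores(result: CVResult) -> dict[str, float]:
    """Per-sample median of the R out-of-fold probabilities."""
    missing = [i for i, s in result.scores.items() if not s]
    if missing:
        raise ValidationError(f"samples with no scores: {missing[:5]}")
    return {i: float(median(s)) for i, s in result.scores.items()}


def feature_frequency(result: CVResult) -> Counter:
    """How many of the R*K fits selected each feature (max possible R*K)."""
    counts: Counter = Counter()
    for fit in result.fits:
        counts.update(fit.selected_features)
    return counts
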