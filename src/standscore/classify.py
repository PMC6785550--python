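"""KNN classification of assisted vs independent standing.

The classifier is a K-nearest-neighbor model whose four tunable dimensions
(number of neighbors, distance metric, distance weighting, predictor
standardization) are optimized by Bayesian search with objective
log(1 + cross-validation loss), the loss being the misclassification ratio
under stratified 10-fold cross-validation.  Accuracy is reported as
100 * (1 - loss).  The optimize+validate cycle is iterated (10 times by
default) and the mean accuracy with a t-distribution 95% confidence
interval is reported per muscle group and feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .bayesopt import Categorical, Integer, bayes_minimize, random_minimize
from .pipeline import FeatureMatrix, MuscleGroup, select_group

__all__ = ["KnnConfig", "KnnStandingClassifier", "CvReport", "cross_validate",
           "optimize_knn", "evaluate_groups", "iterate_optimized_cv"]

METRICS = ("euclidean", "cityblock", "chebyshev", "cosine", "mahalanobis")
WEIGHTINGS = ("uniform", "inverse", "squared_inverse")


@dataclass(frozen=True)
class KnnConfig:
    """The four tuned KNN hyperparameters."""

    n_neighbors: int = 5
    metric: str = "euclidean"
    weighting: str = "uniform"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")


def _squared_inverse(d: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(d, 1e-12) ** 2


class KnnStandingClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn-compatible KNN with the tuned parameterization.

    ``weighting`` extends sklearn's uniform/inverse-distance choices with
    squared inverse distance; ``standardize`` centers and scales predictors
    on the training fold.  The Mahalanobis metric uses the (regularized)
    inverse covariance of the training predictors.
    """

    def __init__(self, n_neighbors: int = 5, metric: str = "euclidean",
                 weighting: str = "uniform", standardize: bool = True):
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.weighting = weighting
        self.standardize = standardize

    def _weights_arg(self):
        return {"uniform": "uniform", "inverse": "distance",
                "squared_inverse": _squared_inverse}[self.weighting]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.scaler_ = StandardScaler().fit(X) if self.standardize else None
        Xt = self.scaler_.transform(X) if self.scaler_ is not None else X
        k = min(self.n_neighbors, len(X))
        metric_params = None
        if self.metric == "mahalanobis":
            cov = np.cov(Xt, rowvar=False)
            cov = np.atleast_2d(cov) + 1e-8 * np.eye(Xt.shape[1])
            metric_params = {"VI": np.linalg.inv(cov)}
        self.knn_ = KNeighborsClassifier(
            n_neighbors=k, metric=self.metric, metric_params=metric_params,
            weights=self._weights_arg(), algorithm="brute")
        self.knn_.fit(Xt, y)
        self.classes_ = self.knn_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "knn_")
        X = np.asarray(X, dtype=float)
        Xt = self.scaler_.transform(X) if self.scaler_ is not None else X
        return self.knn_.predict(Xt)

    def predict_proba(self, X):
        check_is_fitted(self, "knn_")
        X = np.asarray(X, dtype=float)
        Xt = self.scaler_.transform(X) if self.scaler_ is not None else X
        return self.knn_.predict_proba(Xt)


def _as_Xy(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    fm.require_stage("normalized", "log")
    return fm.df.to_numpy(dtype=float), fm.y.to_numpy()


def cross_validate(fm: FeatureMatrix, config: KnnConfig, folds: int = 10,
                   seed: int = 0) -> tuple[float, float]:
    """Stratified k-fold misclassification loss and accuracy (%).

    Accuracy = 100 * (1 - loss) where loss is the pooled misclassified
    fraction across folds.
    """
    X, y = _as_Xy(fm)
    clf = KnnStandingClassifier(**config.__dict__)
    if folds >= len(y):
        # leave-one-out boundary case; stratification is meaningless there
        from sklearn.model_selection import LeaveOneOut
        cv = LeaveOneOut()
    else:
        counts = np.unique(y, return_counts=True)[1]
        if counts.min() < folds:
            raise ValueError(
                f"smallest class has {counts.min()} rows; cannot stratify "
                f"into {folds} folds")
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
    # weight folds by size so the loss is the pooled misclassified ratio
    sizes = np.array([len(te) for _, te in cv.split(X, y)])
    acc = float(np.average(scores, weights=sizes))
    loss = 1.0 - acc
    return loss, 100.0 * acc


_SPACE = (
    Integer("n_neighbors", 1, 30, log=True),
    Categorical("metric", METRICS),
    Categorical("weighting", WEIGHTINGS),
    Categorical("standardize", (True, False)),
)


def optimize_knn(fm: FeatureMatrix, budget: int = 30, seed: int = 0,
                 folds: int = 10, optimizer: str = "bayes"
                 ) -> tuple[KnnConfig, float, list]:
    """Tune the KNN hyperparameters by minimizing log(1 + CV loss).

    Returns (best config, best accuracy %, search trace); ``optimizer`` may
    be "bayes" (GP expected improvement) or "random" (uniform search behind
    the same interface).
    """
    X, y = _as_Xy(fm)
    counts = np.unique(y, return_counts=True)[1]
    if len(counts) < 2:
        raise ValueError("need two classes to optimize a classifier")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows < {folds} folds")
    n_train_min = len(y) - int(np.ceil(len(y) / folds))

    def objective(params: dict) -> float:
        cfg = KnnConfig(n_neighbors=min(params["n_neighbors"], n_train_min),
                        metric=params["metric"], weighting=params["weighting"],
                        standardize=params["standardize"])
        loss, _ = cross_validate(fm, cfg, folds=folds, seed=seed)
        return float(np.log1p(loss))

    minimize = bayes_minimize if optimizer == "bayes" else random_minimize
    best_params, best_obj, trace = minimize(objective, _SPACE,
                                            n_calls=budget, seed=seed)
    cfg = KnnConfig(n_neighbors=min(best_params["n_neighbors"], n_train_min),
                    metric=best_params["metric"],
                    weighting=best_params["weighting"],
                    standardize=best_params["standardize"])
    best_acc = 100.0 * (1.0 - np.expm1(best_obj))
    return cfg, float(best_acc), trace


@dataclass
class CvReport:
    """Accuracy of the optimized classifier for one muscle group/feature set."""

    group: str
    feature_set: str
    accuracy_mean: float                 # %
    ci95: tuple[float, float]            # %
    per_iteration: list[float] = field(default_factory=list)
    best_config: KnnConfig | None = None

    def to_dict(self) -> dict:
        return {"group": self.group, "feature_set": self.feature_set,
                "accuracy_mean": self.accuracy_mean, "ci95": list(self.ci95),
                "per_iteration": self.per_iteration,
                "best_config": (self.best_config.__dict__
                                if self.best_config else None)}


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    m = values.mean()
    if len(values) < 2 or values.std(ddof=1) == 0:
        return (float(m), float(m))
    half = stats.t.ppf(0.5 + level / 2, len(values) - 1) * stats.sem(values)
    return (float(m - half), float(m + half))


def iterate_optimized_cv(fm: FeatureMatrix, iterations: int = 10,
                         budget: int = 30, folds: int = 10, seed: int = 0,
                         optimizer: str = "bayes",
                         group: str = "all", feature_set: str = "combined"
                         ) -> CvReport:
    """Repeat optimize+cross-validate ``iterations`` times and summarize.

    Each iteration re-runs the hyperparameter search with a fresh fold
    shuffle; the per-iteration accuracy is that of the best configuration
    found.  The 95% CI is a t-interval over the iteration accuracies.
    """
    accs, best_cfg, best_acc = [], None, -np.inf
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(iterations):
        it_seed = int(child.generate_state(1)[0] % (2**31))
        cfg, acc, _ = optimize_knn(fm, budget=budget, seed=it_seed,
                                   folds=folds, optimizer=optimizer)
        accs.append(acc)
        if acc > best_acc:
            best_cfg, best_acc = cfg, acc
    arr = np.array(accs)
    return CvReport(group=group, feature_set=feature_set,
                    accuracy_mean=float(arr.mean()), ci95=_t_ci(arr),
                    per_iteration=accs, best_config=best_cfg)


def evaluate_groups(feature_sets: dict[str, FeatureMatrix],
                    groups: list[MuscleGroup], iterations: int = 10,
                    budget: int = 30, folds: int = 10, seed: int = 0,
                    optimizer: str = "bayes") -> list[CvReport]:
    """One CvReport per (muscle group, feature set) combination.

    ``feature_sets`` maps a name (e.g. "time", "cwt", "combined") to a
    classification-ready FeatureMatrix; each is subset per group.
    """
    reports = []
    for gi, group in enumerate(groups):
        for si, (name, fm) in enumerate(feature_sets.items()):
            sub = select_group(fm, group)
            rep = iterate_optimized_cv(
                sub, iterations=iterations, budget=budget, folds=folds,
                seed=seed + 1009 * gi + 101 * si, optimizer=optimizer,
                group=group.name, feature_set=name)
            reports.append(rep)
    return reports
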