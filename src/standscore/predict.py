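"""Muscle-pair KNN models and the distance-weighted posterior ranking score.

For each investigated muscle pair (the left and right instances of one
muscle), a KNN model is trained on one of three assistance-regime datasets:

(i)   hips+knees assisted vs hips+knees independent,
(ii)  one knee assisted vs hips+knees independent,
(iii) hips assisted / knees independent vs hips+knees independent.

A new standing event's feature row is scored with the weighted posterior of
the "independent standing" class over its K = 5 nearest training rows,

    P(C | x_new) = sum_i W(x_i) 1[x_i in C] / sum_i W(x_i),

where the weight of neighbor x_i is its inverse distance to x_new
normalized by the prior frequency of x_i's class (so a class cannot
dominate merely by being bigger).  Scores <= 0.5 label the muscle's
activation "assisted", scores > 0.5 "independent"; left-limb, right-limb
and total aggregates are arithmetic means of the member muscle scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .pipeline import FeatureMatrix, MuscleGroup, select_group

__all__ = ["MusclePairScorer", "TrainedMusclePairModel", "RankedPrediction",
           "REGIMES", "train_models", "score_events", "label_and_aggregate",
           "rank_parameter_sets"]

#: training regime -> (negative class, positive class); the positive class
#: is always independent standing
REGIMES = {
    "i": ("assisted", "independent"),
    "ii": ("one_knee_assisted", "independent"),
    "iii": ("hips_assisted_knees_independent", "independent"),
}

INDEPENDENT_CLASS = "independent"


class MusclePairScorer(BaseEstimator):
    """Distance-weighted KNN posterior scorer (scikit-learn estimator).

    ``weight_mode`` selects the reading of the neighbor weight:
    "inverse_prior" (default) uses W = (1/d) / prior(class), which makes the
    posterior calibrated under class imbalance; "raw_distance" uses
    W = d / prior(class) for sensitivity checks.  A zero-distance neighbor
    dominates the score (ties among zero-distance neighbors are averaged).
    """

    def __init__(self, n_neighbors: int = 5, standardize: bool = True,
                 weight_mode: str = "inverse_prior"):
        self.n_neighbors = n_neighbors
        self.standardize = standardize
        self.weight_mode = weight_mode

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        if INDEPENDENT_CLASS not in classes:
            raise ValueError(f"one class must be {INDEPENDENT_CLASS!r}")
        if self.n_neighbors > len(X):
            raise ValueError("n_neighbors exceeds training size")
        self.classes_ = classes
        self.scaler_ = StandardScaler().fit(X) if self.standardize else None
        self.X_ = self.scaler_.transform(X) if self.scaler_ is not None else X
        self.y_ = y
        self.priors_ = {c: float(np.mean(y == c)) for c in classes}
        self.nn_ = NearestNeighbors(n_neighbors=self.n_neighbors,
                                    algorithm="brute").fit(self.X_)
        return self

    def score_samples(self, X) -> np.ndarray:
        """Posterior of the independent class per row, in [0, 1]."""
        check_is_fitted(self, "nn_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Xt = self.scaler_.transform(X) if self.scaler_ is not None else X
        dist, idx = self.nn_.kneighbors(Xt)
        scores = np.empty(len(Xt))
        for r in range(len(Xt)):
            d, nb = dist[r], idx[r]
            is_pos = self.y_[nb] == INDEPENDENT_CLASS
            if np.any(d == 0):
                scores[r] = float(np.mean(is_pos[d == 0]))
                continue
            priors = np.array([self.priors_[c] for c in self.y_[nb]])
            if self.weight_mode == "inverse_prior":
                w = (1.0 / d) / priors
            elif self.weight_mode == "raw_distance":
                w = d / priors
            else:
                raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
            scores[r] = float(w[is_pos].sum() / w.sum())
        return scores

    def predict(self, X) -> np.ndarray:
        """"independent" iff score > 0.5, else "assisted-side" class label."""
        neg = [c for c in self.classes_ if c != INDEPENDENT_CLASS][0]
        return np.where(self.score_samples(X) > 0.5, INDEPENDENT_CLASS, neg)


@dataclass
class TrainedMusclePairModel:
    """A fitted muscle-pair scorer plus its training bookkeeping."""

    muscle: str                  # e.g. "SOL"; the pair is {L SOL, R SOL}
    regime: str                  # "i" | "ii" | "iii"
    scorer: MusclePairScorer
    feature_columns: list[str]
    n_train: int
    train_cv_accuracy: float = float("nan")   # %

    @property
    def muscle_pair(self) -> tuple[str, str]:
        return (f"L {self.muscle}", f"R {self.muscle}")


def train_models(fm: FeatureMatrix, muscles: list[str], regime: str = "i",
                 n_neighbors: int = 5, standardize: bool = True,
                 weight_mode: str = "inverse_prior",
                 log_cv_accuracy: bool = True,
                 seed: int = 0) -> list[TrainedMusclePairModel]:
    """Fit one muscle-pair scorer per muscle on the given regime's classes.

    ``fm`` must be a classification-ready (log or normalized stage) matrix
    containing both regime classes; rows outside the two classes are
    ignored.  Each model's stratified 10-fold training CV accuracy is
    logged when class sizes allow it.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {list(REGIMES)}")
    neg, pos = REGIMES[regime]
    fm.require_stage("normalized", "log")
    models = []
    for m in muscles:
        sub = select_group(fm, MuscleGroup.pair(m))
        mask = sub.y.isin([neg, pos]).to_numpy()
        X = sub.df.to_numpy(dtype=float)[mask]
        y = sub.y.to_numpy()[mask]
        present = set(y)
        if not {neg, pos} <= present:
            raise ValueError(
                f"muscle pair {m}, regime {regime}: missing class "
                f"{sorted({neg, pos} - present)}")
        scorer = MusclePairScorer(n_neighbors=n_neighbors,
                                  standardize=standardize,
                                  weight_mode=weight_mode).fit(X, y)
        acc = float("nan")
        if log_cv_accuracy and np.unique(y, return_counts=True)[1].min() >= 10:
            from sklearn.model_selection import StratifiedKFold, cross_val_score
            cv = StratifiedKFold(10, shuffle=True, random_state=seed)
            acc = 100.0 * float(np.mean(cross_val_score(
                MusclePairScorer(n_neighbors=n_neighbors,
                                 standardize=standardize,
                                 weight_mode=weight_mode),
                X, y, cv=cv,
                scoring=lambda est, Xv, yv: np.mean(est.predict(Xv) == yv))))
        models.append(TrainedMusclePairModel(
            muscle=m, regime=regime, scorer=scorer,
            feature_columns=list(sub.df.columns), n_train=len(X),
            train_cv_accuracy=acc))
    return models


@dataclass
class RankedPrediction:
    """Per-muscle ranking scores with the 0.5 labeling rule and aggregates."""

    per_muscle_score: dict[str, float]
    per_muscle_label: dict[str, str] = field(init=False)
    aggregate_left: float = field(init=False)
    aggregate_right: float = field(init=False)
    aggregate_total: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.per_muscle_score:
            raise ValueError("no muscle scores")
        for k, s in self.per_muscle_score.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score for {k} outside [0, 1]: {s}")
        # boundary inclusive: a score of exactly 0.5 is labeled assisted
        self.per_muscle_label = {
            k: (INDEPENDENT_CLASS if s > 0.5 else "assisted")
            for k, s in self.per_muscle_score.items()}
        left = [s for k, s in self.per_muscle_score.items()
                if k.startswith("L ")]
        right = [s for k, s in self.per_muscle_score.items()
                 if k.startswith("R ")]
        allv = list(self.per_muscle_score.values())
        self.aggregate_left = float(np.mean(left)) if left else float("nan")
        self.aggregate_right = float(np.mean(right)) if right else float("nan")
        self.aggregate_total = float(np.mean(allv))

    def to_frame(self) -> pd.DataFrame:
        """Colormap-ready table of scores and labels."""
        return pd.DataFrame({
            "muscle": list(self.per_muscle_score),
            "score": list(self.per_muscle_score.values()),
            "label": [self.per_muscle_label[k] for k in self.per_muscle_score],
        })


def score_events(models: list[TrainedMusclePairModel],
                 fm_new: FeatureMatrix) -> pd.DataFrame:
    """Score every (event, channel) row of ``fm_new`` with its pair's model.

    ``fm_new`` must already be projected through the same fitted feature
    transform as the training matrix (frozen maxima/basis/epsilon).
    Returns a tidy frame (event_id, muscle, score).
    """
    by_muscle = {m.muscle: m for m in models}
    recs = []
    for (pid, eid, ch), row in fm_new.df.iterrows():
        muscle = ch.split()[-1]
        model = by_muscle.get(muscle)
        if model is None:
            continue
        if list(fm_new.df.columns) != model.feature_columns:
            raise ValueError("feature schema mismatch between new events and "
                             f"the {muscle} pair model")
        score = float(model.scorer.score_samples(row.to_numpy(dtype=float))[0])
        recs.append({"participant": pid, "event_id": eid, "muscle": ch,
                     "score": score})
    return pd.DataFrame(recs)


def label_and_aggregate(scores: dict[str, float]) -> RankedPrediction:
    """Apply the 0.5 labeling rule and compute L/R/total mean scores."""
    return RankedPrediction(per_muscle_score=dict(scores))


def rank_parameter_sets(models: list[TrainedMusclePairModel],
                        events_by_set: dict[str, FeatureMatrix]
                        ) -> list[tuple[str, RankedPrediction]]:
    """Rank stimulation parameter sets by mean independent-likeness.

    ``events_by_set`` maps a parameter-set identifier to the (projected)
    feature rows of its standing events.  Each set's per-muscle score is the
    mean over its events; sets are ordered by descending total aggregate
    (most independent-like first), ties kept in input order.
    """
    ranked = []
    for ps_id, fm in events_by_set.items():
        scored = score_events(models, fm)
        if scored.empty:
            warnings.warn(f"parameter set {ps_id!r}: no scorable events; skipped")
            continue
        per_muscle = scored.groupby("muscle")["score"].mean().to_dict()
        ranked.append((ps_id, label_and_aggregate(per_muscle)))
    ranked.sort(key=lambda t: -t[1].aggregate_total)
    return ranked
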