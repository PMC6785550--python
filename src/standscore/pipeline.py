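"""Feature assembly and the normalize -> NNMF -> log reduction pipeline.

Per (event, muscle) rows of named features are assembled into a
:class:`FeatureMatrix`, then passed through three stages in fixed order:

1. column-wise normalization to the feature maximum (removes units),
2. non-negative matrix factorization of the spectral feature block
   (dimensionality reduction; row coefficients become the reduced features),
3. logarithmic transform of the reduced values (variance stabilization).

Stage tags on the matrix enforce the order; applying a stage out of order
raises.  The transformers follow the scikit-learn estimator contract
(``fit`` / ``transform`` / ``get_params``) so the same fitted pipeline that
produced the training matrix can project new, unseen events (frozen column
maxima, frozen NNMF basis, frozen epsilon).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import NMF
from sklearn.utils.validation import check_is_fitted

from .io import CHANNEL_VOCAB, MUSCLES, SIDES

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix", "MuscleGroup", "MaxNormalizer", "NnmfReducer",
    "LogStabilizer", "StandingFeatureTransform", "assemble", "select_group",
    "TIME_FEATURES",
]

STAGES = ("raw", "normalized", "reduced", "log")
TIME_FEATURES = ("pattern_variability", "total_power")


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureMatrix:
    """Rows keyed by (participant, event_id, muscle); columns named features.

    ``stage`` records how far through the pipeline the values are; ``y``
    holds the per-row class label (assistance category).
    """

    df: pd.DataFrame            # MultiIndex (participant, event_id, muscle)
    y: pd.Series                # class label per row, aligned with df
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.df.index.equals(self.y.index):
            raise ValueError("labels not aligned with feature rows")
        if self.df.index.has_duplicates:
            raise ValueError("duplicate (participant, event, muscle) keys")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def muscles(self) -> list[str]:
        return sorted(set(self.df.index.get_level_values("muscle")))

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise ValueError(
                f"operation requires stage in {allowed}, matrix is at "
                f"{self.stage!r}; pipeline order is normalize -> NNMF -> log")

    def to_csv(self, path) -> None:
        """Tidy CSV: one (participant, event_id, muscle, feature, value) row,
        plus the row's class label."""
        tidy = (self.df.stack().rename("value").reset_index()
                .rename(columns={"level_3": "feature"}))
        lab = self.y.reset_index().rename(columns={self.y.name or 0: "label"})
        tidy = tidy.merge(lab, on=["participant", "event_id", "muscle"])
        tidy["stage"] = self.stage
        tidy.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        tidy = pd.read_csv(path)
        keys = ["participant", "event_id", "muscle"]
        wide = tidy.pivot_table(index=keys, columns="feature", values="value",
                                sort=False)
        wide.columns.name = None
        y = (tidy.drop_duplicates(keys).set_index(keys)["label"]
             .reindex(wide.index))
        stage = str(tidy["stage"].iloc[0]) if "stage" in tidy else "raw"
        return cls(df=wide, y=y.rename("label"), stage=stage)


@dataclass(frozen=True)
class MuscleGroup:
    """A named selection of side+muscle channel labels."""

    name: str
    members: tuple[str, ...]

    @classmethod
    def all(cls) -> "MuscleGroup":
        return cls("all", CHANNEL_VOCAB)

    @classmethod
    def all_except_il(cls) -> "MuscleGroup":
        return cls("all_except_IL",
                   tuple(c for c in CHANNEL_VOCAB if not c.endswith("IL")))

    @classmethod
    def extensors(cls) -> "MuscleGroup":
        ext = ("SOL", "MG", "VL", "RF", "GL")
        return cls("extensors",
                   tuple(f"{s} {m}" for m in ext for s in SIDES))

    @classmethod
    def flexors(cls) -> "MuscleGroup":
        return cls("flexors",
                   tuple(f"{s} {m}" for m in ("TA", "MH") for s in SIDES))

    @classmethod
    def pair(cls, muscle: str) -> "MuscleGroup":
        if muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {muscle!r}")
        return cls(f"pair:{muscle}", tuple(f"{s} {muscle}" for s in SIDES))


# ---------------------------------------------------------------------------
# assembly


def assemble(rows: dict[tuple[str, str, str], dict[str, float]],
             labels: dict[str, str]) -> FeatureMatrix:
    """Build a raw FeatureMatrix from per-(participant, event, muscle) dicts.

    ``labels`` maps event_id to class label.  Rows with any missing (NaN)
    feature are excluded with a logged count, mirroring how recordings with
    technical faults drop out of a real analysis.
    """
    if not rows:
        raise ValueError("no feature rows to assemble")
    index = pd.MultiIndex.from_tuples(list(rows),
                                      names=["participant", "event_id", "muscle"])
    df = pd.DataFrame(list(rows.values()), index=index)
    n0 = len(df)
    df = df.dropna(axis=0, how="any")
    if len(df) < n0:
        logger.info("assemble: excluded %d incomplete rows", n0 - len(df))
    y = pd.Series([labels[e] for e in df.index.get_level_values("event_id")],
                  index=df.index, name="label")
    fm = FeatureMatrix(df=df, y=y, stage="raw",
                       meta={"n_excluded": n0 - len(df)})
    return fm


def select_group(fm: FeatureMatrix, group: MuscleGroup) -> FeatureMatrix:
    """Restrict rows to the muscles of ``group``."""
    mask = fm.df.index.get_level_values("muscle").isin(group.members)
    if not mask.any():
        raise ValueError(f"group {group.name!r} selects no rows")
    return FeatureMatrix(df=fm.df[mask], y=fm.y[mask], stage=fm.stage,
                         meta={**fm.meta, "group": group.name})


def participant_power_norm(fm: FeatureMatrix,
                           column: str = "total_power") -> FeatureMatrix:
    """Normalize the power column by each (participant, muscle) maximum.

    This is the within-participant normalization applied to total power
    before the global per-feature normalization of the pipeline.
    """
    fm.require_stage("raw")
    if column not in fm.df.columns:
        raise ValueError(f"no column {column!r}")
    df = fm.df.copy()
    grp = df.groupby(level=["participant", "muscle"])[column]
    gmax = grp.transform("max")
    if (gmax <= 0).any():
        bad = df.index[gmax <= 0][:3].tolist()
        raise ValueError(f"zero maximum power for groups containing {bad}")
    df[column] = df[column] / gmax
    return FeatureMatrix(df=df, y=fm.y, stage="raw",
                         meta={**fm.meta, "participant_power_norm": True})


# ---------------------------------------------------------------------------
# sklearn-style stage transformers


class MaxNormalizer(TransformerMixin, BaseEstimator):
    """Column-wise division by the training maximum.

    Fitted attribute ``max_`` holds the per-column maxima; a zero-max column
    raises with the column named.
    """

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        self.max_ = X.max(axis=0).to_numpy(dtype=float)
        zero = [c for c, m in zip(self.columns_, self.max_) if m <= 0]
        if zero:
            raise ValueError(f"zero-maximum feature column(s): {zero}")
        return self

    def transform(self, X):
        check_is_fitted(self, "max_")
        return np.asarray(X, dtype=float) / self.max_


class NnmfReducer(TransformerMixin, BaseEstimator):
    """Non-negative matrix factorization keeping the best of several restarts.

    Factorizes X ~ W H with the multiplicative-update solver; the row
    coefficients W are the reduced features, ``components_`` the frozen
    basis H used to project new rows.  ``rank`` is clipped to the number of
    input features.
    """

    def __init__(self, rank: int = 5, n_restarts: int = 10,
                 max_iter: int = 1000, tol: float = 1e-6,
                 random_state: int = 0):
        self.rank = rank
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("NNMF input must be non-negative")
        rank = min(self.rank, X.shape[1])
        rng = np.random.SeedSequence(self.random_state)
        best = None
        import warnings as _warnings
        from sklearn.exceptions import ConvergenceWarning
        for child in rng.spawn(self.n_restarts):
            seed = int(child.generate_state(1)[0] % (2**31))
            nmf = NMF(n_components=rank, init="random", solver="mu",
                      max_iter=self.max_iter, random_state=seed, tol=self.tol)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", ConvergenceWarning)
                W = nmf.fit_transform(X)
            if best is None or nmf.reconstruction_err_ < best[0]:
                best = (nmf.reconstruction_err_, nmf, W)
        self.reconstruction_err_, self.nmf_, self._fit_W = best
        self.components_ = self.nmf_.components_
        self.rank_ = rank
        return self

    def transform(self, X):
        check_is_fitted(self, "nmf_")
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("NNMF input must be non-negative")
        return self.nmf_.transform(X)

    def fit_transform(self, X, y=None, **kw):
        self.fit(X)
        return self._fit_W


class LogStabilizer(TransformerMixin, BaseEstimator):
    """log(x + epsilon) with epsilon = ``epsilon_rel`` x training column max.

    The offset guards the exact zeros that NNMF coefficients can contain.
    """

    def __init__(self, epsilon_rel: float = 1e-6):
        self.epsilon_rel = epsilon_rel

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        colmax = X.max(axis=0)
        self.epsilon_ = self.epsilon_rel * np.where(colmax > 0, colmax, 1.0)
        return self

    def transform(self, X):
        check_is_fitted(self, "epsilon_")
        return np.log(np.asarray(X, dtype=float) + self.epsilon_)


# ---------------------------------------------------------------------------
# end-to-end feature transform


class StandingFeatureTransform(TransformerMixin, BaseEstimator):
    """Normalize -> NNMF -> log over a FeatureMatrix, sklearn-style.

    The spectral feature block is reduced by NNMF and log-transformed; the
    time-domain features (already unit-free after normalization) are
    concatenated after reduction.  ``reduce_block`` selects which columns
    the factorization sees: "spectral" (default), "all", or None to skip
    reduction entirely (used for the time-only feature set).
    All fitted statistics are frozen at ``fit`` so unseen events are
    projected with the training-stage transforms.
    """

    def __init__(self, rank: int = 5, reduce_block: str | None = "spectral",
                 epsilon_rel: float = 1e-6, n_restarts: int = 10,
                 random_state: int = 0):
        self.rank = rank
        self.reduce_block = reduce_block
        self.epsilon_rel = epsilon_rel
        self.n_restarts = n_restarts
        self.random_state = random_state

    @staticmethod
    def _split_columns(columns) -> tuple[list, list]:
        time_cols = [c for c in columns if c in TIME_FEATURES]
        spec_cols = [c for c in columns if c not in TIME_FEATURES]
        return spec_cols, time_cols

    def fit(self, fm: FeatureMatrix, y=None):
        fm.require_stage("raw", "normalized")
        df = fm.df
        self.feature_names_in_ = list(df.columns)
        self.normalizer_ = MaxNormalizer().fit(df)
        Xn = self.normalizer_.transform(df)
        spec_cols, time_cols = self._split_columns(df.columns)
        self.spec_cols_, self.time_cols_ = spec_cols, time_cols
        if self.reduce_block is None or not spec_cols:
            self.reducer_ = None
            self.log_ = None
            return self
        cols = spec_cols if self.reduce_block == "spectral" else list(df.columns)
        self.reduce_cols_ = cols
        idx = [list(df.columns).index(c) for c in cols]
        self.reduce_idx_ = idx
        self.reducer_ = NnmfReducer(rank=self.rank, n_restarts=self.n_restarts,
                                    random_state=self.random_state)
        W = self.reducer_.fit_transform(Xn[:, idx])
        self.log_ = LogStabilizer(self.epsilon_rel).fit(W)
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        check_is_fitted(self, "normalizer_")
        fm.require_stage("raw", "normalized")
        df = fm.df
        if list(df.columns) != self.feature_names_in_:
            raise ValueError("feature schema mismatch with fitted transform")
        Xn = self.normalizer_.transform(df)
        if self.reducer_ is None:
            out = pd.DataFrame(Xn, index=df.index, columns=df.columns)
            stage = "normalized"
        else:
            W = self.reducer_.transform(Xn[:, self.reduce_idx_])
            L = self.log_.transform(W)
            parts = [pd.DataFrame(
                L, index=df.index,
                columns=[f"nnmf{j+1}" for j in range(L.shape[1])])]
            if self.reduce_block == "spectral" and self.time_cols_:
                tidx = [list(df.columns).index(c) for c in self.time_cols_]
                parts.append(pd.DataFrame(Xn[:, tidx], index=df.index,
                                          columns=self.time_cols_))
            out = pd.concat(parts, axis=1)
            stage = "log"
        return FeatureMatrix(df=out, y=fm.y, stage=stage,
                             meta={**fm.meta, "rank": getattr(self, "rank", None),
                                   "reduce_block": self.reduce_block})

    def fit_transform(self, fm: FeatureMatrix, y=None, **kw) -> FeatureMatrix:
        return self.fit(fm).transform(fm)
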