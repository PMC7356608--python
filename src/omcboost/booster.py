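"""Seed-deterministic gradient-boosted regression trees (XGBoost backend).

The shipped configuration is deliberately conservative for small
pharmacogenomics training sets: a low learning rate (0.05) compensated by many
trees (700), depth-6 trees, and 0.8 row/column subsampling per boosting
iteration without replacement. No per-case hyperparameter search is performed
— with hundreds of cases it would be impractical and would invite selection
bias — so the same configuration serves every case and both the selected-k and
all-features models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import xgboost as xgb
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._seeds import derive_seeds

__all__ = [
    "BoosterConfig",
    "DEFAULT_CONFIG",
    "FittedBooster",
    "train",
    "predict_ensemble",
    "is_constant_prediction",
    "XGBEnsembleRegressor",
]

#: Variance below this (log10 IC50 units squared) marks a constant prediction.
CONSTANT_PREDICTION_TOL = 1e-8


@dataclass(frozen=True)
class BoosterConfig:
    """Fixed learner configuration; all other XGBoost settings stay at defaults."""

    learning_rate: float = 0.05
    n_trees: int = 700
    max_depth: int = 6
    row_subsample: float = 0.8
    column_subsample: float = 0.8
    seed: int = 0
    aggregate: str = "mean"  # how multi-seed ensembles combine predictions

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError(f"learning_rate must be in (0, 1], got {self.learning_rate}")
        for name in ("row_subsample", "column_subsample"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.aggregate not in ("mean", "median"):
            raise ValueError(f"aggregate must be 'mean' or 'median', got {self.aggregate!r}")

    def with_seed(self, seed: int) -> "BoosterConfig":
        return replace(self, seed=int(seed))

    def xgb_params(self) -> dict:
        return {
            "eta": self.learning_rate,
            "max_depth": self.max_depth,
            "subsample": self.row_subsample,
            "colsample_bytree": self.column_subsample,
            "seed": int(self.seed),
            "nthread": 1,
            "verbosity": 0,
            "objective": "reg:squarederror",
        }


DEFAULT_CONFIG = BoosterConfig()

#: Reduced-tree configuration used throughout the test suite for speed; the
#: shipped default remains the 700-tree configuration above.
FAST_CONFIG = BoosterConfig(n_trees=50)


@dataclass
class FittedBooster:
    """A trained booster bound to its training feature names.

    Prediction addresses columns by name: a matrix whose columns are a
    permutation of the training columns is reordered before prediction, so
    results are invariant to column order.
    """

    booster: xgb.Booster
    feature_names: list[str]
    config: BoosterConfig

    def predict(self, X, feature_names: Sequence[str] | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if feature_names is not None:
            feature_names = [str(f) for f in feature_names]
            if sorted(feature_names) != sorted(self.feature_names):
                raise ValueError(
                    "feature-name mismatch: model was trained on "
                    f"{sorted(self.feature_names)[:5]}..., got {sorted(feature_names)[:5]}..."
                )
            if feature_names != self.feature_names:
                reorder = [feature_names.index(f) for f in self.feature_names]
                X = X[:, reorder]
        elif X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {len(self.feature_names)}"
            )
        dmat = xgb.DMatrix(X, feature_names=self.feature_names, nthread=1)
        return self.booster.predict(dmat)


def train(X, y, config: BoosterConfig = DEFAULT_CONFIG, feature_names=None) -> FittedBooster:
    """Train one gradient-boosted regressor; deterministic given (X, y, config)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X {X.shape} and y {y.shape} are inconsistent")
    if X.shape[0] < 2:
        raise ValueError("training requires at least 2 instances")
    if X.shape[1] < 1:
        raise ValueError("empty feature set")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    feature_names = [str(f) for f in feature_names]
    dtrain = xgb.DMatrix(X, label=y, feature_names=feature_names, nthread=1)
    booster = xgb.train(config.xgb_params(), dtrain, num_boost_round=config.n_trees)
    return FittedBooster(booster=booster, feature_names=feature_names, config=config)


def predict_ensemble(
    models: Sequence[FittedBooster],
    X,
    feature_names: Sequence[str] | None = None,
    aggregate: str = "mean",
) -> np.ndarray:
    """Combine per-seed predictions instance-wise (arithmetic mean by default)."""
    if len(models) == 0:
        raise ValueError("predict_ensemble requires at least one model")
    preds = np.stack([m.predict(X, feature_names=feature_names) for m in models])
    if aggregate == "mean":
        return preds.mean(axis=0)
    if aggregate == "median":
        return np.median(preds, axis=0)
    raise ValueError(f"unknown aggregate {aggregate!r}")


def is_constant_prediction(pred, tol: float = CONSTANT_PREDICTION_TOL) -> bool:
    """Whether a prediction vector is constant (sample variance < tol).

    Constant predictors carry no ranking information and are rejected during
    complexity selection regardless of any correlation bookkeeping.
    """
    pred = np.asarray(pred, dtype=float)
    if pred.size < 2:
        raise ValueError("is_constant_prediction requires at least 2 values")
    return bool(np.var(pred, ddof=1) < tol)


class XGBEnsembleRegressor(RegressorMixin, BaseEstimator):
    """Multi-seed gradient-boosted tree ensemble with the conservative defaults.

    Trains ``n_seeds`` boosters differing only in their random seed and
    predicts the per-instance mean (or median) of their outputs, smoothing the
    seed-to-seed variability that subsampled boosting exhibits on small
    training sets.

    Parameters follow :class:`BoosterConfig`; ``random_state`` seeds the
    deterministic derivation of the per-member seeds.
    """

    def __init__(
        self,
        learning_rate: float = 0.05,
        n_trees: int = 700,
        max_depth: int = 6,
        row_subsample: float = 0.8,
        column_subsample: float = 0.8,
        n_seeds: int = 10,
        aggregate: str = "mean",
        random_state: int = 0,
    ):
        self.learning_rate = learning_rate
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.row_subsample = row_subsample
        self.column_subsample = column_subsample
        self.n_seeds = n_seeds
        self.aggregate = aggregate
        self.random_state = random_state

    def _config(self) -> BoosterConfig:
        return BoosterConfig(
            learning_rate=self.learning_rate,
            n_trees=self.n_trees,
            max_depth=self.max_depth,
            row_subsample=self.row_subsample,
            column_subsample=self.column_subsample,
            aggregate=self.aggregate,
        )

    def fit(self, X, y, feature_names=None):
        X, y = check_X_y(X, y, y_numeric=True)
        config = self._config()
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(X.shape[1])]
        seeds = derive_seeds(self.random_state, "final_omc", self.n_seeds)
        self.feature_names_ = [str(f) for f in feature_names]
        self.seeds_ = seeds
        self.models_ = [
            train(X, y, config.with_seed(s), feature_names=self.feature_names_) for s in seeds
        ]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "models_")
        X = check_array(X)
        return predict_ensemble(self.models_, X, aggregate=self.aggregate)
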