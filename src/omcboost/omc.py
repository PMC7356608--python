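"""Optimal-model-complexity search and the per-case pipeline.

For a case with n training cell lines, every candidate complexity k in
2..floor(n/2) (at least two training instances per feature) is scored by
rank-stratified five-fold cross-validation: within each fold the features are
ranked on the four non-validation folds only, the top k are used to train a
booster, and the Spearman correlation on the validation fold is recorded. A
complexity *passes* only if every fold exceeds Rs 0.25 and no fold's model
predicts a constant; among passing complexities the one with the highest
median fold Rs wins (ties to the smaller k, for conciseness). The selected
k_opt is then re-ranked on the entire training set and a 10-seed booster
ensemble is evaluated once on the held-out 10-cell-line test set, alongside an
all-features baseline on the identical split.

Because top-k subsets are nested, the per-fold ranking is computed once per
fold and reused for every k — mathematically identical to re-ranking per k.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._seeds import derive_seed, derive_seeds
from .booster import (
    DEFAULT_CONFIG,
    BoosterConfig,
    FittedBooster,
    is_constant_prediction,
    predict_ensemble,
    train,
)
from .dataset import CaseDataset
from .metrics import UndefinedCorrelationError, r_squared, spearman_rs
from .ranking import FeatureRanking, rank_features
from .stratify import FoldAssignment, TrainTestSplit, make_cv_folds, make_test_split

__all__ = [
    "RS_THRESHOLD",
    "ComplexityProfile",
    "OMCSelection",
    "ModelEvaluation",
    "CaseResult",
    "OMCRegressor",
    "evaluate_complexity",
    "select_omc",
    "run_case",
]

#: Minimum Spearman correlation every validation fold (and, for the
#: "predictive" label, the test set) must strictly exceed.
RS_THRESHOLD = 0.25


@dataclass
class ComplexityProfile:
    """Cross-validation outcome for one candidate complexity k."""

    k: int
    fold_rs: list[float]  # NaN where the correlation is undefined
    constant_flagged: list[bool]
    median_rs: float
    passes: bool

    @classmethod
    def from_folds(cls, k: int, fold_rs, constant_flagged, rs_min: float = RS_THRESHOLD):
        fold_rs = [float(r) for r in fold_rs]
        constant_flagged = [bool(c) for c in constant_flagged]
        finite = np.isfinite(fold_rs).all()
        passes = (
            finite
            and not any(constant_flagged)
            and min(fold_rs) > rs_min  # strict: exactly rs_min fails
        )
        return cls(
            k=k,
            fold_rs=fold_rs,
            constant_flagged=constant_flagged,
            median_rs=float(np.median(fold_rs)),
            passes=bool(passes),
        )


@dataclass
class OMCSelection:
    """The chosen complexity and its feature subset (empty when nothing passes)."""

    k_opt: int | None
    selected_features: list[str]
    profiles: list[ComplexityProfile]


@dataclass
class ModelEvaluation:
    """Test-set performance of one final model.

    ``rs`` is None when the model predicted a constant (the rank correlation
    is then undefined; such a model never counts as predictive).
    """

    rs: float | None
    r2: float | None
    predictions: list[float]
    constant_prediction: bool


def _evaluate_predictions(pred: np.ndarray, obs: np.ndarray) -> ModelEvaluation:
    constant = is_constant_prediction(pred)
    try:
        rs = None if constant else spearman_rs(pred, obs)
    except UndefinedCorrelationError:
        rs = None
    try:
        r2 = r_squared(pred, obs)
    except ValueError:
        r2 = None
    return ModelEvaluation(
        rs=rs, r2=r2, predictions=[float(v) for v in pred], constant_prediction=constant
    )


def _fold_rankings(
    X: np.ndarray,
    y: np.ndarray,
    cell_ids,
    folds: FoldAssignment,
    kind: str,
    feature_names,
) -> dict[int, FeatureRanking]:
    """Feature rankings computed on the non-validation rows of each fold."""
    rankings = {}
    for fold in range(1, folds.n_folds + 1):
        train_rows = np.nonzero(folds.fold_of != fold)[0]
        rankings[fold] = rank_features(
            X[train_rows], y[train_rows], kind, feature_names=feature_names
        )
    return rankings


def _fold_rs_for_k(
    k: int,
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    rankings: dict[int, FeatureRanking],
    name_to_col: dict[str, int],
    config: BoosterConfig,
    fold_seeds: list[int],
) -> tuple[list[float], list[bool]]:
    fold_rs, flags = [], []
    for fold in range(1, folds.n_folds + 1):
        val_rows = folds.fold_indices(fold)
        train_rows = np.nonzero(folds.fold_of != fold)[0]
        top = rankings[fold].top_k(k)
        cols = [name_to_col[f] for f in top]
        model = train(
            X[np.ix_(train_rows, cols)],
            y[train_rows],
            config.with_seed(fold_seeds[fold - 1]),
            feature_names=top,
        )
        pred = model.predict(X[np.ix_(val_rows, cols)])
        flag = is_constant_prediction(pred)
        try:
            rs = float("nan") if flag else spearman_rs(pred, y[val_rows])
        except UndefinedCorrelationError:
            rs = float("nan")
        fold_rs.append(rs)
        flags.append(flag)
    return fold_rs, flags


def evaluate_complexity(
    k: int,
    dataset: CaseDataset,
    folds: FoldAssignment,
    config: BoosterConfig = DEFAULT_CONFIG,
    rs_min: float = RS_THRESHOLD,
    rankings: dict[int, FeatureRanking] | None = None,
    fold_seeds: list[int] | None = None,
) -> ComplexityProfile:
    """Score one complexity k by stratified cross-validation on training rows.

    ``dataset`` must already be restricted to the training rows. Per-fold
    rankings may be supplied to amortize their cost over the whole k-grid.
    """
    n = dataset.m
    if not 2 <= k <= n // 2:
        raise ValueError(f"k={k} outside the complexity grid [2, {n // 2}]")
    kind = dataset.omics.ranking_kind
    if rankings is None:
        rankings = _fold_rankings(
            dataset.X, dataset.y, dataset.cell_ids, folds, kind, dataset.feature_names
        )
    if fold_seeds is None:
        fold_seeds = [config.seed] * folds.n_folds
    name_to_col = {f: j for j, f in enumerate(dataset.feature_names)}
    fold_rs, flags = _fold_rs_for_k(
        k, dataset.X, dataset.y, folds, rankings, name_to_col, config, fold_seeds
    )
    return ComplexityProfile.from_folds(k, fold_rs, flags, rs_min=rs_min)


def select_omc(profiles: list[ComplexityProfile]) -> int | None:
    """Pick k_opt: the passing profile with the highest median fold Rs.

    Ties go to the smallest k (the most concise model); None when no
    complexity passes, in which case the case is not potentially predictive.
    """
    if not profiles:
        raise ValueError("select_omc requires a non-empty profile list")
    passing = [p for p in profiles if p.passes]
    if not passing:
        return None
    best = max(passing, key=lambda p: (p.median_rs, -p.k))
    return best.k


class OMCRegressor(RegressorMixin, BaseEstimator):
    """Drug-response regressor with built-in optimal-complexity feature selection.

    ``fit`` runs the full complexity search on the supplied (training) data:
    rank-stratified fold assignment, per-fold univariate ranking, nested top-k
    evaluation over k = 2..floor(n/2), selection of k_opt, and — when a
    complexity passes — training of the final multi-seed ensemble on the
    top-k_opt features ranked on the entire training set. ``predict`` averages
    the ensemble members.

    Parameters
    ----------
    kind : {"continuous", "binary"}
        Univariate test family: Spearman correlation test for continuous
        features, Wilcoxon rank-sum for binary ones.
    rs_min : float
        Per-fold Spearman threshold a complexity must strictly exceed.
    learning_rate, n_trees, max_depth, row_subsample, column_subsample :
        Booster configuration (see :class:`~omcboost.booster.BoosterConfig`).
    n_seeds : int
        Ensemble size of the final model.
    aggregate : {"mean", "median"}
        How ensemble members' predictions are combined.
    random_state : int
        Master seed; fold assignment, per-fold booster seeds and final
        ensemble seeds are all derived from it deterministically.

    Attributes
    ----------
    k_opt_ : int or None
        Selected complexity; None when no complexity passed the fold gate.
    selected_features_ : list of str
        The top-k_opt features ranked on the entire training set.
    profiles_ : list of ComplexityProfile
        Fold performances for every candidate k.
    ranking_ : FeatureRanking
        Univariate ranking on the entire training set.
    models_ : list of FittedBooster
        The final ensemble (empty when k_opt_ is None).
    """

    def __init__(
        self,
        kind: str = "continuous",
        rs_min: float = RS_THRESHOLD,
        learning_rate: float = 0.05,
        n_trees: int = 700,
        max_depth: int = 6,
        row_subsample: float = 0.8,
        column_subsample: float = 0.8,
        n_folds: int = 5,
        n_seeds: int = 10,
        aggregate: str = "mean",
        random_state: int = 0,
    ):
        self.kind = kind
        self.rs_min = rs_min
        self.learning_rate = learning_rate
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.row_subsample = row_subsample
        self.column_subsample = column_subsample
        self.n_folds = n_folds
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

    def fit(self, X, y, feature_names=None, cell_ids=None):
        X, y = check_X_y(X, y, y_numeric=True)
        n = X.shape[0]
        k_max = n // 2
        if k_max < 2:
            raise ValueError(f"training set of {n} instances is too small (k grid empty)")
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(X.shape[1])]
        feature_names = [str(f) for f in feature_names]
        if k_max > X.shape[1]:
            k_max = X.shape[1]
        config = self._config()

        folds_seed = derive_seed(self.random_state, "folds")
        folds = make_cv_folds(y, cell_ids, folds_seed, n_folds=self.n_folds)
        fold_seeds = derive_seeds(self.random_state, "cv_booster", self.n_folds)
        rankings = _fold_rankings(X, y, cell_ids, folds, self.kind, feature_names)
        name_to_col = {f: j for j, f in enumerate(feature_names)}

        profiles = []
        for k in range(2, k_max + 1):
            fold_rs, flags = _fold_rs_for_k(
                k, X, y, folds, rankings, name_to_col, config, fold_seeds
            )
            profiles.append(ComplexityProfile.from_folds(k, fold_rs, flags, rs_min=self.rs_min))

        k_opt = select_omc(profiles)
        ranking = rank_features(X, y, self.kind, feature_names=feature_names)

        self.n_features_in_ = X.shape[1]
        self.feature_names_ = feature_names
        self.folds_ = folds
        self.fold_seeds_ = fold_seeds
        self.profiles_ = profiles
        self.ranking_ = ranking
        self.k_opt_ = k_opt
        if k_opt is None:
            self.selected_features_ = []
            self.selected_idx_ = np.array([], dtype=int)
            self.models_ = []
            self.final_seeds_ = []
            return self
        selected = ranking.top_k(k_opt)
        self.selected_features_ = selected
        self.selected_idx_ = np.array([name_to_col[f] for f in selected], dtype=int)
        self.final_seeds_ = derive_seeds(self.random_state, "final_omc", self.n_seeds)
        self.models_ = [
            train(X[:, self.selected_idx_], y, config.with_seed(s), feature_names=selected)
            for s in self.final_seeds_
        ]
        return self

    @property
    def selection_(self) -> OMCSelection:
        check_is_fitted(self, "profiles_")
        return OMCSelection(
            k_opt=self.k_opt_,
            selected_features=list(self.selected_features_),
            profiles=list(self.profiles_),
        )

    def predict(self, X):
        check_is_fitted(self, "models_")
        if self.k_opt_ is None:
            raise ValueError(
                "no complexity passed the validation-fold gate; "
                "this case is not potentially predictive and has no final model"
            )
        X = check_array(X)
        if X.shape[1] == self.n_features_in_:
            X = X[:, self.selected_idx_]
        elif X.shape[1] != self.k_opt_:
            raise ValueError(
                f"X has {X.shape[1]} columns; expected {self.n_features_in_} "
                f"(full matrix) or {self.k_opt_} (selected features)"
            )
        return predict_ensemble(self.models_, X, aggregate=self.aggregate)


@dataclass
class CaseResult:
    """Complete record of one case run: split, search, final evaluations."""

    drug: str
    cancer_type: str
    omics: str
    m: int
    p: int
    master_seed: int
    config: dict
    train_cell_ids: list[str]
    test_cell_ids: list[str]
    fold_of: dict[str, int]
    ranking: list[list]  # [feature, p_value, effect] on the entire training set
    profiles: list[ComplexityProfile]
    k_opt: int | None
    selected_features: list[str]
    omc_evaluation: ModelEvaluation | None
    all_features_evaluation: ModelEvaluation | None
    classification: str
    seeds: dict
    manifest: dict | None = None
    schema_version: int = 1

    def to_dict(self) -> dict:
        doc = asdict(self)
        return _sanitize(doc)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=indent, allow_nan=False)

    @classmethod
    def from_dict(cls, doc: dict) -> "CaseResult":
        doc = dict(doc)
        doc["profiles"] = [
            ComplexityProfile(
                k=p["k"],
                fold_rs=[float("nan") if r is None else r for r in p["fold_rs"]],
                constant_flagged=p["constant_flagged"],
                median_rs=float("nan") if p["median_rs"] is None else p["median_rs"],
                passes=p["passes"],
            )
            for p in doc["profiles"]
        ]
        for key in ("omc_evaluation", "all_features_evaluation"):
            if doc.get(key) is not None:
                doc[key] = ModelEvaluation(**doc[key])
        return cls(**doc)


def _sanitize(obj):
    """Make a document JSON-serializable: NaN -> None, numpy scalars -> python."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_case(
    dataset: CaseDataset,
    master_seed: int,
    config: BoosterConfig = DEFAULT_CONFIG,
    rs_min: float = RS_THRESHOLD,
    n_folds: int = 5,
    n_seeds: int = 10,
    include_all_features: bool = True,
) -> CaseResult:
    """Run the full pipeline on one case.

    Test split -> fold assignment -> per-k evaluation -> k_opt selection ->
    (when a complexity passes) final multi-seed ensemble on the top-k_opt
    features, evaluated on the 10-cell-line test set -> the all-features
    baseline ensemble on the identical split. Entirely deterministic given
    (dataset, master_seed, config).
    """
    if not dataset.is_eligible:
        raise ValueError(
            f"case {dataset.case_id} has m={dataset.m} < 45 cell lines and is ineligible"
        )
    from .validation import classify_parts  # local import avoids a module cycle

    split = make_test_split(
        dataset.y, dataset.cell_ids, seed=derive_seed(master_seed, "split")
    )
    train_ds = dataset.subset(split.train_idx)
    test_ds = dataset.subset(split.test_idx)

    est = OMCRegressor(
        kind=dataset.omics.ranking_kind,
        rs_min=rs_min,
        learning_rate=config.learning_rate,
        n_trees=config.n_trees,
        max_depth=config.max_depth,
        row_subsample=config.row_subsample,
        column_subsample=config.column_subsample,
        n_folds=n_folds,
        n_seeds=n_seeds,
        aggregate=config.aggregate,
        random_state=master_seed,
    )
    est.fit(train_ds.X, train_ds.y, feature_names=train_ds.feature_names,
            cell_ids=train_ds.cell_ids)

    omc_eval = None
    if est.k_opt_ is not None:
        pred = est.predict(test_ds.X)
        omc_eval = _evaluate_predictions(pred, test_ds.y)

    all_eval = None
    all_seeds: list[int] = []
    if include_all_features:
        all_seeds = derive_seeds(master_seed, "final_all", n_seeds)
        all_models = [
            train(train_ds.X, train_ds.y, config.with_seed(s),
                  feature_names=train_ds.feature_names)
            for s in all_seeds
        ]
        all_pred = predict_ensemble(all_models, test_ds.X, aggregate=config.aggregate)
        all_eval = _evaluate_predictions(all_pred, test_ds.y)

    classification = classify_parts(est.k_opt_, omc_eval, rs_min=rs_min)

    return CaseResult(
        drug=dataset.drug,
        cancer_type=dataset.cancer_type,
        omics=dataset.omics.value,
        m=dataset.m,
        p=dataset.p,
        master_seed=master_seed,
        config=asdict(config),
        train_cell_ids=list(train_ds.cell_ids),
        test_cell_ids=list(test_ds.cell_ids),
        fold_of={cid: int(f) for cid, f in zip(train_ds.cell_ids, est.folds_.fold_of)},
        ranking=[
            [f, float(p), float(e)]
            for f, p, e in zip(est.ranking_.feature_names, est.ranking_.p_values,
                               est.ranking_.effects)
        ],
        profiles=est.profiles_,
        k_opt=est.k_opt_,
        selected_features=list(est.selected_features_),
        omc_evaluation=omc_eval,
        all_features_evaluation=all_eval,
        classification=classification,
        seeds={
            "master": int(master_seed),
            "split": int(split.seed),
            "folds": int(est.folds_.seed),
            "cv_booster": [int(s) for s in est.fold_seeds_],
            "final_omc": [int(s) for s in est.final_seeds_],
            "final_all": [int(s) for s in all_seeds],
        },
    )
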