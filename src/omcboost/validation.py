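"""Predictive classification, y-randomization, and complementarity summaries.

A case is *potentially predictive* when some complexity clears the per-fold
Spearman gate, and *predictive* when the final model additionally exceeds the
same threshold on the held-out test set. The y-randomization control refits
the selected feature subset after shuffling the responses: a genuinely
informative subset should beat its shuffled counterpart decisively.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seeds import derive_seed
from .booster import BoosterConfig, DEFAULT_CONFIG, is_constant_prediction, train
from .dataset import CaseDataset
from .metrics import UndefinedCorrelationError, spearman_rs
from .omc import RS_THRESHOLD, CaseResult, ModelEvaluation
from .stratify import make_cv_folds

__all__ = [
    "PredictiveClass",
    "YRandomizationResult",
    "classify",
    "classify_parts",
    "y_randomize",
    "complementarity",
]


class PredictiveClass(str, enum.Enum):
    NOT_POTENTIALLY_PREDICTIVE = "not_potentially_predictive"
    POTENTIALLY_PREDICTIVE = "potentially_predictive"
    PREDICTIVE = "predictive"


def classify_parts(
    k_opt: int | None,
    omc_evaluation: ModelEvaluation | None,
    rs_min: float = RS_THRESHOLD,
) -> str:
    """Two-gate classification from the selection outcome and test evaluation."""
    if k_opt is None:
        return PredictiveClass.NOT_POTENTIALLY_PREDICTIVE.value
    rs = None if omc_evaluation is None else omc_evaluation.rs
    if rs is not None and rs > rs_min:
        return PredictiveClass.PREDICTIVE.value
    return PredictiveClass.POTENTIALLY_PREDICTIVE.value


def classify(result: CaseResult, rs_min: float = RS_THRESHOLD) -> PredictiveClass:
    """Classify a completed case result."""
    return PredictiveClass(classify_parts(result.k_opt, result.omc_evaluation, rs_min))


@dataclass
class YRandomizationResult:
    """Cross-validated performance with real vs shuffled responses."""

    real_rs: list[float]
    permuted_rs: list[float]
    t_p: float


def _cv_mean_rs(
    X: np.ndarray,
    y: np.ndarray,
    cell_ids,
    config: BoosterConfig,
    fold_seed: int,
    booster_seed: int,
    n_folds: int,
) -> float:
    """Mean validation-fold Spearman over one stratified CV run.

    Folds with an undefined correlation (constant predictions or constant
    observed responses) contribute 0 — no correlation information.
    """
    folds = make_cv_folds(y, cell_ids, fold_seed, n_folds=n_folds)
    fold_rs = []
    for fold in range(1, n_folds + 1):
        val = folds.fold_indices(fold)
        tr = np.nonzero(folds.fold_of != fold)[0]
        model = train(X[tr], y[tr], config.with_seed(booster_seed + fold))
        pred = model.predict(X[val])
        try:
            rs = 0.0 if is_constant_prediction(pred) else spearman_rs(pred, y[val])
        except UndefinedCorrelationError:
            rs = 0.0
        fold_rs.append(rs)
    return float(np.mean(fold_rs))


def y_randomize(
    dataset: CaseDataset,
    features: list[str],
    runs: int = 10,
    config: BoosterConfig = DEFAULT_CONFIG,
    seed: int = 0,
    n_folds: int = 5,
    shuffler=None,
) -> YRandomizationResult:
    """Compare cross-validated performance on real vs label-shuffled responses.

    Uses the full case dataset (training and test rows merged) restricted to
    the given feature subset. For each of ``runs`` runs, a fresh rank-
    stratified five-fold CV on the real labels records the mean validation
    Spearman; a matching run on freshly shuffled labels (stratified on the
    shuffled values' ranks) does the same. A two-sided paired t-test compares
    the two lists.

    ``shuffler`` (testing hook) replaces the permutation: a callable
    ``(rng, y) -> y_shuffled``.
    """
    if not features:
        raise ValueError("y_randomize requires a non-empty feature list")
    name_to_col = {f: j for j, f in enumerate(dataset.feature_names)}
    missing = [f for f in features if f not in name_to_col]
    if missing:
        raise ValueError(f"features not in dataset: {missing}")
    cols = [name_to_col[f] for f in features]
    X = dataset.X[:, cols]
    y = dataset.y
    if shuffler is None:
        shuffler = lambda rng, yy: rng.permutation(yy)

    real_rs, permuted_rs = [], []
    for run in range(runs):
        run_seed = derive_seed(seed, "y_randomization", run)
        rng = np.random.default_rng(run_seed)
        real_rs.append(
            _cv_mean_rs(X, y, dataset.cell_ids, config, run_seed, run_seed, n_folds)
        )
        y_perm = shuffler(rng, y)
        permuted_rs.append(
            _cv_mean_rs(X, y_perm, dataset.cell_ids, config, run_seed + 1, run_seed + 1, n_folds)
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        t_p = stats.ttest_rel(real_rs, permuted_rs).pvalue
    t_p = 1.0 if not np.isfinite(t_p) else float(t_p)  # degenerate: identical lists
    return YRandomizationResult(real_rs=real_rs, permuted_rs=permuted_rs, t_p=t_p)


def complementarity(results: list[CaseResult], rs_min: float = RS_THRESHOLD) -> dict:
    """Quadrant bookkeeping: which cases are predictive by which strategy.

    A case counts as OMC-predictive when a complexity was selected and the
    selected-features model exceeds rs_min on the test set; all-features-
    predictive when the baseline does. Also reports the mean paired test-Rs
    difference (selected minus all-features, over cases with both
    evaluations), its two-sided paired t-test p, and the mean feature
    reduction 1 - k_opt/p over OMC-predictive cases.
    """
    counts = {"both": 0, "omc_only": 0, "all_only": 0, "neither": 0}
    omc_rs, all_rs, reductions = [], [], []
    for res in results:
        omc_pred = (
            res.k_opt is not None
            and res.omc_evaluation is not None
            and res.omc_evaluation.rs is not None
            and res.omc_evaluation.rs > rs_min
        )
        all_pred = (
            res.all_features_evaluation is not None
            and res.all_features_evaluation.rs is not None
            and res.all_features_evaluation.rs > rs_min
        )
        if omc_pred and all_pred:
            counts["both"] += 1
        elif omc_pred:
            counts["omc_only"] += 1
        elif all_pred:
            counts["all_only"] += 1
        else:
            counts["neither"] += 1
        if (
            res.omc_evaluation is not None
            and res.omc_evaluation.rs is not None
            and res.all_features_evaluation is not None
            and res.all_features_evaluation.rs is not None
        ):
            omc_rs.append(res.omc_evaluation.rs)
            all_rs.append(res.all_features_evaluation.rs)
        if omc_pred:
            reductions.append(1.0 - res.k_opt / res.p)

    if omc_rs:
        diff = float(np.mean(np.asarray(omc_rs) - np.asarray(all_rs)))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = stats.ttest_rel(omc_rs, all_rs).pvalue
        t_p = 1.0 if not np.isfinite(t_p) else float(t_p)
    else:
        diff, t_p = float("nan"), float("nan")
    return {
        **counts,
        "n_cases": len(results),
        "mean_rs_difference": diff,
        "paired_t_p": t_p,
        "mean_feature_reduction": float(np.mean(reductions)) if reductions else float("nan"),
        "n_omc_predictive": counts["both"] + counts["omc_only"],
        "n_all_predictive": counts["both"] + counts["all_only"],
    }
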