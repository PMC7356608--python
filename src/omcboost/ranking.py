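"""Univariate feature pre-ranking against the drug response.

Binary features (mutation / CNA status) are scored with the two-sided Wilcoxon
rank-sum test comparing responses of carriers vs non-carriers; continuous
features (expression, methylation beta-values) with the two-sided Spearman
rank-correlation test. The p-values are used purely as an ordering device —
no multiple-testing correction is applied, and none is warranted, because the
downstream complexity search consumes only the feature order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["FeatureRanking", "rank_features", "wilcoxon_rank_sum_p", "spearman_test"]

#: Largest group size at which the exact Wilcoxon null distribution is used
#: (ties force the normal approximation regardless).
EXACT_GROUP_LIMIT = 25


@dataclass
class FeatureRanking:
    """Features ordered from most to least associated with the response.

    Sorted ascending by p-value; ties broken by descending absolute effect
    (rank-biserial correlation for binary features, Spearman rho for
    continuous), then lexicographic feature name. The tie-break matters:
    binary features produce many identical p-values and the top-k subsets
    feed model training, so the order must be deterministic.
    """

    feature_names: list[str]
    p_values: np.ndarray
    effects: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)

    def __len__(self) -> int:
        return len(self.feature_names)

    def top_k(self, k: int) -> list[str]:
        """The first k feature names; top_k(k) is a prefix of top_k(k+1)."""
        if not 1 <= k <= len(self.feature_names):
            raise ValueError(f"k={k} out of range [1, {len(self.feature_names)}]")
        return self.feature_names[:k]


def wilcoxon_rank_sum_p(y_carriers: np.ndarray, y_noncarriers: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p and rank-biserial effect for one binary feature.

    Exact null distribution when both groups have <= 25 members and the pooled
    responses are tie-free; otherwise the normal approximation with continuity
    correction. An empty group carries no information: p = 1, effect = 0.
    """
    n1, n0 = y_carriers.size, y_noncarriers.size
    if n1 == 0 or n0 == 0:
        return 1.0, 0.0
    pooled = np.concatenate([y_carriers, y_noncarriers])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (max(n1, n0) <= EXACT_GROUP_LIMIT) and not has_ties
    res = stats.mannwhitneyu(
        y_carriers,
        y_noncarriers,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    # Rank-biserial correlation: P(carrier > non-carrier) - P(carrier < non-carrier).
    effect = 2.0 * float(res.statistic) / (n1 * n0) - 1.0
    return float(res.pvalue), effect


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Spearman correlation test (t-approximation) for one feature."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0, 0.0
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(rho):
        return 1.0, 0.0
    return p, rho


def _spearman_p_vectorized(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided t-approximation p for every column of X at once."""
    n = y.size
    rx = stats.rankdata(X, axis=0)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx.T @ ry) / denom
    rho = np.clip(rho, -1.0, 1.0)
    constant = ~np.isfinite(rho)
    rho[constant] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, 0.0)  # |rho| == 1 -> p = 0
    p[constant] = 1.0
    rho[constant] = 0.0
    return p, rho


def rank_features(X, y, kind: str, feature_names=None) -> FeatureRanking:
    """Rank every feature of X by its univariate association with y.

    ``kind`` is "binary" (Wilcoxon rank-sum on carrier vs non-carrier
    responses) or "continuous" (Spearman correlation test). Degenerate
    features — constant columns, or binary columns whose carrier or
    non-carrier group is empty in the supplied rows — are kept with p = 1 so
    feature indexing stays stable across folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X {X.shape} and y {y.shape} are inconsistent")
    if X.size == 0:
        raise ValueError("empty feature matrix")
    if kind not in ("binary", "continuous"):
        raise ValueError(f"kind must be 'binary' or 'continuous', got {kind!r}")
    if kind == "binary" and not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("kind='binary' but the matrix has entries other than 0/1")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    feature_names = [str(f) for f in feature_names]

    p = X.shape[1]
    if kind == "binary":
        p_values = np.empty(p)
        effects = np.empty(p)
        for j in range(p):
            carriers = X[:, j] == 1.0
            p_values[j], effects[j] = wilcoxon_rank_sum_p(y[carriers], y[~carriers])
    else:
        if np.ptp(y) == 0:
            p_values = np.ones(p)
            effects = np.zeros(p)
        else:
            p_values, effects = _spearman_p_vectorized(X, y)

    order = sorted(range(p), key=lambda j: (p_values[j], -abs(effects[j]), feature_names[j]))
    return FeatureRanking(
        feature_names=[feature_names[j] for j in order],
        p_values=p_values[order],
        effects=effects[order],
        kind=kind,
    )


def top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """Module-level alias for :meth:`FeatureRanking.top_k`."""
    return ranking.top_k(k)
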