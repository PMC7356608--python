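"""Rank-stratified test-set extraction and cross-validation fold assignment.

Both procedures operate on the rank order of the response so that every
evaluation set (the 10-cell-line external test set and each validation fold)
covers the full log10 IC50 range instead of, say, only the sensitive tail.

Test split: the global response extremes always stay in training; the second
most extreme values (ascending ranks 2 and m-1) anchor the test set and eight
further members are taken at equidistant interior ranks.

Folds: the ranked training responses are cut into consecutive blocks of five
and each block is scattered across the five folds by a seeded permutation, so
every fold samples every stratum of the response range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IneligibleCaseError",
    "TrainTestSplit",
    "FoldAssignment",
    "make_test_split",
    "make_cv_folds",
    "equidistant_test_ranks",
]

TEST_SET_SIZE = 10
N_FOLDS = 5


class IneligibleCaseError(ValueError):
    """The case has too few cell lines for the stratified split."""


def _rank_order(y: np.ndarray, cell_ids) -> np.ndarray:
    """Indices sorting y ascending; ties broken by cell-id lexicographic order.

    The tie-break makes the ordering (hence every downstream artifact) fully
    deterministic across runs and platforms.
    """
    if cell_ids is None:
        cell_ids = [str(i) for i in range(len(y))]
    ids = np.asarray([str(c) for c in cell_ids])
    # np.lexsort: last key is primary.
    return np.lexsort((ids, np.asarray(y, dtype=float)))


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class TrainTestSplit:
    """Index partition into training set (n = m - 10) and external test set (10)."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)


@dataclass
class FoldAssignment:
    """Map from training-instance index to fold label in 1..n_folds."""

    fold_of: np.ndarray
    seed: int
    n_folds: int = N_FOLDS

    def __post_init__(self) -> None:
        self.fold_of = np.asarray(self.fold_of, dtype=int)

    def fold_indices(self, fold: int) -> np.ndarray:
        """Indices of the instances assigned to ``fold`` (1-based label)."""
        return np.nonzero(self.fold_of == fold)[0]


def equidistant_test_ranks(m: int, test_size: int = TEST_SET_SIZE) -> list[int]:
    """The 1-based ascending-response ranks placed in the external test set.

    Ranks 2 and m-1 are always included; the remaining test_size - 2 ranks are
    spaced equidistantly over the interior, r_j = round(2 + j * (m - 3) / 9)
    for j = 1..8 at the default size, rounding half away from zero. A collision
    with an already-chosen rank advances to the next unused interior rank
    (interior = 3..m-2), so exactly ``test_size`` distinct ranks result.
    """
    if m < test_size + 2:
        raise IneligibleCaseError(f"cannot stratify a test set of {test_size} from {m} instances")
    chosen = [2, m - 1]
    used = set(chosen)
    n_free = test_size - 2
    for j in range(1, n_free + 1):
        r = _round_half_away(2 + j * (m - 3) / (n_free + 1))
        r = max(3, min(r, m - 2))
        while r in used:
            r += 1
            if r > m - 2:
                raise IneligibleCaseError(f"ran out of interior ranks stratifying m={m}")
        used.add(r)
        chosen.append(r)
    return sorted(chosen)


def make_test_split(
    y,
    cell_ids=None,
    seed: int = 0,
    *,
    test_size: int = TEST_SET_SIZE,
    min_cell_lines: int = 45,
) -> TrainTestSplit:
    """Extract the rank-stratified external test set.

    The split is deterministic given the responses and identifiers: the seed is
    recorded for provenance but the equidistant-rank rule leaves nothing to
    randomize.
    """
    y = np.asarray(y, dtype=float)
    m = y.shape[0]
    if m < test_size + 2:
        raise IneligibleCaseError(f"impossible split: m={m} < {test_size + 2}")
    if m < min_cell_lines:
        raise IneligibleCaseError(
            f"ineligible case: m={m} < {min_cell_lines} treated cell lines"
        )
    order = _rank_order(y, cell_ids)
    ranks = equidistant_test_ranks(m, test_size)
    test_idx = np.sort(order[[r - 1 for r in ranks]])
    mask = np.ones(m, dtype=bool)
    mask[test_idx] = False
    return TrainTestSplit(train_idx=np.nonzero(mask)[0], test_idx=test_idx, seed=seed)


def make_cv_folds(
    y_train,
    cell_ids=None,
    seed: int = 0,
    *,
    n_folds: int = N_FOLDS,
) -> FoldAssignment:
    """Assign training instances to rank-stratified cross-validation folds.

    Instances are ranked by ascending response (ties broken by cell id),
    partitioned into consecutive blocks of ``n_folds``, and each block is
    scattered over the folds by a seeded random permutation; a final partial
    block goes to a random subset of distinct folds. Fold sizes therefore
    differ by at most one.
    """
    y_train = np.asarray(y_train, dtype=float)
    n = y_train.shape[0]
    if n < 2 * n_folds:
        raise ValueError(f"too few training instances ({n}) for {n_folds} stratified folds")
    order = _rank_order(y_train, cell_ids)
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(n, dtype=int)
    for start in range(0, n, n_folds):
        block = order[start : start + n_folds]
        if block.size == n_folds:
            labels = rng.permutation(n_folds) + 1
        else:
            labels = rng.choice(n_folds, size=block.size, replace=False) + 1
        fold_of[block] = labels
    return FoldAssignment(fold_of=fold_of, seed=seed, n_folds=n_folds)
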