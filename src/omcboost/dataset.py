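"""The per-case dataset container and its delimited-text I/O.

A *case* is one (drug, cancer type, omics profile) triple: a feature matrix of
m cell lines x p molecular features plus the m log10 IC50 responses. Binary
profiles (SNV mutation status, CNA altered-segment status) must be exactly
{0, 1}; expression and methylation profiles are real-valued.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Omics", "CaseDataset", "read_case", "write_case", "read_response"]

#: Minimum number of cell lines for the full pipeline (10 go to the test set,
#: at least 35 must remain for training).
MIN_ELIGIBLE_CELL_LINES = 45

CELL_ID_COLUMN = "cell_id"
RESPONSE_COLUMN = "response"


class Omics(str, enum.Enum):
    """Molecular profile type of a case's feature matrix."""

    SNV = "snv"
    CNA = "cna"
    GEX = "gex"
    METHY = "methy"

    @property
    def is_binary(self) -> bool:
        return self in (Omics.SNV, Omics.CNA)

    @property
    def ranking_kind(self) -> str:
        return "binary" if self.is_binary else "continuous"


@dataclass
class CaseDataset:
    """One drug / cancer-type / omics case: features, responses, identifiers."""

    drug: str
    cancer_type: str
    omics: Omics
    cell_ids: list[str]
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.omics = Omics(self.omics)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self._validate()

    def _validate(self) -> None:
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        m, p = self.X.shape
        if len(self.cell_ids) != m or self.y.shape != (m,):
            raise ValueError(
                f"inconsistent case: {len(self.cell_ids)} cell ids, "
                f"X has {m} rows, y has {self.y.shape[0] if self.y.ndim == 1 else '?'} entries"
            )
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} feature names for {p} columns")
        if len(set(self.cell_ids)) != m:
            raise ValueError("duplicate cell-line identifiers")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.X)):
            bad = [self.cell_ids[i] for i in np.unique(np.nonzero(~np.isfinite(self.X))[0])]
            raise ValueError(f"non-finite feature values in rows: {bad}")
        if not np.all(np.isfinite(self.y)):
            bad = [self.cell_ids[i] for i in np.nonzero(~np.isfinite(self.y))[0]]
            raise ValueError(f"non-finite responses for cell lines: {bad}")
        if self.omics.is_binary:
            nonbinary = ~np.isin(self.X, (0.0, 1.0))
            if nonbinary.any():
                rows, cols = np.nonzero(nonbinary)
                offenders = sorted(
                    {(self.cell_ids[r], self.feature_names[c]) for r, c in zip(rows, cols)}
                )[:10]
                raise ValueError(
                    f"binary omics {self.omics.value} contains non-binary entries at "
                    f"(cell, feature): {offenders}"
                )

    @property
    def case_id(self) -> tuple[str, str, str]:
        return (self.drug, self.cancer_type, self.omics.value)

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def is_eligible(self) -> bool:
        """Whether the case has enough cell lines for the full pipeline."""
        return self.m >= MIN_ELIGIBLE_CELL_LINES

    def subset(self, row_idx) -> "CaseDataset":
        """A new case restricted to the given row indices (order preserved)."""
        row_idx = np.asarray(row_idx, dtype=int)
        return CaseDataset(
            drug=self.drug,
            cancer_type=self.cancer_type,
            omics=self.omics,
            cell_ids=[self.cell_ids[i] for i in row_idx],
            feature_names=list(self.feature_names),
            X=self.X[row_idx],
            y=self.y[row_idx],
        )


def read_response(response_path: str | Path) -> pd.Series:
    """Read a tab-separated cell_id -> log10 IC50 table into a Series."""
    df = pd.read_csv(response_path, sep="\t", dtype={CELL_ID_COLUMN: str})
    for col in (CELL_ID_COLUMN, RESPONSE_COLUMN):
        if col not in df.columns:
            raise ValueError(f"response file {response_path} lacks required column '{col}'")
    if df[CELL_ID_COLUMN].duplicated().any():
        dups = df.loc[df[CELL_ID_COLUMN].duplicated(), CELL_ID_COLUMN].tolist()
        raise ValueError(f"duplicate cell ids in response file: {dups}")
    return df.set_index(CELL_ID_COLUMN)[RESPONSE_COLUMN]


def read_case(
    matrix_path: str | Path,
    response_path: str | Path,
    *,
    drug: str,
    cancer_type: str,
    omics: Omics | str,
) -> CaseDataset:
    """Load a case from a tab-separated feature matrix and a response table.

    The matrix has a header row of feature names and a first column named
    ``cell_id``. Rows of X and y are aligned by identifier, not file order;
    any cell line present in one file but not the other is an error.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", dtype={CELL_ID_COLUMN: str})
    if CELL_ID_COLUMN not in matrix.columns:
        raise ValueError(f"matrix file {matrix_path} lacks a '{CELL_ID_COLUMN}' column")
    matrix = matrix.set_index(CELL_ID_COLUMN)
    if matrix.isna().any().any():
        bad_rows = matrix.index[matrix.isna().any(axis=1)].tolist()
        raise ValueError(f"missing feature values for cell lines: {bad_rows}")

    response = read_response(response_path)
    missing_in_response = sorted(set(matrix.index) - set(response.index))
    missing_in_matrix = sorted(set(response.index) - set(matrix.index))
    if missing_in_response or missing_in_matrix:
        raise ValueError(
            "cell-id mismatch between matrix and response: "
            f"missing from response {missing_in_response}; "
            f"missing from matrix {missing_in_matrix}"
        )

    cell_ids = list(matrix.index)
    return CaseDataset(
        drug=drug,
        cancer_type=cancer_type,
        omics=Omics(omics),
        cell_ids=cell_ids,
        feature_names=list(matrix.columns),
        X=matrix.to_numpy(dtype=float),
        y=response.loc[cell_ids].to_numpy(dtype=float),
    )


def write_case(dataset: CaseDataset, matrix_path: str | Path, response_path: str | Path) -> None:
    """Write a case back to the canonical tab-separated formats.

    Binary matrices are written as integers so a read/write round trip is
    byte-equivalent for canonically formatted inputs.
    """
    X = dataset.X.astype(int) if dataset.omics.is_binary else dataset.X
    matrix = pd.DataFrame(X, index=pd.Index(dataset.cell_ids, name=CELL_ID_COLUMN),
                          columns=dataset.feature_names)
    matrix.to_csv(matrix_path, sep="\t")
    response = pd.DataFrame(
        {CELL_ID_COLUMN: dataset.cell_ids, RESPONSE_COLUMN: dataset.y}
    )
    response.to_csv(response_path, sep="\t", index=False)
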