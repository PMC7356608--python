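"""Feature-matrix construction from pre-processed pharmacogenomics tables.

Builders turn generic delimited-text exports of curated resources (variant
lists, copy-number segment tables, expression / methylation value matrices,
identifier mappings) into the binary or continuous feature matrices the
pipeline consumes. The guiding rule throughout is clinical relevance by
intersection: only features observed in *both* cell lines and primary tumors
are kept. Binary encodings deliberately collapse detail — any variant class
marks a gene as mutated, any alteration marks a segment — because finer
distinctions (driver vs passenger, copy count) have no settled relationship
with drug response.

All builders are order-stable: permuting input rows yields the same matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "build_snv_matrix",
    "intersect_with_primary",
    "build_cna_matrix",
    "build_continuous_matrix",
    "MappingReport",
]

VARIANT_COLUMNS = ("cell_id", "gene", "variant_class")
SEGMENT_COLUMNS = ("cancer_type", "region_id", "cell_id", "altered")


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} lacks required columns: {missing}")


def build_snv_matrix(
    variants: pd.DataFrame, gene_whitelist: list[str], cell_ids: list[str]
) -> pd.DataFrame:
    """Binary mutation matrix: 1 iff any variant links the cell to the gene.

    One column per whitelist gene (all-zero columns are retained so the
    feature space is identical across cases); variant class is ignored.
    Variant rows for cells outside ``cell_ids`` are dropped with a warning.
    """
    if len(gene_whitelist) == 0:
        raise ValueError("empty gene whitelist")
    _require_columns(variants, ("cell_id", "gene"), "variant table")
    if variants[["cell_id", "gene"]].isna().any().any():
        raise ValueError("variant table has missing cell_id or gene entries")
    cell_ids = [str(c) for c in cell_ids]
    genes = [str(g) for g in gene_whitelist]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in whitelist")

    variants = variants.astype({"cell_id": str, "gene": str})
    unknown = sorted(set(variants["cell_id"]) - set(cell_ids))
    if unknown:
        warnings.warn(
            f"dropping variants for {len(unknown)} cell line(s) absent from cell_ids: "
            f"{unknown[:5]}",
            stacklevel=2,
        )
        variants = variants[variants["cell_id"].isin(cell_ids)]

    matrix = pd.DataFrame(0, index=pd.Index(cell_ids, name="cell_id"), columns=genes,
                          dtype=int)
    hits = variants[variants["gene"].isin(genes)]
    for cell, gene in zip(hits["cell_id"], hits["gene"]):
        matrix.at[cell, gene] = 1  # duplicates are idempotent
    return matrix


def intersect_with_primary(cell_feature_ids: list, tumor_feature_ids: list) -> list:
    """Features present in both cell lines and primary tumors.

    Order follows the cell-line list; an empty intersection is returned as-is
    (downstream eligibility checks will fail loudly).
    """
    tumor_set = set(tumor_feature_ids)
    seen = set()
    out = []
    for f in cell_feature_ids:
        if f in tumor_set and f not in seen:
            out.append(f)
            seen.add(f)
    return out


def build_cna_matrix(
    segments: pd.DataFrame,
    tumor_region_ids: list[str],
    cancer_type: str,
    cell_ids: list[str],
) -> pd.DataFrame:
    """Binary copy-number-alteration matrix for one cancer type.

    Columns are the cancer type's segments intersected with the primary-tumor
    region list (cell-line order preserved); an entry is 1 iff the cell
    carries the altered segment. Segments are cancer-specific, so each cancer
    type yields a different feature set.
    """
    _require_columns(segments, SEGMENT_COLUMNS, "segment table")
    if (segments["region_id"].isna() | (segments["region_id"].astype(str) == "")).any():
        raise ValueError("segment table has empty region identifiers")
    segments = segments.astype({"cancer_type": str, "region_id": str, "cell_id": str})
    sub = segments[segments["cancer_type"] == str(cancer_type)]
    if sub.empty:
        raise ValueError(f"no segments recorded for cancer type {cancer_type!r}")
    observed = list(dict.fromkeys(sub["region_id"]))
    regions = intersect_with_primary(observed, [str(r) for r in tumor_region_ids])
    cell_ids = [str(c) for c in cell_ids]

    matrix = pd.DataFrame(0, index=pd.Index(cell_ids, name="cell_id"), columns=regions,
                          dtype=int)
    altered = sub[sub["altered"].astype(bool) & sub["region_id"].isin(regions)]
    for cell, region in zip(altered["cell_id"], altered["region_id"]):
        if cell in matrix.index:
            matrix.at[cell, region] = 1
    return matrix


@dataclass
class MappingReport:
    """Requested features that could not be mapped and were dropped.

    Mapping failures are non-fatal by design: curated resources routinely use
    secondary gene names, and the report is the hook for manual correction.
    """

    unmapped: list[str] = field(default_factory=list)


def build_continuous_matrix(
    values: pd.DataFrame,
    keep_features: list[str],
    id_map: dict[str, str] | None,
    cell_ids: list[str],
    beta_values: bool = False,
) -> tuple[pd.DataFrame, MappingReport]:
    """Continuous matrix (cells x features) restricted to mappable kept features.

    ``values`` is a feature-by-cell table (features as index, cell ids as
    columns). ``id_map`` translates requested feature names into the value
    table's namespace; unmappable features are dropped and reported. Values
    pass through unchanged — inputs are assumed already normalized. With
    ``beta_values=True`` entries must lie in [0, 1] (methylation fractions).
    """
    if len(keep_features) == 0:
        raise ValueError("keep_features is empty")
    values = values.copy()
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    cell_ids = [str(c) for c in cell_ids]
    missing_cells = sorted(set(cell_ids) - set(values.columns))
    if missing_cells:
        raise ValueError(f"cells missing from value table: {missing_cells}")

    report = MappingReport()
    mapped_names = []  # (requested name, name in value table)
    for f in keep_features:
        f = str(f)
        target = id_map.get(f, f) if id_map else f
        if target in values.index:
            mapped_names.append((f, target))
        else:
            report.unmapped.append(f)

    if not mapped_names:
        raise ValueError("no requested feature could be mapped to the value table")
    sub = values.loc[[t for _, t in mapped_names], cell_ids].T
    sub.columns = [f for f, _ in mapped_names]
    sub.index.name = "cell_id"
    if beta_values:
        arr = sub.to_numpy(dtype=float)
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("beta-values must lie in [0, 1]")
    return sub, report
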