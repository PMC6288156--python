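"""Expression / annotation / clinical table I-O and cohort preparation.

All tables travel as TSV.  The expression matrix is genes x samples with the
gene identifier in the first column; sample annotation and clinical tables are
one row per sample / patient.  Tissue types use the closed vocabulary
``DAN, PAN, CAN, MET, LYMPH`` plus ``AN`` for the collapsed adjacent-normal
group (DAN = distant adjacent normal, >3 mm from the nearest tumour focus;
PAN = proximal adjacent normal, <1 mm; CAN = primary tumour focus; MET =
lymph-node metastasis; LYMPH = non-malignant lymph node).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUE_TYPES = ("DAN", "PAN", "CAN", "MET", "LYMPH", "AN")

#: Columns every sample-annotation table must carry.
ANNOTATION_COLUMNS = ("sample_id", "patient_id", "tissue_type", "focus_label", "qc_pass")


class FormatError(ValueError):
    """Raised when an input table violates the documented schema."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared unit.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with sample ids as columns.
    unit:
        One of ``counts``, ``fpkm``, ``log2fpkm``, ``log2counts``.
    """

    data: pd.DataFrame
    unit: str = "counts"

    _LINEAR_UNITS = ("counts", "fpkm")
    _LOG_UNITS = ("log2fpkm", "log2counts")

    def __post_init__(self) -> None:
        if self.unit not in self._LINEAR_UNITS + self._LOG_UNITS:
            raise FormatError(f"unknown expression unit {self.unit!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise FormatError("expression matrix contains non-finite entries")
        if self.unit in self._LINEAR_UNITS and (values < 0).any():
            raise FormatError("negative values in a linear-scale expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return replace(self, data=self.data.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return replace(self, data=self.data.loc[list(gene_ids)])


def read_expression(path: str | Path, unit: str = "counts") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    try:
        data = table.astype(float)
    except ValueError as exc:
        # pinpoint the offending cell for the error report
        for gene, row in table.iterrows():
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric value {cell!r} at gene {gene!r}, sample {col!r} in {path}"
                    ) from exc
        raise FormatError(f"non-numeric value in {path}") from exc
    return ExpressionMatrix(data=data, unit=unit)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    validate_annotation(ann)
    return ann


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    annotation.to_csv(path, sep="\t", index=False)


def validate_annotation(annotation: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise FormatError(f"annotation table missing columns: {missing}")
    bad = set(annotation["tissue_type"]) - set(TISSUE_TYPES)
    if bad:
        raise FormatError(f"unknown tissue types: {sorted(bad)}")
    if annotation["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in annotation")


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str})


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(path, sep="\t", index=False)


def qc_filter(annotation: pd.DataFrame) -> pd.DataFrame:
    """Drop samples whose ``qc_pass`` flag is false; row order preserved."""
    validate_annotation(annotation)
    keep = annotation["qc_pass"].astype(bool)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("qc_filter: removed %d low-quality samples, %d remain",
                    n_removed, int(keep.sum()))
    if keep.sum() == 0:
        logger.warning("qc_filter: every sample failed QC; returning empty table")
    return annotation.loc[keep].reset_index(drop=True)


@dataclass
class CohortEligibilityRules:
    """Boolean clinical-table columns whose flagged rows are excluded.

    Typical flags: ``post_endocrine_treated``, ``duplicate``, ``zero_days_to_bcr``.
    """

    exclude_flags: list[str] = field(default_factory=list)


def apply_eligibility(clinical: pd.DataFrame, rules: CohortEligibilityRules) -> pd.DataFrame:
    """Remove patients carrying any exclusion flag; removal counts are logged per rule."""
    missing = [c for c in rules.exclude_flags if c not in clinical.columns]
    if missing:
        raise FormatError(f"eligibility rule columns absent from clinical table: {missing}")
    drop = pd.Series(False, index=clinical.index)
    for flag in rules.exclude_flags:
        col = clinical[flag].astype(bool)
        logger.info("apply_eligibility: %s flagged %d patients", flag, int(col.sum()))
        drop |= col
    kept = clinical.loc[~drop].reset_index(drop=True)
    logger.info("apply_eligibility: %d of %d patients retained", len(kept), len(clinical))
    return kept


def collapse_an(annotation: pd.DataFrame) -> pd.DataFrame:
    """Merge the DAN and PAN groups into a single adjacent-normal (AN) group.

    Idempotent; every non-adjacent-normal label is untouched.
    """
    out = annotation.copy()
    out["tissue_type"] = out["tissue_type"].replace({"DAN": "AN", "PAN": "AN"})
    return out


def filter_expressed(
    expr: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    min_fpkm: float = 1.0,
    min_frac: float = 0.5,
) -> ExpressionMatrix:
    """Keep genes expressed above ``min_fpkm`` in >= ``min_frac`` of every subgroup.

    ``groups`` maps sample id -> subgroup label.  A gene survives only if the
    rule holds in *each* subgroup, so the retained set shrinks as either
    threshold grows.
    """
    if expr.unit != "fpkm":
        raise FormatError("filter_expressed operates on FPKM matrices")
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    unassigned = [s for s in expr.sample_ids if s not in groups.index]
    if unassigned:
        raise FormatError(f"samples without a subgroup: {unassigned}")
    keep = pd.Series(True, index=expr.data.index)
    for label in groups.unique():
        samples = [s for s in expr.sample_ids if groups[s] == label]
        if not samples:
            raise FormatError(f"subgroup {label!r} has no samples in the matrix")
        frac = (expr.data[samples] > min_fpkm).mean(axis=1)
        keep &= frac >= min_frac
    logger.info("filter_expressed: %d of %d genes retained", int(keep.sum()), len(keep))
    return replace(expr, data=expr.data.loc[keep])


def fpkm_from_counts(expr: ExpressionMatrix, gene_lengths: pd.Series) -> ExpressionMatrix:
    """Fragments per kilobase per million from raw counts and gene lengths (bp).

    Provided for completeness; external cohorts are normally consumed
    pre-normalised.
    """
    if expr.unit != "counts":
        raise FormatError("fpkm_from_counts expects raw counts")
    missing = [g for g in expr.gene_ids if g not in gene_lengths.index]
    if missing:
        raise FormatError(f"gene lengths missing for {len(missing)} genes (e.g. {missing[:3]})")
    lengths_kb = gene_lengths.loc[expr.gene_ids].astype(float) / 1000.0
    if (lengths_kb <= 0).any():
        raise FormatError("gene lengths must be positive")
    per_million = expr.data.sum(axis=0) / 1e6
    fpkm = expr.data.div(per_million, axis=1).div(lengths_kb, axis=0)
    return ExpressionMatrix(data=fpkm, unit="fpkm")


def to_log2(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Entrywise log2(x + pseudocount)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if expr.unit not in ExpressionMatrix._LINEAR_UNITS:
        raise FormatError(f"matrix already on log scale ({expr.unit})")
    unit = "log2fpkm" if expr.unit == "fpkm" else "log2counts"
    return ExpressionMatrix(data=np.log2(expr.data + pseudocount), unit=unit)


def match_panel_genes(
    panel_genes: Iterable[str],
    expr: ExpressionMatrix,
    alias_map: Mapping[str, str] | None = None,
) -> tuple[list[str], float]:
    """Map panel genes onto a cohort's matrix by exact id (after optional aliasing).

    Returns the matched gene ids (in panel order) and the coverage fraction,
    which is logged — external cohorts on other platforms typically carry only
    a subset of a discovery panel.
    """
    alias_map = dict(alias_map or {})
    present = set(expr.gene_ids)
    matched = []
    panel_genes = list(panel_genes)
    for g in panel_genes:
        target = alias_map.get(g, g)
        if target in present:
            matched.append(target)
    coverage = len(matched) / len(panel_genes) if panel_genes else 0.0
    logger.info("match_panel_genes: %d/%d panel genes present (%.1f%%)",
                len(matched), len(panel_genes), 100 * coverage)
    return matched, coverage
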