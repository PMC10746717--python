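"""Preprocessing of relative protein quantification tables.

The pipeline order is fixed and order-sensitive:

1. ``exclude_sparse_levels`` — drop patients whose severity level has too
   few members to learn from (the cohort this mirrors contained a single
   level-1 patient, who was excluded).
2. ``filter_contaminants`` — remove keratins (except keratins 18/19),
   dermcidins/dermacolins and trypsins by protein-name match.
3. ``drop_undetected`` — remove proteins never detected in any patient.
4. ``encode_special_values`` — recode the two special states: recorded
   0 (protein inference) becomes 1 FIRST, then missing (not detected)
   becomes 0.  Running the rewrites in the other order would merge the
   two states.
5. ``log_standardize`` — log1p then per-feature standard scaling.

Peak areas span orders of magnitude and are right-skewed, which is why the
log transform precedes scaling.  log1p is used so that the 0 encoding of
non-detections maps to 0 and the transform is defined everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tearomics.containers import ClinicalTable, ProteinQuantTable

DEFAULT_REMOVE_PATTERNS = ["keratin", "dermcidin", "dermacolin", "dermcolin", "trypsin"]
DEFAULT_KEEP_PATTERNS = [
    "keratin, type i cytoskeletal 18",
    "keratin, type i cytoskeletal 19",
]


@dataclass(frozen=True)
class ContaminantRules:
    """Name-based contaminant filter: case-insensitive substring match.

    A column is removed when its protein name matches any remove pattern,
    unless the name also matches a keep pattern (keep wins).
    """

    remove_name_patterns: tuple[str, ...] = tuple(DEFAULT_REMOVE_PATTERNS)
    keep_name_patterns: tuple[str, ...] = tuple(DEFAULT_KEEP_PATTERNS)

    def __post_init__(self) -> None:
        if not self.remove_name_patterns or any(not p for p in self.remove_name_patterns):
            raise ValueError("remove patterns must be non-empty strings")
        if any(not p for p in self.keep_name_patterns):
            raise ValueError("keep patterns must be non-empty strings")

    def is_contaminant(self, name: str) -> bool:
        low = str(name).lower()
        if any(p.lower() in low for p in self.keep_name_patterns):
            return False
        return any(p.lower() in low for p in self.remove_name_patterns)


@dataclass
class PreprocessedMatrix:
    """Model-ready feature matrix plus the fitted transform parameters.

    ``transform_params`` has one row per feature with the log1p-scale
    ``mean`` and population ``sd`` used for scaling; constant features
    are recorded with sd 0 and map to all-zero columns.
    """

    values: pd.DataFrame
    transform_params: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_accessions(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def exclude_sparse_levels(
    clinical: ClinicalTable, quant: ProteinQuantTable, min_count: int = 2
) -> tuple[ClinicalTable, ProteinQuantTable]:
    """Drop samples belonging to severity levels with < min_count members."""
    if set(clinical.sample_ids) != set(quant.sample_ids):
        raise ValueError("clinical and quantification tables must share sample ids")
    counts = clinical.level_counts()
    keep_levels = {lv for lv, n in counts.items() if n >= min_count}
    mask = np.isin(clinical.levels, sorted(keep_levels))
    if not mask.any():
        raise ValueError("no severity level reaches min_count; degenerate cohort")
    kept_ids = [sid for sid, m in zip(clinical.sample_ids, mask) if m]
    return clinical.subset(kept_ids), quant.subset_samples(kept_ids)


def filter_contaminants(
    quant: ProteinQuantTable, rules: ContaminantRules | None = None
) -> ProteinQuantTable:
    """Remove contaminant proteins by name; column order preserved."""
    rules = rules or ContaminantRules()
    keep = [acc for acc in quant.accessions if not rules.is_contaminant(quant.names[acc])]
    return quant.subset_proteins(keep)


def drop_undetected(quant: ProteinQuantTable) -> ProteinQuantTable:
    """Remove proteins not detected in any sample (all entries missing)."""
    keep = [acc for acc in quant.accessions if quant.values[acc].notna().any()]
    return quant.subset_proteins(keep)


def encode_special_values(quant: ProteinQuantTable) -> ProteinQuantTable:
    """Recode special states: 0 -> 1 (inference) first, then missing -> 0.

    The order is a hard contract: swapping it would turn non-detections
    into inference flags and lose the distinction between the two states.
    """
    arr = quant.values.to_numpy(dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("negative quantification value encountered")
    arr = arr.copy()
    arr[arr == 0.0] = 1.0
    arr[np.isnan(arr)] = 0.0
    values = pd.DataFrame(arr, index=quant.values.index, columns=quant.values.columns)
    return ProteinQuantTable(values, quant.names)


def log_standardize(quant: ProteinQuantTable) -> PreprocessedMatrix:
    """log1p then per-feature standard scaling (population sd).

    Requires fully-encoded input (no missing, no negatives).  Constant
    features map to all-zero columns with sd recorded as 0.
    """
    arr = quant.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing values present; run encode_special_values first")
    if arr.min(initial=0.0) < 0:
        raise ValueError("negative quantification value encountered")
    logged = np.log1p(arr)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0)  # ddof=0, the ML-scaler convention
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    scaled = (logged - mean) / safe_sd
    scaled[:, sd == 0.0] = 0.0
    values = pd.DataFrame(scaled, index=quant.values.index, columns=quant.values.columns)
    params = pd.DataFrame({"mean": mean, "sd": sd}, index=quant.values.columns)
    return PreprocessedMatrix(values, params)


def apply_transform(params: pd.DataFrame, quant: ProteinQuantTable) -> PreprocessedMatrix:
    """Re-apply stored log1p/scaling parameters to new encoded data.

    Reproduces training-time encoding exactly for round-trip use.
    """
    missing = [a for a in quant.accessions if a not in params.index]
    if missing:
        raise ValueError(f"no stored transform for accessions {missing[:5]}")
    arr = np.log1p(quant.values.to_numpy(dtype=float))
    mean = params.loc[quant.accessions, "mean"].to_numpy()
    sd = params.loc[quant.accessions, "sd"].to_numpy()
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    scaled = (arr - mean) / safe_sd
    scaled[:, sd == 0.0] = 0.0
    values = pd.DataFrame(scaled, index=quant.values.index, columns=quant.values.columns)
    return PreprocessedMatrix(values, params.loc[quant.accessions])


@dataclass
class PreprocessReport:
    """Per-stage bookkeeping emitted alongside the matrix."""

    samples_removed: list[str] = field(default_factory=list)
    contaminants_removed: list[str] = field(default_factory=list)
    undetected_removed: list[str] = field(default_factory=list)
    n_zero_encoded: int = 0
    n_missing_encoded: int = 0
    stage_shapes: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "samples_removed": self.samples_removed,
            "contaminants_removed": self.contaminants_removed,
            "undetected_removed": self.undetected_removed,
            "n_zero_encoded": self.n_zero_encoded,
            "n_missing_encoded": self.n_missing_encoded,
            "stage_shapes": {k: list(v) for k, v in self.stage_shapes.items()},
        }


def preprocess_pipeline(
    clinical: ClinicalTable,
    quant: ProteinQuantTable,
    rules: ContaminantRules | None = None,
    min_count: int = 2,
) -> tuple[ClinicalTable, PreprocessedMatrix, PreprocessReport]:
    """Run the full fixed-order preprocessing chain with a report."""
    report = PreprocessReport()
    report.stage_shapes["input"] = quant.values.shape

    clin2, q = exclude_sparse_levels(clinical, quant, min_count=min_count)
    report.samples_removed = sorted(set(clinical.sample_ids) - set(clin2.sample_ids))
    report.stage_shapes["exclude_sparse_levels"] = q.values.shape

    before = set(q.accessions)
    q = filter_contaminants(q, rules)
    report.contaminants_removed = sorted(before - set(q.accessions))
    report.stage_shapes["filter_contaminants"] = q.values.shape

    before = set(q.accessions)
    q = drop_undetected(q)
    report.undetected_removed = sorted(before - set(q.accessions))
    report.stage_shapes["drop_undetected"] = q.values.shape

    arr = q.values.to_numpy(dtype=float)
    report.n_zero_encoded = int((arr == 0.0).sum())
    report.n_missing_encoded = int(np.isnan(arr).sum())
    q = encode_special_values(q)
    matrix = log_standardize(q)
    report.stage_shapes["final"] = matrix.values.shape
    return clin2, matrix, report
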