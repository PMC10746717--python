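"""Shared data containers: quantification and clinical tables.

A :class:`ProteinQuantTable` holds the raw samples x proteins peak-area
matrix.  Entries carry three-valued semantics inherited from label-free
quantification software output:

* ``NaN``  — the protein was not detected in that sample,
* ``0``    — protein inference (quantification not unambiguously assignable),
* positive — a relative peak area (arbitrary units).

A :class:`ClinicalTable` maps each sample to its MGD severity level (2-4;
level 1 may appear in raw cohorts but is excluded during preprocessing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_LEVELS = frozenset({1, 2, 3, 4})


@dataclass
class ProteinQuantTable:
    """Samples x proteins peak-area matrix with protein name metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per protein
        accession.  ``NaN`` means not detected.
    names
        Series mapping accession -> human-readable protein name, aligned
        with ``values.columns``.
    """

    values: pd.DataFrame
    names: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("protein accessions must be unique")
        self.names = self.names.reindex(self.values.columns)
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if np.any(~np.isfinite(finite)):
            raise ValueError("quantification values must be finite or NaN")
        if np.any(finite < 0):
            raise ValueError("quantification values must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "ProteinQuantTable":
        return ProteinQuantTable(self.values.loc[sample_ids], self.names)

    def subset_proteins(self, accessions) -> "ProteinQuantTable":
        return ProteinQuantTable(self.values[accessions], self.names.loc[accessions])

    # --- TSV round trip (empty cell == missing) -------------------------
    def to_tsv(self, quant_path: str | Path, proteins_path: str | Path) -> None:
        self.values.to_csv(quant_path, sep="\t", index_label="sample_id", na_rep="")
        meta = pd.DataFrame({"accession": self.values.columns, "name": self.names.values})
        meta.to_csv(proteins_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, quant_path: str | Path, proteins_path: str | Path) -> "ProteinQuantTable":
        values = pd.read_csv(quant_path, sep="\t", index_col="sample_id")
        meta = pd.read_csv(proteins_path, sep="\t")
        names = pd.Series(meta["name"].values, index=meta["accession"].values)
        return cls(values, names)


@dataclass
class ClinicalTable:
    """Per-sample MGD severity labels."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"sample_id", "mgd_level"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"clinical table needs columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        bad = set(self.table["mgd_level"].astype(int)) - VALID_LEVELS
        if bad:
            raise ValueError(f"invalid MGD levels: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def levels(self) -> np.ndarray:
        return self.table["mgd_level"].to_numpy(dtype=int)

    def level_counts(self) -> dict[int, int]:
        counts = self.table["mgd_level"].value_counts()
        return {int(k): int(v) for k, v in counts.sort_index().items()}

    def subset(self, sample_ids) -> "ClinicalTable":
        keep = self.table["sample_id"].isin(set(sample_ids))
        return ClinicalTable(self.table.loc[keep].reset_index(drop=True))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClinicalTable":
        return cls(pd.read_csv(path, sep="\t"))
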