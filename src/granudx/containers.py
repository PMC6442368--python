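"""Core in-memory containers for the pipeline.

The central object is an :class:`ExpressionMatrix` — a protein × sample
table of quantitation values carrying a scale flag (``linear`` intensities
straight from DIA software, or ``log2``) and a provenance tag that records
whether the matrix has been batch-adjusted.  The provenance tag exists
because the differential-expression stage must consume the *raw* log2
matrix (batch is handled by blocking in the linear model), while PCA and
heatmaps consume the ComBat-adjusted one; tagging matrices lets stage
boundaries enforce that rule instead of relying on call-site discipline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "PeptideSupport",
    "ProteinAnnotation",
    "GeneSetCollection",
    "SCALE_LINEAR",
    "SCALE_LOG2",
    "PROVENANCE_RAW_LINEAR",
    "PROVENANCE_LOG2",
    "PROVENANCE_COMBAT",
]

SCALE_LINEAR = "linear"
SCALE_LOG2 = "log2"

PROVENANCE_RAW_LINEAR = "raw-linear"
PROVENANCE_LOG2 = "log2"
PROVENANCE_COMBAT = "combat-adjusted"


@dataclass
class ExpressionMatrix:
    """Protein × sample quantitation matrix.

    Parameters
    ----------
    values
        DataFrame with protein ids as the index and sample ids as columns.
        Missing cells are NaN.
    scale
        ``"linear"`` (non-negative intensities) or ``"log2"``.
    provenance
        One of ``{"raw-linear", "log2", "combat-adjusted"}``; defaults to
        the tag implied by ``scale``.
    """

    values: pd.DataFrame
    scale: str = SCALE_LINEAR
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_LINEAR, SCALE_LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.provenance is None:
            self.provenance = (
                PROVENANCE_RAW_LINEAR if self.scale == SCALE_LINEAR else PROVENANCE_LOG2
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if self.scale == SCALE_LINEAR and np.nanmin(arr, initial=0.0) < 0:
            bad = self.values.columns[(self.values < 0).any(axis=0)].tolist()
            raise ValueError(
                f"linear-scale matrix contains negative values (samples: {bad})"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)].copy(), self.scale, self.provenance
        )

    def subset_proteins(self, protein_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(protein_ids)].copy(), self.scale, self.provenance
        )


@dataclass
class SampleTable:
    """Per-sample annotations: group, processing-date batch, subject, timepoint.

    ``group`` labels come from a declared vocabulary (healthy plus patient
    disease labels); ``batch`` is the sample-processing date used either for
    blocking (differential expression) or ComBat adjustment (visualisation).
    """

    data: pd.DataFrame
    group_vocabulary: Optional[frozenset[str]] = None

    REQUIRED = ("sample_id", "group", "batch")
    OPTIONAL = ("subject_id", "timepoint")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"{col} required in sample table")
        if self.data["sample_id"].duplicated().any():
            dups = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {dups.tolist()}")
        for col in self.OPTIONAL:
            if col not in self.data.columns:
                self.data[col] = pd.NA
        if self.group_vocabulary is not None:
            unknown = set(self.data["group"]) - set(self.group_vocabulary)
            if unknown:
                raise ValueError(f"group labels outside vocabulary: {sorted(unknown)}")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def samples_in_group(self, group: str) -> list[str]:
        return self.data.loc[self.data["group"] == group, "sample_id"].tolist()

    def samples_for_subject(self, subject_id: str) -> list[str]:
        return self.data.loc[
            self.data["subject_id"] == subject_id, "sample_id"
        ].tolist()

    def batch_of(self) -> pd.Series:
        """sample_id → batch label."""
        return self.data.set_index("sample_id")["batch"]

    def group_of(self) -> pd.Series:
        return self.data.set_index("sample_id")["group"]

    def group_counts(self) -> dict[str, int]:
        return self.data["group"].value_counts().to_dict()


class PeptideSupport(dict):
    """protein_id → number of peptides supporting the quantitation (≥ 1)."""

    def __init__(self, mapping: Mapping[str, int]):
        bad = {k: v for k, v in mapping.items() if int(v) < 1}
        if bad:
            raise ValueError(f"peptide counts must be >= 1, got {bad}")
        super().__init__({k: int(v) for k, v in mapping.items()})

    def covers(self, protein_ids: Iterable[str]) -> bool:
        return all(p in self for p in protein_ids)


@dataclass
class ProteinAnnotation:
    """Static per-protein annotation used by the proteomic ruler."""

    protein_id: str
    gene_symbol: str
    molecular_weight: Optional[float] = None  # Da, average isotopic
    is_histone: bool = False
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise ValueError(
                f"{self.protein_id}: molecular weight must be positive"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO BP terms from a GMT file)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        seen: list[str] = []
        for m in members:
            if m and m not in seen:
                seen.append(m)
        if not seen:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = (description, tuple(seen))

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)
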