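"""Core in-memory containers shared across the pipeline.

The pipeline moves between two representations of a breath-sampling study:

* :class:`PeakTable` — one analytical run (a breath sample, a QC tube or a
  blank) as a list of detected chromatographic peaks, each with a retention
  time in minutes and an integrated area.
* :class:`AbundanceMatrix` — the curated samples x features table, with
  per-sample metadata (subject, day, analytical batch) and a per-cell
  missingness status distinguishing genuinely observed values, values filled
  at the limit of detection, and non-LOD missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# Cell status codes for AbundanceMatrix.status
OBSERVED = "observed"
LOD_FILLED = "lod_filled"
NON_LOD_MISSING = "non_lod_missing"
STATUS_CODES = (OBSERVED, LOD_FILLED, NON_LOD_MISSING)

ROLE_BREATH = "breath"
ROLE_QC = "qc"
ROLE_BLANK = "blank"
ROLES = (ROLE_BREATH, ROLE_QC, ROLE_BLANK)


@dataclass
class PeakTable:
    """Detected peaks of a single analytical run.

    ``peaks`` has columns ``compound_id`` (may be empty strings for untargeted
    breath peaks), ``retention_time_min`` and ``area``.  An ``area`` of NaN
    flags a peak that could not be reliably quantified for reasons other than
    the limit of detection (e.g. interference from a neighbouring peak); the
    matrix assembler turns these into non-LOD missing cells.
    """

    sample_id: str
    role: str
    sequence_index: int
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        required = {"compound_id", "retention_time_min", "area"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise ValueError(f"peak table missing columns: {sorted(missing)}")
        rt = self.peaks["retention_time_min"].to_numpy(float)
        if len(rt) and (rt <= 0).any():
            raise ValueError("retention times must be strictly positive")
        area = self.peaks["area"].to_numpy(float)
        if len(area) and (area[~np.isnan(area)] < 0).any():
            raise ValueError("peak areas must be non-negative")

    def copy(self) -> "PeakTable":
        return replace(self, peaks=self.peaks.copy())


@dataclass
class AbundanceMatrix:
    """Samples x features abundance table with metadata and missingness mask.

    ``values``  : DataFrame indexed by sample_id, one column per feature id.
    ``status``  : DataFrame of the same shape holding one of
                  {observed, lod_filled, non_lod_missing} per cell.  Non-LOD
                  missing cells hold NaN in ``values`` until they are either
                  filtered out or imputed by :func:`preprocess.filter_features`.
    ``sample_meta``  : DataFrame indexed by sample_id with at least columns
                  ``subject_id``, ``day``, ``batch``.
    ``feature_meta`` : DataFrame indexed by feature id; optional columns
                  ``tentative_id``, ``chemical_class``, ``reference_rt`` are
                  carried as pass-through annotations.
    """

    values: pd.DataFrame
    status: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.values.columns)
        if self.values.shape != self.status.shape:
            raise ValueError("values and status must have identical shape")
        if not self.values.index.equals(self.status.index) or not self.values.columns.equals(
            self.status.columns
        ):
            raise ValueError("values and status must share index and columns")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match the sample axis")
        for col in ("subject_id", "day", "batch"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")
        bad = ~self.status.isin(STATUS_CODES)
        if bad.to_numpy().any():
            raise ValueError("status cells must be one of " + ", ".join(STATUS_CODES))
        nlm = (self.status == NON_LOD_MISSING).to_numpy()
        present = ~self.values.isna().to_numpy()
        if (present & ~nlm).sum() + nlm.sum() != self.values.size and (
            self.values.isna().to_numpy() & ~nlm
        ).any():
            raise ValueError("NaN values are only allowed in non_lod_missing cells")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def subjects(self) -> pd.Series:
        return self.sample_meta["subject_id"]

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(),
            self.status.copy(),
            self.sample_meta.copy(),
            self.feature_meta.copy(),
        )

    @classmethod
    def from_values(
        cls,
        values: pd.DataFrame,
        sample_meta: pd.DataFrame,
        feature_meta: pd.DataFrame | None = None,
    ) -> "AbundanceMatrix":
        """Wrap a complete matrix, marking every cell as observed."""
        status = pd.DataFrame(OBSERVED, index=values.index, columns=values.columns)
        return cls(values.copy(), status, sample_meta.copy(), feature_meta)


# Clinical tables are plain DataFrames with one row per subject.  These column
# groups drive how the exploratory module correlates them with PC scores.
CLINICAL_CONTINUOUS = [
    "age",
    "bmi",
    "feno_ppb",
    "sputum_eos_pct",
    "sputum_neut_pct",
    "blood_eos",
    "blood_neut",
    "total_ige",
    "acq6",
    "post_bd_fev1_pct",
    "post_bd_fev1_fvc",
    "ics_dose",
    "exacerbations",
]
CLINICAL_BINARY = [
    "female",
    "atopy",
    "nasal_polyps",
    "gord",
    "maintenance_ocs",
    "anti_il5",
    "never_smoker",
]
# Sputum granulocyte percentages are log transformed before correlation.
GRANULOCYTE_COLUMNS = ["sputum_eos_pct", "sputum_neut_pct"]


def validate_clinical(table: pd.DataFrame) -> None:
    """Check invariants of a per-subject clinical table."""
    if "subject_id" not in table.columns:
        raise ValueError("clinical table must have a subject_id column")
    if table["subject_id"].duplicated().any():
        raise ValueError("duplicated subject ids in clinical table")
    for col in GRANULOCYTE_COLUMNS:
        if col in table.columns:
            v = table[col].to_numpy(float)
            if ((v < 0) | (v > 100)).any():
                raise ValueError(f"{col} must lie in [0, 100]")
    if "feno_ppb" in table.columns and (table["feno_ppb"].to_numpy(float) <= 0).any():
        raise ValueError("FeNO must be strictly positive")
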