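"""Cohort record schema for a registry case listing of resected primary
retroperitoneal tumors.

One row per patient: demographic/tumor/treatment covariates, follow-up in
whole months, vital status, and a cause-of-death flag distinguishing
cancer-specific from other-cause deaths.  The canonical in-memory container
is a :class:`pandas.DataFrame` with the columns in :data:`SCHEMA_COLUMNS`;
:class:`SubjectRecord` gives typed row-level access and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Any, Mapping

import pandas as pd

__all__ = [
    "SubjectRecord",
    "SCHEMA_COLUMNS",
    "CATEGORICAL_LEVELS",
    "BOOLEAN_FIELDS",
    "REFERENCE_LEVELS",
    "ANALYSIS_VARIABLES",
    "SchemaError",
    "RecordError",
    "EmptyInputError",
    "validate_cohort",
    "records_to_frame",
    "frame_to_records",
]


class SchemaError(ValueError):
    """A required column is missing or the header cannot be mapped."""


class RecordError(ValueError):
    """A data row violates the record schema; carries the row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


class EmptyInputError(ValueError):
    """The case listing contains a header but no data rows."""


#: Allowed levels per categorical column, in canonical display order.
#: ``unknown`` is a legitimate modelled category for grade, size, marital
#: status and extent of resection, distinct from a truly absent (null) value.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("lt65", "ge65"),
    "sex": ("male", "female"),
    "race": ("white", "black", "api", "other"),
    "marital_status": ("married", "unmarried", "unknown"),
    "fnclcc_grade": ("I", "II", "III", "unknown"),
    "size_class": ("lt5", "s5to10", "s10to15", "ge15", "unknown"),
    "multifocality": ("no", "yes"),
    "histology": ("SFT", "MFHC", "MPNST", "LMS", "DDlipo", "WDlipo", "other"),
    "extent_of_resection": ("complete", "incomplete", "unknown"),
    "vital_status": ("alive", "dead"),
}

BOOLEAN_FIELDS: tuple[str, ...] = (
    "radiation",
    "chemotherapy",
    "chemoradiotherapy",
    "neoadjuvant_radiation",
    "surgery_performed",
    "primary_tumor",
    "cancer_specific_death",
)

SCHEMA_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "age_group",
    "sex",
    "race",
    "marital_status",
    "fnclcc_grade",
    "size_class",
    "multifocality",
    "histology",
    "radiation",
    "chemotherapy",
    "chemoradiotherapy",
    "neoadjuvant_radiation",
    "surgery_performed",
    "primary_tumor",
    "extent_of_resection",
    "followup_months",
    "vital_status",
    "cancer_specific_death",
)

#: Reference level per modelled covariate (the level carrying implicit HR 1).
REFERENCE_LEVELS: dict[str, str] = {
    "age_group": "lt65",
    "sex": "male",
    "race": "white",
    "marital_status": "married",
    "fnclcc_grade": "I",
    "size_class": "lt5",
    "multifocality": "no",
    "histology": "SFT",
    "extent_of_resection": "complete",
    "radiation": "no",
    "chemotherapy": "no",
    "chemoradiotherapy": "no",
}

#: Columns that must be non-null for a record to enter the analysis cohort.
ANALYSIS_VARIABLES: tuple[str, ...] = (
    "age_group",
    "sex",
    "race",
    "marital_status",
    "fnclcc_grade",
    "size_class",
    "multifocality",
    "histology",
    "radiation",
    "chemotherapy",
    "chemoradiotherapy",
    "extent_of_resection",
    "followup_months",
    "vital_status",
)


@dataclass
class SubjectRecord:
    """One patient of the case listing; see module docstring for semantics."""

    subject_id: str
    age_group: str
    sex: str
    race: str
    marital_status: str
    fnclcc_grade: str
    size_class: str
    multifocality: str
    histology: str
    radiation: bool
    chemotherapy: bool
    chemoradiotherapy: bool
    neoadjuvant_radiation: bool
    surgery_performed: bool
    primary_tumor: bool
    extent_of_resection: str
    followup_months: int
    vital_status: str
    cancer_specific_death: bool

    def __post_init__(self) -> None:
        for name, levels in CATEGORICAL_LEVELS.items():
            value = getattr(self, name)
            if value not in levels:
                raise ValueError(f"{name}={value!r} not in {levels}")
        if self.followup_months < 0:
            raise ValueError("followup_months must be non-negative")
        if self.cancer_specific_death and self.vital_status != "dead":
            raise ValueError("cancer_specific_death requires vital_status=dead")
        if self.chemoradiotherapy and not (self.chemotherapy and self.radiation):
            raise ValueError(
                "chemoradiotherapy implies both chemotherapy and radiation"
            )

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_row(cls, row: Mapping[str, Any]) -> "SubjectRecord":
        return cls(**{f.name: row[f.name] for f in fields(cls)})


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Stack records into the canonical cohort DataFrame."""
    return pd.DataFrame([r.to_dict() for r in records], columns=SCHEMA_COLUMNS)


def frame_to_records(cohort: pd.DataFrame) -> list[SubjectRecord]:
    return [SubjectRecord.from_row(row) for row in cohort.to_dict("records")]


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Validate an in-memory cohort against the schema.

    Raises
    ------
    SchemaError
        If a schema column is missing.
    RecordError
        On the first row violating a level set or an invariant; the
        exception carries the positional row index.
    """
    for col in SCHEMA_COLUMNS:
        if col not in cohort.columns:
            raise SchemaError(f"missing column: {col}")
    for name, levels in CATEGORICAL_LEVELS.items():
        bad = ~cohort[name].isna() & ~cohort[name].isin(levels)
        if bad.any():
            i = int(bad.to_numpy().argmax())
            raise RecordError(i, f"{name}={cohort[name].iloc[i]!r} not in {levels}")
    fm = pd.to_numeric(cohort["followup_months"], errors="coerce")
    neg = fm.notna() & (fm < 0)
    if neg.any():
        i = int(neg.to_numpy().argmax())
        raise RecordError(i, "followup_months must be non-negative")
    csd = cohort["cancer_specific_death"].fillna(False).astype(bool)
    bad = csd & (cohort["vital_status"] != "dead")
    if bad.any():
        i = int(bad.to_numpy().argmax())
        raise RecordError(i, "cancer_specific_death requires vital_status=dead")
    crt = cohort["chemoradiotherapy"].fillna(False).astype(bool)
    bad = crt & ~(
        cohort["chemotherapy"].fillna(False).astype(bool)
        & cohort["radiation"].fillna(False).astype(bool)
    )
    if bad.any():
        i = int(bad.to_numpy().argmax())
        raise RecordError(i, "chemoradiotherapy implies chemotherapy and radiation")
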