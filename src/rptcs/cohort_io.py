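"""Reading, writing and filtering registry case listings.

The expected input is a flat CSV export in the shape of a SEER*Stat case
listing: a header row and one row per patient.  Column names vary between
export versions, so a *dialect* maps schema fields to CSV headers; the
default dialect matches the output of :mod:`rptcs.synthetic`.

The inclusion chain reproduces the usual selection discipline for this
cohort: primary tumors only, no neoadjuvant radiotherapy, surgically
resected, and complete analysis variables.  Records whose grade, size,
marital status or extent of resection carry the explicit ``unknown`` level
are retained — those are modelled categories — whereas truly absent (null)
values cause exclusion at the completeness step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .records import (
    ANALYSIS_VARIABLES,
    BOOLEAN_FIELDS,
    CATEGORICAL_LEVELS,
    SCHEMA_COLUMNS,
    EmptyInputError,
    RecordError,
    SchemaError,
    validate_cohort,
)

__all__ = [
    "Dialect",
    "DEFAULT_DIALECT",
    "AttritionStep",
    "AttritionReport",
    "read_case_listing",
    "write_case_listing",
    "apply_inclusion_filters",
]

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping from schema fields to CSV headers.

    ``coerce_unrecognized=True`` routes categorical values outside the
    schema's level sets to that column's ``unknown`` (or ``other``) level;
    by default they are a row-level error.
    """

    columns: Mapping[str, str]
    coerce_unrecognized: bool = False

    @classmethod
    def identity(cls) -> "Dialect":
        return cls(columns={c: c for c in SCHEMA_COLUMNS})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        spec = yaml.safe_load(Path(path).read_text())
        return cls(
            columns=spec["columns"],
            coerce_unrecognized=bool(spec.get("coerce_unrecognized", False)),
        )


DEFAULT_DIALECT = Dialect.identity()

# case-insensitive lookup per categorical column
_LEVEL_LOOKUP = {
    col: {lv.lower(): lv for lv in levels}
    for col, levels in CATEGORICAL_LEVELS.items()
}


def _parse_bool(raw: object, col: str, row: int) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise RecordError(row, f"cannot parse boolean {col}={raw!r}")


def read_case_listing(
    path: str | Path, dialect: Dialect | str = "default"
) -> pd.DataFrame:
    """Read a case-listing CSV into a validated cohort DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row (RFC-4180, UTF-8).
    dialect
        A :class:`Dialect`, the string ``"default"``, or a path to a YAML
        dialect file.

    Raises
    ------
    SchemaError
        A mapped column is absent from the header.
    EmptyInputError
        The file holds no data rows.
    RecordError
        A cell cannot be normalized to the schema (with its row index).
    """
    if isinstance(dialect, str):
        dialect = DEFAULT_DIALECT if dialect == "default" else Dialect.from_yaml(dialect)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for field_name in SCHEMA_COLUMNS:
        src = dialect.columns.get(field_name, field_name)
        if src not in raw.columns:
            raise SchemaError(f"missing column: {src} (field {field_name})")
    if len(raw) == 0:
        raise EmptyInputError(f"no data rows in {path}")

    out: dict[str, object] = {}
    out["subject_id"] = raw[dialect.columns["subject_id"]].astype(str)
    for col, lookup in _LEVEL_LOOKUP.items():
        values = raw[dialect.columns.get(col, col)].str.strip()
        normalized = values.str.lower().map(lookup)
        missing = values == ""
        bad = normalized.isna() & ~missing
        if bad.any():
            i = int(bad.to_numpy().argmax())
            if dialect.coerce_unrecognized:
                levels = CATEGORICAL_LEVELS[col]
                sink = "unknown" if "unknown" in levels else (
                    "other" if "other" in levels else None
                )
                if sink is None:
                    raise RecordError(i, f"unrecognized {col}={values.iloc[i]!r}")
                normalized = normalized.where(~bad, sink)
            else:
                raise RecordError(i, f"unrecognized {col}={values.iloc[i]!r}")
        out[col] = normalized.where(~missing, None)
    for col in BOOLEAN_FIELDS:
        values = raw[dialect.columns.get(col, col)].str.strip()
        out[col] = [
            _parse_bool(v, col, i) if v != "" else None
            for i, v in enumerate(values)
        ]
    fm_raw = raw[dialect.columns.get("followup_months", "followup_months")].str.strip()
    fm = pd.to_numeric(fm_raw, errors="coerce")
    bad = fm.isna() & (fm_raw != "")
    if bad.any():
        i = int(bad.to_numpy().argmax())
        raise RecordError(i, f"unparseable followup_months={fm_raw.iloc[i]!r}")
    neg = fm.notna() & (fm < 0)
    if neg.any():
        i = int(neg.to_numpy().argmax())
        raise RecordError(i, f"negative followup_months={fm_raw.iloc[i]!r}")
    out["followup_months"] = fm.astype("Int64")

    cohort = pd.DataFrame(out, columns=SCHEMA_COLUMNS)
    validate_cohort(cohort)
    return cohort


def write_case_listing(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort to CSV in the default dialect (lossless round-trip)."""
    cohort.to_csv(path, index=False)


@dataclass(frozen=True)
class AttritionStep:
    criterion_label: str
    n_before: int
    n_excluded: int
    n_after: int


@dataclass
class AttritionReport:
    """Ordered record of the inclusion chain, one step per criterion."""

    steps: list[AttritionStep] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return self.steps[0].n_before if self.steps else 0

    @property
    def n_output(self) -> int:
        return self.steps[-1].n_after if self.steps else 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            [s.__dict__ for s in self.steps], indent=2, sort_keys=True
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def to_text(self) -> str:
        width = max((len(s.criterion_label) for s in self.steps), default=9)
        lines = [
            f"{'criterion':<{width}}  before  excluded  after",
        ]
        for s in self.steps:
            lines.append(
                f"{s.criterion_label:<{width}}  {s.n_before:>6}  {s.n_excluded:>8}  {s.n_after:>5}"
            )
        return "\n".join(lines)


_FILTER_CHAIN: tuple[tuple[str, str], ...] = (
    ("primary tumor", "primary_tumor"),
    ("no neoadjuvant radiation", "neoadjuvant_radiation"),
    ("surgery performed", "surgery_performed"),
)


def apply_inclusion_filters(
    cohort: pd.DataFrame,
) -> tuple[pd.DataFrame, AttritionReport]:
    """Apply the inclusion chain in order and report attrition per step.

    Steps: (1) primary tumors only; (2) no neoadjuvant radiotherapy;
    (3) surgery performed; (4) complete analysis variables (explicit
    ``unknown`` levels are retained, nulls are dropped).
    """
    report = AttritionReport()
    current = cohort
    for label, flag in _FILTER_CHAIN:
        want = flag != "neoadjuvant_radiation"
        keep = current[flag].fillna(not want).astype(bool) == want
        nxt = current[keep]
        report.steps.append(
            AttritionStep(label, len(current), int((~keep).sum()), len(nxt))
        )
        current = nxt
    complete = current[list(ANALYSIS_VARIABLES)].notna().all(axis=1)
    nxt = current[complete]
    report.steps.append(
        AttritionStep(
            "complete analysis variables",
            len(current),
            int((~complete).sum()),
            len(nxt),
        )
    )
    return nxt.reset_index(drop=True), report
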