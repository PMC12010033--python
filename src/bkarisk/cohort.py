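"""Strict CSV schema for patient cohorts.

One row per patient.  Booleans are encoded 0/1, mobilization as the literal
strings ``early``/``late``/``bedridden``.  ``days_to_death`` is empty for
one-year survivors; the six Katz component columns are either all filled
(0/1) or all empty — a partially filled Katz tuple is invalid, and missing
is distinct from zero.  Reading validates every row; writing is the exact
inverse, so a cohort round-trips field-for-field.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .errors import SchemaError, ValidationError
from .scoring import (
    KATZ_ACTIVITIES,
    Comorbidity,
    Mobilization,
    PatientRecord,
)

__all__ = [
    "SCHEMA_VERSION",
    "COLUMNS",
    "CohortTable",
    "ValidationReport",
    "read_cohort",
    "write_cohort",
]

SCHEMA_VERSION = "1.0"

_COMORBIDITY_COLUMNS = {
    "copd": Comorbidity.COPD,
    "hypertension": Comorbidity.HYPERTENSION,
    "diabetes_mellitus": Comorbidity.DIABETES_MELLITUS,
    "prior_mi": Comorbidity.PRIOR_MI,
    "prior_stroke": Comorbidity.PRIOR_STROKE,
    "prior_limb_infection": Comorbidity.PRIOR_LIMB_INFECTION,
}
_KATZ_COLUMNS = tuple(f"katz_{a}" for a in KATZ_ACTIVITIES)

COLUMNS = (
    "patient_id",
    "age_years",
    *_COMORBIDITY_COLUMNS,
    "mobilization",
    "hypoxia",
    "metabolic_disorder",
    "died_within_1yr",
    "days_to_death",
    *_KATZ_COLUMNS,
    "postop_comorbidity",
    "prosthetic_usage",
    "wound_complication",
)


@dataclass(frozen=True)
class CohortTable:
    """An ordered collection of validated patient records."""

    records: tuple
    source: str = "unknown"
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class ValidationReport:
    """Row-level problems found while reading a cohort file."""

    row_errors: list = field(default_factory=list)  # (row, field, message)
    n_accepted: int = 0
    n_rejected: int = 0

    @property
    def ok(self) -> bool:
        return not self.row_errors


def _parse_bool(raw: str, column: str) -> bool:
    if raw == "0":
        return False
    if raw == "1":
        return True
    raise ValidationError(f"{column}: expected 0 or 1, got {raw!r}")


def _parse_int(raw: str, column: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ValidationError(f"{column}: expected an integer, got {raw!r}") from None


def _parse_row(row: dict) -> PatientRecord:
    age = _parse_int(row["age_years"], "age_years")
    comorbidities = frozenset(
        cond
        for col, cond in _COMORBIDITY_COLUMNS.items()
        if _parse_bool(row[col], col)
    )
    raw_days = row["days_to_death"].strip()
    days = _parse_int(raw_days, "days_to_death") if raw_days else None

    katz_raw = [row[c].strip() for c in _KATZ_COLUMNS]
    if all(v == "" for v in katz_raw):
        katz = None
    elif all(v != "" for v in katz_raw):
        katz = tuple(
            _parse_bool(v, c) for v, c in zip(katz_raw, _KATZ_COLUMNS)
        )
    else:
        missing = [c for v, c in zip(katz_raw, _KATZ_COLUMNS) if v == ""]
        raise ValidationError(
            f"katz components partially filled (missing {missing}); "
            "provide all six or none"
        )

    return PatientRecord(
        patient_id=row["patient_id"],
        age_years=age,
        comorbidities=comorbidities,
        mobilization=Mobilization.coerce(row["mobilization"]),
        hypoxia=_parse_bool(row["hypoxia"], "hypoxia"),
        metabolic_disorder=_parse_bool(
            row["metabolic_disorder"], "metabolic_disorder"
        ),
        died_within_1yr=_parse_bool(row["died_within_1yr"], "died_within_1yr"),
        days_to_death=days,
        katz_components=katz,
        postop_comorbidity=_parse_bool(
            row["postop_comorbidity"], "postop_comorbidity"
        ),
        prosthetic_usage=_parse_bool(row["prosthetic_usage"], "prosthetic_usage"),
        wound_complication=_parse_bool(
            row["wound_complication"], "wound_complication"
        ),
    )


def read_cohort(path, strict: bool = False):
    """Read and validate a cohort CSV.

    Returns ``(CohortTable, ValidationReport)``.  In strict mode any invalid
    row raises; in lenient mode invalid rows are dropped and reported.
    Row numbers in the report are 1-based over data rows (header excluded).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
        records = []
        report = ValidationReport()
        for row_no, row in enumerate(reader, start=1):
            try:
                records.append(_parse_row(row))
                report.n_accepted += 1
            except ValidationError as exc:
                message = str(exc)
                fieldname = message.split(":", 1)[0] if ":" in message else ""
                if strict:
                    raise ValidationError(
                        f"{path} row {row_no}: {message}"
                    ) from exc
                report.row_errors.append((row_no, fieldname, message))
                report.n_rejected += 1
    table = CohortTable(records=tuple(records), source=str(path))
    return table, report


def _format_record(record: PatientRecord) -> dict:
    row = {
        "patient_id": record.patient_id,
        "age_years": str(record.age_years),
        "mobilization": record.mobilization.value,
        "hypoxia": str(int(record.hypoxia)),
        "metabolic_disorder": str(int(record.metabolic_disorder)),
        "died_within_1yr": str(int(record.died_within_1yr)),
        "days_to_death": (
            "" if record.days_to_death is None else str(record.days_to_death)
        ),
        "postop_comorbidity": str(int(record.postop_comorbidity)),
        "prosthetic_usage": str(int(record.prosthetic_usage)),
        "wound_complication": str(int(record.wound_complication)),
    }
    for col, cond in _COMORBIDITY_COLUMNS.items():
        row[col] = str(int(cond in record.comorbidities))
    if record.katz_components is None:
        row.update({c: "" for c in _KATZ_COLUMNS})
    else:
        row.update(
            {c: str(int(v)) for c, v in zip(_KATZ_COLUMNS, record.katz_components)}
        )
    return row


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort to CSV in the canonical column order (RFC-4180)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(COLUMNS))
        writer.writeheader()
        for record in cohort:
            writer.writerow(_format_record(record))
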