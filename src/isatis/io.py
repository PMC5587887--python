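"""Cohort file round-trip: one CSV/TSV row per patient.

Layout: covariate columns (``patient_id``, ``arm``, ``los_days``, ``sex``,
``age_years``, ``relationship``, ``education``, ``activity``, ``insurance``,
``delay_days``) followed by one column per questionnaire item (``Q1``..).
Item columns hold the raw 0..10 answer code; an empty cell means the item
was left unanswered.  The delimiter (comma or tab) is sniffed from the
header line; encoding is UTF-8 with "." as the decimal mark.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable

from .questionnaire import VALID_CODES, QuestionnaireSpec, default_isatis_spec
from .scoring import PatientRecord

__all__ = ["COVARIATE_COLUMNS", "read_cohort", "write_cohort"]

COVARIATE_COLUMNS = (
    "patient_id",
    "arm",
    "los_days",
    "sex",
    "age_years",
    "relationship",
    "education",
    "activity",
    "insurance",
    "delay_days",
)


class CohortFileError(ValueError):
    """Malformed cohort file; the message names the offending line/cell."""


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def write_cohort(
    records: Iterable[PatientRecord],
    path: str | Path,
    spec: QuestionnaireSpec | None = None,
    delimiter: str = ",",
) -> None:
    spec = spec or default_isatis_spec()
    item_cols = list(spec.all_items)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(list(COVARIATE_COLUMNS) + item_cols)
        for rec in records:
            delay = "" if rec.delay_days is None else _fmt_num(rec.delay_days)
            row = [
                rec.patient_id,
                rec.arm,
                str(rec.los_days),
                rec.sex,
                _fmt_num(rec.age_years),
                rec.relationship,
                rec.education,
                rec.activity,
                rec.insurance,
                delay,
            ]
            row += [
                "" if (c := rec.responses.get(item)) is None else str(c)
                for item in item_cols
            ]
            w.writerow(row)


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_cohort(
    path: str | Path, spec: QuestionnaireSpec | None = None
) -> list[PatientRecord]:
    """Read a cohort file, validating codes cell by cell.

    Raises
    ------
    CohortFileError
        Naming the line number and cell for any unparsable or
        out-of-range value.
    """
    spec = spec or default_isatis_spec()
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise CohortFileError(f"{path}: empty file (no header)")
    delim = _sniff_delimiter(lines[0])
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    header = reader.fieldnames or []
    missing = [c for c in COVARIATE_COLUMNS if c not in header]
    if missing:
        raise CohortFileError(f"{path}: missing columns {missing}")
    item_cols = [c for c in header if c in set(spec.all_items)]

    records: list[PatientRecord] = []
    for lineno, row in enumerate(reader, start=2):
        responses: dict[str, int] = {}
        for item in item_cols:
            cell = (row.get(item) or "").strip()
            if not cell:
                continue
            try:
                code = int(cell)
            except ValueError:
                raise CohortFileError(
                    f"{path}:{lineno}: column {item}: not an integer: {cell!r}"
                ) from None
            if code not in VALID_CODES:
                raise CohortFileError(
                    f"{path}:{lineno}: column {item}: code {code} outside 0..10"
                )
            responses[item] = code
        delay_cell = (row.get("delay_days") or "").strip()
        try:
            delay = float(delay_cell) if delay_cell else None
            rec = PatientRecord(
                patient_id=row["patient_id"],
                arm=row["arm"],
                los_days=int(row["los_days"]),
                sex=row["sex"],
                age_years=float(row["age_years"]),
                relationship=row["relationship"],
                education=row["education"],
                activity=row["activity"],
                insurance=row["insurance"],
                delay_days=delay,
                responses=responses,
            )
        except ValueError as exc:
            raise CohortFileError(f"{path}:{lineno}: {exc}") from exc
        if delay is not None and math.isnan(delay):
            raise CohortFileError(f"{path}:{lineno}: delay_days is NaN")
        records.append(rec)
    return records
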