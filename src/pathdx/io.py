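"""Reading and writing the package's delimited-table formats.

All tables are UTF-8 CSV with a header row; dates are ISO-8601 (YYYY-MM-DD).

* ``patients.csv`` — ``patient_id,birth_date,sex,ethnicity``
* ``events.csv`` — ``patient_id,event_date,raw_code``
* ``codemap.csv`` — ``raw_code,group_id,group_label,category,is_administrative``
* code-list files — one code per line, ``#`` starts a comment

Readers validate eagerly and raise :class:`SchemaError` naming the first
offending row (0-based data-row index, i.e. not counting the header).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = ("patient_id", "birth_date", "sex", "ethnicity")
EVENT_COLUMNS = ("patient_id", "event_date", "raw_code")


class SchemaError(ValueError):
    """A file does not match the expected schema.

    Attributes
    ----------
    row : int | None
        0-based index of the first offending data row, if applicable.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographic row."""

    patient_id: str
    birth_date: date
    sex: str
    ethnicity: str


@dataclass(frozen=True)
class EventRecord:
    """One coded clinical event (visit, symptom, test, prescription ...)."""

    patient_id: str
    event_date: date
    raw_code: str


def _parse_iso_date(text: str, row: int, column: str) -> date:
    try:
        return date.fromisoformat(text)
    except ValueError:
        raise SchemaError(
            f"column {column!r}: unparseable ISO-8601 date {text!r}", row=row
        ) from None


def _open_rows(path: str | Path, required: tuple[str, ...]) -> Iterator[dict]:
    """Yield per-row dicts restricted to ``required`` columns.

    Unknown columns are tolerated (logged once); missing required columns are
    a SchemaError. Streaming: rows are yielded as parsed, memory is bounded.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames
        if header is None:
            raise SchemaError(f"{path}: empty file, expected header {required}")
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        extra = [c for c in header if c not in required]
        if extra:
            logger.warning("%s: ignoring unknown column(s) %s", path, extra)
        for i, row in enumerate(reader):
            yield {c: (row[c] if row[c] is not None else "") for c in required} | {
                "_row": i
            }


def iter_events(path: str | Path) -> Iterator[EventRecord]:
    """Stream :class:`EventRecord` rows from ``events.csv`` in file order."""
    for row in _open_rows(path, EVENT_COLUMNS):
        i = row["_row"]
        if not row["raw_code"]:
            raise SchemaError("empty raw_code", row=i)
        if not row["patient_id"]:
            raise SchemaError("empty patient_id", row=i)
        yield EventRecord(
            patient_id=row["patient_id"],
            event_date=_parse_iso_date(row["event_date"], i, "event_date"),
            raw_code=row["raw_code"],
        )


def read_events(path: str | Path) -> list[EventRecord]:
    """Read all events, preserving row order."""
    return list(iter_events(path))


def read_patients(path: str | Path) -> list[PatientRecord]:
    """Read ``patients.csv``; duplicate patient ids are a SchemaError."""
    out: list[PatientRecord] = []
    seen: set[str] = set()
    for row in _open_rows(path, PATIENT_COLUMNS):
        i = row["_row"]
        pid = row["patient_id"]
        if not pid:
            raise SchemaError("empty patient_id", row=i)
        if pid in seen:
            raise SchemaError(f"duplicate patient_id {pid!r}", row=i)
        seen.add(pid)
        out.append(
            PatientRecord(
                patient_id=pid,
                birth_date=_parse_iso_date(row["birth_date"], i, "birth_date"),
                sex=row["sex"],
                ethnicity=row["ethnicity"],
            )
        )
    return out


def write_events(path: str | Path, events: Iterable[EventRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for e in events:
            w.writerow([e.patient_id, e.event_date.isoformat(), e.raw_code])


def write_patients(path: str | Path, patients: Iterable[PatientRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PATIENT_COLUMNS)
        for p in patients:
            w.writerow([p.patient_id, p.birth_date.isoformat(), p.sex, p.ethnicity])


def read_code_list(path: str | Path) -> list[str]:
    """Read a one-code-per-line file; '#' comments and blank lines skipped."""
    codes: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            codes.append(line)
    return codes


def write_code_list(path: str | Path, codes: Iterable[str], comment: str = "") -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for c in codes:
            fh.write(f"{c}\n")
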