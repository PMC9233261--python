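"""Reading and writing clinical-note corpora in plain-text formats.

A corpus is an ordered collection of :class:`Note` records. JSONL (one UTF-8
JSON object per line) is the canonical format because note text contains
arbitrary punctuation and newlines; CSV (RFC-4180 quoting) is provided for
convenience. Note text is stored verbatim — no case folding at rest — and
all downstream character offsets are 0-based half-open spans over that
verbatim text.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Iterable, Sequence

#: Closed vocabulary of note types: inpatient history & physical, ambulatory
#: progress, emergency/urgent-care progress, inpatient consult, inpatient
#: discharge summary, inpatient progress.
NOTE_TYPES = ("hp", "apn", "epn", "icn", "ids", "ipn")
PROVIDER_TYPES = ("resident", "fellow", "attending", "app")
SETTINGS = ("ambulatory", "emergency", "inpatient")

AGE_MIN, AGE_MAX = 0, 21

# Synonyms normalized at read time so stratification keys are stable.
_NOTE_TYPE_SYNONYMS = {
    "h&p": "hp", "hnp": "hp", "history and physical": "hp",
    "ambulatory progress note": "apn",
    "emergency progress note": "epn", "urgent care progress note": "epn",
    "inpatient consult note": "icn", "consult": "icn",
    "inpatient discharge summary": "ids", "discharge summary": "ids",
    "inpatient progress note": "ipn",
}
_PROVIDER_SYNONYMS = {
    "advanced practice provider": "app",
    "nurse practitioner": "app",
    "physician assistant": "app",
}
_SETTING_SYNONYMS = {
    "ambulatory care": "ambulatory",
    "emergency care": "emergency",
    "inpatient care": "inpatient",
}


class CorpusError(Exception):
    """Base class for corpus I/O failures."""


class SchemaError(CorpusError):
    """A required field/column is missing."""


class ValidationError(CorpusError):
    """A field value violates a Note invariant."""


@dataclass
class Note:
    """One clinical note: verbatim free text plus encounter metadata."""

    note_id: str
    patient_id: str
    text: str
    note_type: str
    age_years: int
    provider_type: str
    setting: str
    specialty: str

    def __post_init__(self) -> None:
        self.note_type = _canon(self.note_type, NOTE_TYPES, _NOTE_TYPE_SYNONYMS,
                                "note_type")
        self.provider_type = _canon(self.provider_type, PROVIDER_TYPES,
                                    _PROVIDER_SYNONYMS, "provider_type")
        self.setting = _canon(self.setting, SETTINGS, _SETTING_SYNONYMS,
                              "setting")
        if not isinstance(self.age_years, int) or isinstance(self.age_years, bool):
            try:
                self.age_years = int(str(self.age_years))
            except (TypeError, ValueError):
                raise ValidationError(
                    f"age_years: not an integer: {self.age_years!r}") from None
        if not (AGE_MIN <= self.age_years <= AGE_MAX):
            raise ValidationError(
                f"age_years: {self.age_years} outside allowed range "
                f"{AGE_MIN}-{AGE_MAX}")
        if not self.note_id:
            raise ValidationError("note_id: must be nonempty")


def _canon(value: str, allowed: Sequence[str], synonyms: dict[str, str],
           field: str) -> str:
    v = str(value).strip().lower()
    v = synonyms.get(v, v)
    if v not in allowed:
        raise ValidationError(
            f"{field}: unknown value {value!r}; allowed: {', '.join(allowed)}")
    return v


_FIELDS = [f.name for f in fields(Note)]


def _infer_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        if format not in ("jsonl", "csv"):
            raise ValueError(f"unknown format {format!r}; use 'jsonl' or 'csv'")
        return format
    suffix = Path(path).suffix.lower()
    return "csv" if suffix == ".csv" else "jsonl"


def read_notes(path: str | Path, format: str | None = None) -> list[Note]:
    """Read a corpus, preserving record order.

    Every record is validated against the Note invariants; a missing field
    raises :class:`SchemaError` and an invalid value raises
    :class:`ValidationError`, both naming the offending field and line.
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    notes: list[Note] = []
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"line {lineno}: invalid JSON: {exc}") from None
                notes.append(_note_from_mapping(obj, lineno))
    else:
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            missing = [f for f in _FIELDS if f not in reader.fieldnames]
            if missing:
                raise SchemaError(f"header: missing column(s) {', '.join(missing)}")
            for lineno, row in enumerate(reader, start=2):
                notes.append(_note_from_mapping(row, lineno))
    return notes


def _note_from_mapping(obj: dict, lineno: int) -> Note:
    missing = [f for f in _FIELDS if f not in obj or obj[f] is None]
    if missing:
        raise SchemaError(f"line {lineno}: missing field(s) {', '.join(missing)}")
    try:
        return Note(**{f: obj[f] for f in _FIELDS})
    except ValidationError as exc:
        raise ValidationError(f"line {lineno}: {exc}") from None


def write_notes(notes: Iterable[Note], path: str | Path,
                format: str | None = None) -> Path:
    """Write a corpus; ``read_notes(write_notes(x))`` reproduces x exactly."""
    fmt = _infer_format(path, format)
    path = Path(path)
    notes = list(notes)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for note in notes:
                fh.write(json.dumps(asdict(note), ensure_ascii=False) + "\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS)
            writer.writeheader()
            for note in notes:
                writer.writerow(asdict(note))
    return path


def notes_to_jsonl_str(notes: Iterable[Note]) -> str:
    """Serialize notes to a JSONL string (used for byte-identity checks)."""
    buf = io.StringIO()
    for note in notes:
        buf.write(json.dumps(asdict(note), ensure_ascii=False) + "\n")
    return buf.getvalue()
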