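"""Domain types, delimited-file readers/writers and ICD-10 cause groups.

Files are plain delimited text (comma by default, tab accepted) with a
header row.  Tri-state status fields are encoded ``"1"`` / ``"0"`` / empty
string for yes / no / missing.  Dates are ISO-8601 (``YYYY-MM-DD``).
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TriState",
    "Sex",
    "Remoteness",
    "Source",
    "DeathRecord",
    "LinkedRecord",
    "CauseGroup",
    "CANCER",
    "CARDIOVASCULAR",
    "EXTERNAL",
    "BUILTIN_CAUSE_GROUPS",
    "RecordValidationError",
    "icd10_in_range",
    "classify_cause",
    "read_deaths",
    "write_deaths",
    "read_linked_records",
    "write_linked_records",
]


class TriState(str, Enum):
    """Yes / no / missing status value."""

    YES = "yes"
    NO = "no"
    MISSING = "missing"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Remoteness(str, Enum):
    """ARIA+ style five-category remoteness, plus Unknown for unassignable."""

    MAJOR_CITIES = "MajorCities"
    INNER_REGIONAL = "InnerRegional"
    OUTER_REGIONAL = "OuterRegional"
    REMOTE = "Remote"
    VERY_REMOTE = "VeryRemote"
    UNKNOWN = "Unknown"


class Source(str, Enum):
    """Linked-record source dataset codes."""

    APD = "APD"
    EDDC = "EDDC"
    PDC_MOTHER = "PDC_mother"
    PDC_INFANT = "PDC_infant"
    RBDM_MOTHER = "RBDM_mother"
    RBDM_INFANT = "RBDM_infant"


class RecordValidationError(ValueError):
    """Raised when a record violates a field invariant.

    ``line`` is the 1-based line number in the source file when the record
    came from a file, else ``None``.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]{1,2})?$")


@dataclass(frozen=True)
class DeathRecord:
    """One registered death: demographics, underlying cause and reported status."""

    death_id: str
    age_years: int
    sex: Sex
    remoteness: Remoteness
    cause_icd10: str
    reported_indigenous: TriState

    def __post_init__(self) -> None:
        if not (0 <= self.age_years <= 130):
            raise RecordValidationError(
                f"age_years {self.age_years!r} outside [0, 130] for death {self.death_id!r}"
            )
        if not _ICD10_RE.match(self.cause_icd10):
            raise RecordValidationError(
                f"malformed ICD-10 code {self.cause_icd10!r} for death {self.death_id!r}"
            )


_APD_ONLY_FIELDS = ("admit_date", "discharge_date", "facility", "transferred_from", "transferred_to")


@dataclass(frozen=True)
class LinkedRecord:
    """One linked administrative record for a person.

    Episode dates and transfer/facility fields are only permitted on
    hospital (APD) rows; parental status flags carry information only on
    infant birth-related rows.
    """

    record_id: str
    death_id: str
    source: Source
    indigenous_flag: TriState
    mother_indigenous_flag: TriState = TriState.MISSING
    father_indigenous_flag: TriState = TriState.MISSING
    admit_date: _dt.date | None = None
    discharge_date: _dt.date | None = None
    facility: str | None = None
    transferred_from: str | None = None
    transferred_to: str | None = None

    def __post_init__(self) -> None:
        if self.source is Source.APD:
            if self.admit_date is None or self.discharge_date is None:
                raise RecordValidationError(
                    f"APD record {self.record_id!r} requires admit_date and discharge_date"
                )
            if self.admit_date > self.discharge_date:
                raise RecordValidationError(
                    f"APD record {self.record_id!r} has admit_date after discharge_date"
                )
        else:
            for name in _APD_ONLY_FIELDS:
                if getattr(self, name) is not None:
                    raise RecordValidationError(
                        f"{self.source.value} record {self.record_id!r} must not set {name}"
                    )


# --------------------------------------------------------------------------
# ICD-10 cause grouping
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CauseGroup:
    """A named ICD-10 range set; membership by 3-character code order."""

    name: str
    ranges: tuple[tuple[str, str], ...] = field(default=())


CANCER = CauseGroup("cancer", (("C00", "C97"),))
CARDIOVASCULAR = CauseGroup("cardiovascular", (("I00", "I99"),))
EXTERNAL = CauseGroup("external", (("V01", "Y98"),))
OTHER = CauseGroup("other", ())

BUILTIN_CAUSE_GROUPS: tuple[CauseGroup, ...] = (CANCER, CARDIOVASCULAR, EXTERNAL)


def _code_key(code3: str) -> tuple[str, int]:
    return code3[0], int(code3[1:3])


def icd10_in_range(code: str, group: CauseGroup) -> bool:
    """True iff ``code`` falls in one of ``group``'s inclusive ICD-10 ranges.

    Decimal codes (e.g. ``"I21.4"``) are classified by their 3-character
    parent.  Ordering is lexicographic on (letter, 2-digit number), so a
    range such as V01-Y98 spans the letters V, W, X and Y.
    """
    if not _ICD10_RE.match(code):
        raise RecordValidationError(f"malformed ICD-10 code {code!r}")
    key = _code_key(code[:3])
    return any(_code_key(lo) <= key <= _code_key(hi) for lo, hi in group.ranges)


def classify_cause(code: str, groups: Sequence[CauseGroup] = BUILTIN_CAUSE_GROUPS) -> str:
    """Name of the first group containing ``code``, or ``"other"``."""
    for group in groups:
        if icd10_in_range(code, group):
            return group.name
    return OTHER.name


# --------------------------------------------------------------------------
# Delimited-file I/O
# --------------------------------------------------------------------------

_TRISTATE_TO_TEXT = {TriState.YES: "1", TriState.NO: "0", TriState.MISSING: ""}
_TEXT_TO_TRISTATE = {"1": TriState.YES, "0": TriState.NO, "": TriState.MISSING}

DEATHS_COLUMNS = ("death_id", "age_years", "sex", "remoteness", "cause_icd10", "reported_indigenous")
LINKED_COLUMNS = (
    "record_id",
    "death_id",
    "source",
    "indigenous_flag",
    "mother_indigenous_flag",
    "father_indigenous_flag",
    "admit_date",
    "discharge_date",
    "facility",
    "transferred_from",
    "transferred_to",
)


def _parse_tristate(text: str, what: str, line: int) -> TriState:
    try:
        return _TEXT_TO_TRISTATE[text.strip()]
    except KeyError:
        raise RecordValidationError(f"invalid {what} value {text!r} (expect 1/0/blank)", line) from None


def _parse_date(text: str, what: str, line: int) -> _dt.date | None:
    text = text.strip()
    if not text:
        return None
    try:
        return _dt.date.fromisoformat(text)
    except ValueError:
        raise RecordValidationError(f"invalid {what} date {text!r}", line) from None


def _open_reader(path: str | Path, delimiter: str):
    handle = open(path, newline="")
    return handle, csv.DictReader(handle, delimiter=delimiter)


def _check_header(reader: csv.DictReader, required: Iterable[str], path: str | Path) -> None:
    have = set(reader.fieldnames or ())
    missing = [c for c in required if c not in have]
    if missing:
        raise RecordValidationError(f"{path}: missing required column(s) {missing}")


def read_deaths(path: str | Path, delimiter: str = ",") -> list[DeathRecord]:
    """Read a deaths table; raises :class:`RecordValidationError` on bad rows.

    Duplicate ``death_id`` values are a hard error.
    """
    handle, reader = _open_reader(path, delimiter)
    deaths: list[DeathRecord] = []
    seen: set[str] = set()
    with handle:
        _check_header(reader, DEATHS_COLUMNS, path)
        for line, row in enumerate(reader, start=2):
            death_id = row["death_id"].strip()
            if death_id in seen:
                raise RecordValidationError(f"duplicate death_id {death_id!r}", line)
            seen.add(death_id)
            try:
                age = int(row["age_years"])
            except ValueError:
                raise RecordValidationError(f"invalid age_years {row['age_years']!r}", line) from None
            try:
                sex = Sex(row["sex"].strip())
            except ValueError:
                raise RecordValidationError(f"invalid sex {row['sex']!r}", line) from None
            try:
                remoteness = Remoteness(row["remoteness"].strip())
            except ValueError:
                raise RecordValidationError(f"invalid remoteness {row['remoteness']!r}", line) from None
            try:
                deaths.append(
                    DeathRecord(
                        death_id=death_id,
                        age_years=age,
                        sex=sex,
                        remoteness=remoteness,
                        cause_icd10=row["cause_icd10"].strip(),
                        reported_indigenous=_parse_tristate(row["reported_indigenous"], "reported_indigenous", line),
                    )
                )
            except RecordValidationError as exc:
                if exc.line is None:
                    raise RecordValidationError(str(exc), line) from None
                raise
    return deaths


def write_deaths(path: str | Path, deaths: Iterable[DeathRecord], delimiter: str = ",") -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(DEATHS_COLUMNS)
        for d in deaths:
            writer.writerow(
                [
                    d.death_id,
                    d.age_years,
                    d.sex.value,
                    d.remoteness.value,
                    d.cause_icd10,
                    _TRISTATE_TO_TEXT[d.reported_indigenous],
                ]
            )


def read_linked_records(path: str | Path, delimiter: str = ",") -> list[LinkedRecord]:
    """Read a linked-records table.

    ``death_id`` values need not appear in any deaths file (unlinked
    residue is legitimate); structural invariants (APD dates, no dates on
    non-APD rows) are enforced per row.
    """
    handle, reader = _open_reader(path, delimiter)
    records: list[LinkedRecord] = []
    seen: set[str] = set()
    with handle:
        _check_header(reader, ("record_id", "death_id", "source", "indigenous_flag"), path)
        for line, row in enumerate(reader, start=2):
            record_id = row["record_id"].strip()
            if record_id in seen:
                raise RecordValidationError(f"duplicate record_id {record_id!r}", line)
            seen.add(record_id)
            try:
                source = Source(row["source"].strip())
            except ValueError:
                raise RecordValidationError(f"unknown source code {row['source']!r}", line) from None

            def opt(col: str) -> str | None:
                value = (row.get(col) or "").strip()
                return value or None

            try:
                records.append(
                    LinkedRecord(
                        record_id=record_id,
                        death_id=row["death_id"].strip(),
                        source=source,
                        indigenous_flag=_parse_tristate(row["indigenous_flag"], "indigenous_flag", line),
                        mother_indigenous_flag=_parse_tristate(
                            row.get("mother_indigenous_flag", ""), "mother_indigenous_flag", line
                        ),
                        father_indigenous_flag=_parse_tristate(
                            row.get("father_indigenous_flag", ""), "father_indigenous_flag", line
                        ),
                        admit_date=_parse_date(row.get("admit_date", ""), "admit", line),
                        discharge_date=_parse_date(row.get("discharge_date", ""), "discharge", line),
                        facility=opt("facility"),
                        transferred_from=opt("transferred_from"),
                        transferred_to=opt("transferred_to"),
                    )
                )
            except RecordValidationError as exc:
                if exc.line is None:
                    raise RecordValidationError(str(exc), line) from None
                raise
    return records


def write_linked_records(path: str | Path, records: Iterable[LinkedRecord], delimiter: str = ",") -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(LINKED_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.death_id,
                    r.source.value,
                    _TRISTATE_TO_TEXT[r.indigenous_flag],
                    _TRISTATE_TO_TEXT[r.mother_indigenous_flag],
                    _TRISTATE_TO_TEXT[r.father_indigenous_flag],
                    r.admit_date.isoformat() if r.admit_date else "",
                    r.discharge_date.isoformat() if r.discharge_date else "",
                    r.facility or "",
                    r.transferred_from or "",
                    r.transferred_to or "",
                ]
            )
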