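"""Domain types, validation and delimited-text I/O for EQA program data.

An external quality assessment (EQA) session ships a two-specimen panel
(one low and one mid CD4 level) to every registered laboratory.  Each lab
returns, per specimen, percentage and/or absolute values for the CD3, CD4
and CD8 T-cell markers, or declares itself unable to report.  This module
defines the validated in-memory representation of those records and the
comma-delimited file formats used to exchange them.

Submissions file columns (header required)::

    session_id,lab_id,instrument,specimen_id,status,unable_reason,
    receipt_date,analysis_date,cd3_pct,cd3_abs,cd4_pct,cd4_abs,cd8_pct,cd8_abs

Manifest file columns::

    session_id,specimen_id,level

Numeric cells left empty mean "not reported" (0 is a legal count and is
never used as a missing-value sentinel).  Dates are ISO-8601 (YYYY-MM-DD);
any other dialect is rejected.  Parsing follows a partial-load contract:
rows violating a type invariant are rejected with a row-addressed
diagnostic while valid rows are retained.
"""

from __future__ import annotations

import csv
import datetime
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class EqaError(Exception):
    """Base class for all package errors."""


class SchemaError(EqaError):
    """Input file header does not match the documented column schema."""


class DuplicateKeyError(EqaError):
    """Two rows share the same (lab_id, session_id, specimen_id) key."""


class ManifestError(EqaError):
    """Panel manifest violates the two-specimens-per-session contract."""


class ValidationError(EqaError):
    """A record violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Level(str, Enum):
    """CD4 concentration level of a panel specimen."""

    LOW = "low"
    MID = "mid"


class Marker(str, Enum):
    CD3 = "CD3"
    CD4 = "CD4"
    CD8 = "CD8"


class ValueKind(str, Enum):
    PERCENT = "percent"
    ABSOLUTE = "absolute"


class Instrument(str, Enum):
    """CD4 enumeration platform classes seen in the program."""

    FACSCOUNT = "FACSCount"
    CYFLOW = "CyFlow"
    PIMA = "PIMA"
    OTHER = "Other"


class Status(str, Enum):
    REPORTED = "reported"
    UNABLE = "unable_to_report"


class UnableReason(str, Enum):
    NO_LOGIN = "no_login"
    BROKEN_INSTRUMENT = "broken_instrument"
    NO_REAGENTS = "no_reagents"
    EXPIRED_REAGENTS = "expired_reagents"
    OTHER = "other"


#: A scored quantity: (specimen_id, marker, value_kind).
Quantity = tuple[str, Marker, ValueKind]


def quantity_sort_key(q: Quantity) -> tuple[str, str, str]:
    return (q[0], q[1].value, q[2].value)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Specimen:
    """One panel specimen in one session."""

    specimen_id: str
    session_id: str
    level: Level

    def __post_init__(self) -> None:
        if not self.specimen_id or not self.session_id:
            raise ValidationError("specimen_id and session_id must be non-empty")


@dataclass(frozen=True)
class MarkerReading:
    """Percent and/or absolute value reported for one marker.

    At least one of ``percent`` (fraction of lymphocytes, 0-100) and
    ``absolute`` (cells/µL, >= 0) must be present.
    """

    marker: Marker
    percent: Optional[float] = None
    absolute: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker", Marker(self.marker))
        if self.percent is None and self.absolute is None:
            raise ValidationError(f"{self.marker.value}: at least one of percent/absolute required")
        if self.percent is not None and not (0.0 <= self.percent <= 100.0):
            raise ValidationError(f"{self.marker.value}: percent out of [0,100]: {self.percent}")
        if self.absolute is not None and self.absolute < 0:
            raise ValidationError(f"{self.marker.value}: absolute count negative: {self.absolute}")


@dataclass(frozen=True)
class Submission:
    """One laboratory's result set for one specimen in one session."""

    lab_id: str
    session_id: str
    specimen_id: str
    instrument: Instrument
    status: Status
    readings: tuple[MarkerReading, ...] = ()
    unable_reason: Optional[UnableReason] = None
    receipt_date: Optional[datetime.date] = None
    analysis_date: Optional[datetime.date] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "instrument", Instrument(self.instrument))
        object.__setattr__(self, "status", Status(self.status))
        if self.unable_reason is not None:
            object.__setattr__(self, "unable_reason", UnableReason(self.unable_reason))
        if self.status is Status.REPORTED:
            if not self.readings:
                raise ValidationError("status=reported requires at least one marker reading")
        else:
            if self.readings:
                raise ValidationError("status=unable_to_report forbids marker readings")
            if self.unable_reason is None:
                raise ValidationError("status=unable_to_report requires unable_reason")
        markers = [r.marker for r in self.readings]
        if len(markers) != len(set(markers)):
            raise ValidationError("duplicate marker reading")
        if (
            self.receipt_date is not None
            and self.analysis_date is not None
            and self.analysis_date < self.receipt_date
        ):
            raise ValidationError("analysis_date before receipt_date")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lab_id, self.session_id, self.specimen_id)

    def value(self, marker: Marker, kind: ValueKind | str) -> Optional[float]:
        kind = ValueKind(kind)
        for r in self.readings:
            if r.marker is marker:
                return r.percent if kind is ValueKind.PERCENT else r.absolute
        return None

    def quantities(self) -> Iterator[tuple[Marker, ValueKind, float]]:
        """Yield every (marker, kind, value) actually reported."""
        for r in sorted(self.readings, key=lambda r: r.marker.value):
            if r.percent is not None:
                yield r.marker, ValueKind.PERCENT, r.percent
            if r.absolute is not None:
                yield r.marker, ValueKind.ABSOLUTE, r.absolute


@dataclass(frozen=True)
class RowDiagnostic:
    """A rejected input row: 1-based file line number plus reason."""

    line: int
    message: str


@dataclass
class ParseResult:
    """Outcome of a partial-load parse."""

    submissions: list[Submission] = field(default_factory=list)
    rejected: list[RowDiagnostic] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

SUBMISSION_COLUMNS = [
    "session_id", "lab_id", "instrument", "specimen_id", "status", "unable_reason",
    "receipt_date", "analysis_date",
    "cd3_pct", "cd3_abs", "cd4_pct", "cd4_abs", "cd8_pct", "cd8_abs",
]

MANIFEST_COLUMNS = ["session_id", "specimen_id", "level"]

_ISO_DATE = re.compile(r"^\d{4}-\d{2}-\d{2}$")

_VALUE_CELLS: list[tuple[str, Marker, ValueKind]] = [
    ("cd3_pct", Marker.CD3, ValueKind.PERCENT),
    ("cd3_abs", Marker.CD3, ValueKind.ABSOLUTE),
    ("cd4_pct", Marker.CD4, ValueKind.PERCENT),
    ("cd4_abs", Marker.CD4, ValueKind.ABSOLUTE),
    ("cd8_pct", Marker.CD8, ValueKind.PERCENT),
    ("cd8_abs", Marker.CD8, ValueKind.ABSOLUTE),
]


def _parse_date(cell: str, column: str) -> Optional[datetime.date]:
    cell = cell.strip()
    if not cell:
        return None
    if not _ISO_DATE.match(cell):
        raise ValidationError(f"{column}: date not ISO-8601 (YYYY-MM-DD): {cell!r}")
    try:
        return datetime.date.fromisoformat(cell)
    except ValueError as exc:
        raise ValidationError(f"{column}: {exc}") from exc


def _parse_number(cell: str, column: str) -> Optional[float]:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ValidationError(f"{column}: not a number: {cell!r}") from exc


def parse_instrument(text: str) -> Instrument:
    """Map an instrument cell to the platform enum.

    Unknown strings map to ``Other`` with a warning rather than a
    rejection, because program rosters routinely carry an "Others" class.
    """
    text = text.strip()
    for inst in Instrument:
        if text.lower() == inst.value.lower():
            return inst
    warnings.warn(f"unknown instrument {text!r} mapped to Other", stacklevel=3)
    return Instrument.OTHER


def _row_to_submission(row: dict[str, str]) -> Submission:
    status_text = row["status"].strip()
    try:
        status = Status(status_text)
    except ValueError:
        raise ValidationError(f"status: unknown value {status_text!r}") from None

    reason_text = row["unable_reason"].strip()
    reason: Optional[UnableReason] = None
    if reason_text:
        try:
            reason = UnableReason(reason_text)
        except ValueError:
            raise ValidationError(f"unable_reason: unknown value {reason_text!r}") from None

    by_marker: dict[Marker, dict[str, float]] = {}
    for column, marker, kind in _VALUE_CELLS:
        value = _parse_number(row[column], column)
        if value is None:
            continue
        slot = "percent" if kind is ValueKind.PERCENT else "absolute"
        by_marker.setdefault(marker, {})[slot] = value
        if kind is ValueKind.PERCENT and not (0.0 <= value <= 100.0):
            raise ValidationError(f"{column}: percent out of [0,100]: {value}")
        if kind is ValueKind.ABSOLUTE and value < 0:
            raise ValidationError(f"{column}: absolute count negative: {value}")

    readings = tuple(
        MarkerReading(marker=m, **vals)
        for m, vals in sorted(by_marker.items(), key=lambda kv: kv[0].value)
    )
    return Submission(
        lab_id=row["lab_id"].strip(),
        session_id=row["session_id"].strip(),
        specimen_id=row["specimen_id"].strip(),
        instrument=parse_instrument(row["instrument"]),
        status=status,
        readings=readings,
        unable_reason=reason,
        receipt_date=_parse_date(row["receipt_date"], "receipt_date"),
        analysis_date=_parse_date(row["analysis_date"], "analysis_date"),
    )


def _check_header(fieldnames: Sequence[str] | None, expected: Sequence[str], path: Path) -> None:
    if fieldnames is None:
        raise SchemaError(f"{path}: empty file, no header row")
    missing = [c for c in expected if c not in fieldnames]
    unknown = [c for c in fieldnames if c not in expected]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    if unknown:
        raise SchemaError(f"{path}: unknown column(s): {', '.join(unknown)}")


def parse_submissions(path: str | Path) -> ParseResult:
    """Load a submissions file under the partial-load contract.

    Returns a :class:`ParseResult` whose ``submissions`` hold every valid
    row and whose ``rejected`` list addresses each invalid row by file
    line.  Header problems raise :class:`SchemaError`; a repeated
    (lab, session, specimen) key among valid rows raises
    :class:`DuplicateKeyError`.
    """
    path = Path(path)
    result = ParseResult()
    seen: set[tuple[str, str, str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, SUBMISSION_COLUMNS, path)
        for line, row in enumerate(reader, start=2):
            try:
                sub = _row_to_submission(row)
            except ValidationError as exc:
                result.rejected.append(RowDiagnostic(line=line, message=str(exc)))
                continue
            if sub.key in seen:
                raise DuplicateKeyError(
                    f"{path}:{line}: duplicate (lab, session, specimen) key {sub.key}"
                )
            seen.add(sub.key)
            result.submissions.append(sub)
    return result


def write_submissions(submissions: Iterable[Submission], path: str | Path) -> None:
    """Write submissions in the documented schema (round-trips with parse)."""
    path = Path(path)

    def cell(value: Optional[float]) -> str:
        return "" if value is None else repr(float(value))

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUBMISSION_COLUMNS)
        for s in submissions:
            values = {m: {"percent": None, "absolute": None} for m in Marker}
            for r in s.readings:
                values[r.marker]["percent"] = r.percent
                values[r.marker]["absolute"] = r.absolute
            writer.writerow([
                s.session_id, s.lab_id, s.instrument.value, s.specimen_id,
                s.status.value,
                s.unable_reason.value if s.unable_reason else "",
                s.receipt_date.isoformat() if s.receipt_date else "",
                s.analysis_date.isoformat() if s.analysis_date else "",
                cell(values[Marker.CD3]["percent"]), cell(values[Marker.CD3]["absolute"]),
                cell(values[Marker.CD4]["percent"]), cell(values[Marker.CD4]["absolute"]),
                cell(values[Marker.CD8]["percent"]), cell(values[Marker.CD8]["absolute"]),
            ])


def parse_panel_manifest(path: str | Path) -> list[Specimen]:
    """Load a panel manifest: each session lists exactly one low and one mid specimen."""
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"{path}: empty manifest file")
        return []
    specimens: list[Specimen] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, MANIFEST_COLUMNS, path)
        for line, row in enumerate(reader, start=2):
            try:
                level = Level(row["level"].strip())
            except ValueError:
                raise ManifestError(
                    f"{path}:{line}: unknown level {row['level']!r}"
                ) from None
            specimens.append(
                Specimen(
                    specimen_id=row["specimen_id"].strip(),
                    session_id=row["session_id"].strip(),
                    level=level,
                )
            )
    if not specimens:
        warnings.warn(f"{path}: manifest has a header but no specimens")
        return []
    by_session: dict[str, list[Specimen]] = {}
    for sp in specimens:
        by_session.setdefault(sp.session_id, []).append(sp)
    for session_id, group in by_session.items():
        ids = {sp.specimen_id for sp in group}
        levels = sorted(sp.level.value for sp in group)
        if len(group) != 2 or len(ids) != 2 or levels != ["low", "mid"]:
            raise ManifestError(
                f"{path}: session {session_id} must list exactly one low and one mid "
                f"specimen (got levels {levels})"
            )
    return specimens


def write_panel_manifest(specimens: Iterable[Specimen], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for sp in specimens:
            writer.writerow([sp.session_id, sp.specimen_id, sp.level.value])
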