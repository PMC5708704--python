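"""Reading, validating and writing per-keystroke timing logs and subject metadata.

The keystroke log is a plain CSV stream, one row per keypress, recording only
*when* and *with which hand* a key was struck — never which character.  Each
row carries a time-of-day timestamp (``hh:mm:ss.sss``), the hand class
(``L``/``R``/``S`` for left hand, right hand, space bar), the keyboard column
index (1-5, counted from the centre of each hand's zone), the key hold time in
milliseconds, and — when the key has a successor in the same typing session —
the two-letter direction class of the ordered pair and the latency in
milliseconds from this key-down to the next key-down.  Flight time (latency
minus hold) is derived, never stored; it may be negative under key rollover.

Subject metadata is a second CSV with one row per participant: disease status,
diagnosis year, tremor and sidedness reports, UPDRS band, severity impact,
medication flags, birth year and gender.
"""

from __future__ import annotations

import csv
import datetime
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "HANDS",
    "DIRECTIONS",
    "KeystrokeEvent",
    "KeystrokeLog",
    "SubjectRecord",
    "LogDialect",
    "ParseReport",
    "LogFormatError",
    "read_log",
    "write_log",
    "read_subjects",
    "write_subjects",
]

HANDS = ("L", "R", "S")

#: All two-letter ordered-pair classes.  ``SS`` (space followed by space) is a
#: legal class for bookkeeping but is excluded from latency features downstream.
DIRECTIONS = ("LL", "LR", "RL", "RR", "LS", "RS", "SL", "SR", "SS")

_LOG_COLUMNS = ("timestamp", "hand", "column", "hold_ms", "next_direction", "latency_ms")

_SUBJECT_COLUMNS = (
    "subject_id",
    "parkinsons",
    "diagnosis_year",
    "tremors",
    "sidedness",
    "updrs",
    "impact",
    "levodopa",
    "other_meds",
    "birth_year",
    "gender",
)

_SIDEDNESS = ("Left", "Right", "None", "Unknown")
_IMPACTS = ("Mild", "Medium", "Severe", "NA")


class LogFormatError(ValueError):
    """Raised when a keystroke log or subject table is structurally unusable."""


@dataclass(frozen=True)
class KeystrokeEvent:
    """A single keypress and its (optional) link to the next keypress.

    ``latency_ms`` and ``next_direction`` are both ``None`` exactly when the
    event is the last of its typing session.  ``flight_ms`` is always derived
    as ``latency_ms - hold_ms`` and may be negative (rollover: the next key is
    pressed before this one is released).
    """

    timestamp: datetime.time
    hand: str
    column: int
    hold_ms: float
    next_direction: Optional[str] = None
    latency_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if not 1 <= int(self.column) <= 5:
            raise ValueError(f"column must be in 1..5, got {self.column!r}")
        if self.hold_ms < 0:
            raise ValueError(f"hold_ms must be non-negative, got {self.hold_ms}")
        if (self.latency_ms is None) != (self.next_direction is None):
            raise ValueError(
                "latency_ms and next_direction must be both present or both absent"
            )
        if self.next_direction is not None:
            if self.next_direction not in DIRECTIONS:
                raise ValueError(f"unknown direction class {self.next_direction!r}")
            if self.next_direction[0] != self.hand:
                raise ValueError(
                    f"direction {self.next_direction!r} inconsistent with hand {self.hand!r}"
                )

    @property
    def flight_ms(self) -> Optional[float]:
        if self.latency_ms is None:
            return None
        return self.latency_ms - self.hold_ms


@dataclass
class ParseReport:
    """Row-level diagnostics from :func:`read_log`."""

    n_rows: int = 0
    n_malformed: int = 0
    n_reordered: int = 0
    n_gap_breaks: int = 0
    n_link_mismatches: int = 0
    errors: list = field(default_factory=list)


@dataclass
class KeystrokeLog:
    """An ordered stream of keystrokes for one subject.

    Session boundaries are implicit: an event whose ``latency_ms`` is absent
    terminates its session.  Timestamps carry no date component, so sessions
    recorded on different days are distinguished by file segmentation, not by
    timestamp arithmetic.
    """

    subject_id: str
    events: list = field(default_factory=list)
    parse_report: Optional[ParseReport] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")

    def __len__(self) -> int:
        return len(self.events)

    def sessions(self) -> list:
        """Split the event stream into sessions (lists of events)."""
        out, cur = [], []
        for ev in self.events:
            cur.append(ev)
            if ev.latency_ms is None:
                out.append(cur)
                cur = []
        if cur:
            out.append(cur)
        return out


@dataclass(frozen=True)
class SubjectRecord:
    """Per-participant metadata as self-reported at enrolment."""

    subject_id: str
    has_pd: bool
    diagnosis_year: Optional[int] = None
    tremors: Optional[bool] = None
    sidedness: str = "Unknown"
    updrs: Optional[int] = None
    impact: str = "NA"
    levodopa: bool = False
    other_meds: str = ""
    birth_year: int = 0
    gender: str = "F"

    def __post_init__(self) -> None:
        if self.sidedness not in _SIDEDNESS:
            raise ValueError(f"sidedness must be one of {_SIDEDNESS}")
        if self.impact not in _IMPACTS:
            raise ValueError(f"impact must be one of {_IMPACTS}")
        if (self.impact == "NA") != (not self.has_pd):
            raise ValueError(
                f"subject {self.subject_id}: impact must be NA exactly for non-PD subjects"
            )
        if self.gender not in ("M", "F"):
            raise ValueError("gender must be 'M' or 'F'")
        if self.updrs is not None and not 1 <= self.updrs <= 5:
            raise ValueError("updrs must be in 1..5 when present")


@dataclass(frozen=True)
class LogDialect:
    """CSV dialect for keystroke logs.

    ``session_gap_ms`` severs the pair link whenever a recorded latency
    exceeds it: gaps that long are breaks between typing sessions, and a
    timing pair spanning them is meaningless.
    """

    delimiter: str = ","
    session_gap_ms: float = 300_000.0  # 5 minutes


DEFAULT_DIALECT = LogDialect()


def format_timestamp(t: datetime.time) -> str:
    return f"{t.hour:02d}:{t.minute:02d}:{t.second:02d}.{t.microsecond // 1000:03d}"


def parse_timestamp(s: str) -> datetime.time:
    t = datetime.datetime.strptime(s.strip(), "%H:%M:%S.%f").time()
    # quantise to millisecond resolution so round-trips are exact
    return t.replace(microsecond=(t.microsecond // 1000) * 1000)


def _parse_row(row: Mapping[str, str]) -> KeystrokeEvent:
    lat = row.get("latency_ms", "").strip()
    direction = row.get("next_direction", "").strip()
    return KeystrokeEvent(
        timestamp=parse_timestamp(row["timestamp"]),
        hand=row["hand"].strip(),
        column=int(row["column"]),
        hold_ms=float(row["hold_ms"]),
        next_direction=direction or None,
        latency_ms=float(lat) if lat else None,
    )


def read_log(
    path,
    dialect: LogDialect = DEFAULT_DIALECT,
    subject_id: Optional[str] = None,
    max_malformed_fraction: float = 0.10,
) -> KeystrokeLog:
    """Read a keystroke log CSV.

    Rows are parsed individually; malformed rows are collected in the
    returned log's ``parse_report`` rather than aborting the read, unless
    they exceed ``max_malformed_fraction`` of all rows, in which case a
    :class:`LogFormatError` is raised.  Within each session, events are
    re-ordered by timestamp if the file was shuffled, and any latency longer
    than ``dialect.session_gap_ms`` is treated as a session break (the pair
    link is severed).
    """
    path = Path(path)
    report = ParseReport()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None or not set(_LOG_COLUMNS) <= set(reader.fieldnames):
            raise LogFormatError(
                f"{path}: header must contain columns {_LOG_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        events = []
        for lineno, row in enumerate(reader, start=2):
            report.n_rows += 1
            try:
                events.append(_parse_row(row))
            except (KeyError, ValueError) as exc:
                report.n_malformed += 1
                report.errors.append((lineno, str(exc)))
    if report.n_rows and report.n_malformed / report.n_rows > max_malformed_fraction:
        raise LogFormatError(
            f"{path}: {report.n_malformed}/{report.n_rows} rows malformed "
            f"(> {max_malformed_fraction:.0%}); first errors: {report.errors[:3]}"
        )

    # all sessions in one file share the same day's clock, so a global stable
    # sort restores temporal order even when rows were shuffled; session
    # terminators (absent latency) travel with their events
    sorted_events = sorted(events, key=lambda ev: ev.timestamp)
    report.n_reordered = sum(1 for a, b in zip(events, sorted_events) if a is not b)

    # sever pair links across long gaps
    final = []
    for ev in sorted_events:
        if ev.latency_ms is not None and ev.latency_ms > dialect.session_gap_ms:
            ev = replace(ev, latency_ms=None, next_direction=None)
            report.n_gap_breaks += 1
        final.append(ev)

    # link consistency: second letter of the direction class must match the
    # successor's hand (diagnostic only; shuffled-but-valid files pass)
    for ev, nxt in zip(final, final[1:]):
        if ev.next_direction is not None and ev.next_direction[1] != nxt.hand:
            report.n_link_mismatches += 1

    return KeystrokeLog(
        subject_id=subject_id if subject_id is not None else path.stem,
        events=final,
        parse_report=report,
    )


def write_log(log: KeystrokeLog, path) -> Path:
    """Write a keystroke log CSV such that :func:`read_log` round-trips it."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LOG_COLUMNS)
        for ev in log.events:
            writer.writerow(
                [
                    format_timestamp(ev.timestamp),
                    ev.hand,
                    ev.column,
                    repr(ev.hold_ms),
                    ev.next_direction or "",
                    "" if ev.latency_ms is None else repr(ev.latency_ms),
                ]
            )
    return path


def _parse_bool(s: str, *, default: Optional[bool] = None) -> Optional[bool]:
    s = s.strip().upper()
    if not s:
        return default
    if s in ("Y", "YES", "TRUE", "1"):
        return True
    if s in ("N", "NO", "FALSE", "0"):
        return False
    raise ValueError(f"cannot parse boolean flag {s!r}")


def _parse_subject_row(row: Mapping[str, str]) -> SubjectRecord:
    has_pd = _parse_bool(row["parkinsons"])
    if has_pd is None:
        raise ValueError("parkinsons flag missing")
    impact = (row.get("impact") or "").strip() or "NA"
    if not has_pd:
        impact = "NA"  # invariant: severity is meaningful only for PD subjects
    updrs = (row.get("updrs") or "").strip()
    dyear = (row.get("diagnosis_year") or "").strip()
    return SubjectRecord(
        subject_id=row["subject_id"].strip(),
        has_pd=has_pd,
        diagnosis_year=int(dyear) if dyear else None,
        tremors=_parse_bool(row.get("tremors", "")),
        sidedness=(row.get("sidedness") or "").strip() or "Unknown",
        updrs=int(updrs) if updrs else None,
        impact=impact,
        levodopa=bool(_parse_bool(row.get("levodopa", ""), default=False)),
        other_meds=(row.get("other_meds") or "").strip(),
        birth_year=int(row["birth_year"]),
        gender=(row.get("gender") or "F").strip(),
    )


def read_subjects(path, reference_year: int = 2017) -> list:
    """Read the subject metadata CSV into a list of :class:`SubjectRecord`.

    Duplicate subject identifiers are rejected.  Subjects whose age at
    ``reference_year`` falls outside the 50-80 enrolment band trigger a
    warning but are retained (age is an enrolment criterion, not a data
    validity one).
    """
    path = Path(path)
    records: list = []
    seen: set = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "parkinsons" not in reader.fieldnames:
            raise LogFormatError(
                f"{path}: mandatory column 'parkinsons' missing from header"
            )
        if "subject_id" not in reader.fieldnames or "birth_year" not in reader.fieldnames:
            raise LogFormatError(f"{path}: 'subject_id' and 'birth_year' are mandatory")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = _parse_subject_row(row)
            except (KeyError, ValueError) as exc:
                raise LogFormatError(f"{path}:{lineno}: bad subject row: {exc}") from exc
            if rec.subject_id in seen:
                raise LogFormatError(
                    f"{path}:{lineno}: duplicate subject_id {rec.subject_id!r}"
                )
            seen.add(rec.subject_id)
            age = reference_year - rec.birth_year
            if not 50 <= age <= 80:
                warnings.warn(
                    f"subject {rec.subject_id}: age {age} outside the 50-80 "
                    f"enrolment band",
                    stacklevel=2,
                )
            records.append(rec)
    return records


def write_subjects(records: Iterable[SubjectRecord], path) -> Path:
    path = Path(path)

    def _b(v: Optional[bool]) -> str:
        return "" if v is None else ("Y" if v else "N")

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SUBJECT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.subject_id,
                    _b(r.has_pd),
                    r.diagnosis_year if r.diagnosis_year is not None else "",
                    _b(r.tremors),
                    r.sidedness,
                    r.updrs if r.updrs is not None else "",
                    r.impact,
                    _b(r.levodopa),
                    r.other_meds,
                    r.birth_year,
                    r.gender,
                ]
            )
    return path
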