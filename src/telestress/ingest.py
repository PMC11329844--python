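"""Reading, validation, and canonical in-memory form of the three raw streams.

The pipeline consumes three per-cohort CSV files (UTF-8, comma separated,
ISO-8601 dates, blank cell = missing):

* ``wearable.csv`` — one row per participant-day of device data,
* ``shifts.csv`` — one row per participant-workday of attendance data,
* ``questionnaires.csv`` — one row per participant-week of survey answers.

Clock times are minutes from midnight of the record's date; a sleep onset on
the previous evening is a negative offset (e.g. -30 = 23:30 the night
before), which avoids any midnight-wrap ambiguity.  Readers validate every
row and raise :class:`~telestress.errors.ValidationError` naming the
offending rows — no silent drops.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

WEARABLE_COLUMNS = [
    "participant_id", "date", "sleep_duration", "sleep_efficiency",
    "sleep_start", "sleep_end", "steps", "distance", "floors", "calories",
    "hr_mean", "hr_sd",
]
SHIFT_COLUMNS = [
    "participant_id", "date", "actual_start", "actual_end",
    "scheduled_start", "scheduled_end", "scheduled_hours", "wfh", "absent",
]
QUESTIONNAIRE_COLUMNS = [
    "participant_id", "week_index",
    "k6_1", "k6_2", "k6_3", "k6_4", "k6_5", "k6_6",
    "k6_total", "outings", "lunches_skipped",
]


@dataclass
class DailyWearableRecord:
    participant_id: str
    date: dt.date
    sleep_duration: Optional[float] = None   # minutes
    sleep_efficiency: Optional[float] = None  # percent 0-100
    sleep_start: Optional[float] = None      # minutes from midnight (signed)
    sleep_end: Optional[float] = None
    steps: Optional[int] = None
    distance: Optional[float] = None         # km
    floors: Optional[int] = None
    calories: Optional[float] = None         # kcal
    hr_mean: Optional[float] = None          # bpm
    hr_sd: Optional[float] = None            # bpm

    def validate(self) -> None:
        if self.sleep_efficiency is not None and not 0 <= self.sleep_efficiency <= 100:
            raise ValidationError(
                f"sleep_efficiency {self.sleep_efficiency} outside [0, 100]")
        for name in ("steps", "floors", "distance", "calories", "sleep_duration"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} {v} is negative")
        if self.hr_mean is not None and not 20 < self.hr_mean < 250:
            raise ValidationError(f"hr_mean {self.hr_mean} outside (20, 250)")
        if self.hr_sd is not None and self.hr_sd < 0:
            raise ValidationError(f"hr_sd {self.hr_sd} is negative")


@dataclass
class WorkShiftRecord:
    participant_id: str
    date: dt.date
    scheduled_start: float            # minutes from midnight
    scheduled_end: float
    scheduled_hours: float            # hours
    wfh: bool
    absent: bool
    actual_start: Optional[float] = None
    actual_end: Optional[float] = None

    def validate(self) -> None:
        if self.actual_start is not None and self.actual_end is not None:
            if self.actual_end < self.actual_start:
                raise ValidationError(
                    f"actual_end {self.actual_end} before actual_start {self.actual_start}")
        if not self.absent and self.scheduled_hours <= 0:
            raise ValidationError(
                f"scheduled_hours {self.scheduled_hours} not positive on a worked day")
        if self.absent and (self.actual_start is not None or self.actual_end is not None):
            raise ValidationError("absent day carries actual start/end times")


@dataclass
class WeeklyQuestionnaireRecord:
    participant_id: str
    week_index: int                   # 1-based study week
    k6_items: tuple[int, ...]         # six items, each 0-4
    k6_total: int                     # 0-24
    outings: int
    lunches_skipped: int              # 0-7

    def validate(self) -> None:
        if len(self.k6_items) != 6:
            raise ValidationError(f"expected 6 K6 items, got {len(self.k6_items)}")
        for item in self.k6_items:
            if not 0 <= item <= 4:
                raise ValidationError(f"K6 item {item} outside [0, 4]")
        if self.k6_total != sum(self.k6_items):
            raise ValidationError(
                f"k6_total {self.k6_total} != sum of items {sum(self.k6_items)}")
        if not 0 <= self.k6_total <= 24:
            raise ValidationError(f"k6_total {self.k6_total} outside [0, 24]")
        if not 0 <= self.lunches_skipped <= 7:
            raise ValidationError(
                f"lunches_skipped {self.lunches_skipped} outside [0, 7]")
        if self.outings < 0:
            raise ValidationError(f"outings {self.outings} is negative")
        if self.week_index < 1:
            raise ValidationError(f"week_index {self.week_index} < 1")


@dataclass
class ParticipantData:
    """All three streams for one participant."""

    participant_id: str
    wearable: list[DailyWearableRecord] = field(default_factory=list)
    shifts: list[WorkShiftRecord] = field(default_factory=list)
    questionnaires: list[WeeklyQuestionnaireRecord] = field(default_factory=list)

    def validate(self) -> None:
        for stream, key in (
            (self.wearable, lambda r: r.date),
            (self.shifts, lambda r: r.date),
            (self.questionnaires, lambda r: r.week_index),
        ):
            keys = [key(r) for r in stream]
            if len(set(keys)) != len(keys):
                dupes = sorted({k for k in keys if keys.count(k) > 1})
                raise ValidationError(
                    f"duplicate keys {dupes} in a stream of participant "
                    f"{self.participant_id!r}")


# ---------------------------------------------------------------- parsing

def _parse_float(cell: str) -> Optional[float]:
    return float(cell) if cell != "" else None


def _parse_int(cell: str) -> Optional[int]:
    return int(cell) if cell != "" else None


def _parse_bool(cell: str) -> bool:
    low = cell.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean from {cell!r}")


def _parse_date(cell: str) -> dt.date:
    return dt.date.fromisoformat(cell)


def _read_rows(path, expected_columns: Sequence[str]):
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != list(expected_columns):
            raise FormatError(
                f"{path.name}: header {reader.fieldnames} does not match "
                f"expected {list(expected_columns)}")
        yield from enumerate(reader, start=2)  # data rows start at line 2


def _collect(path, columns, build: Callable[[dict], object]) -> list:
    records, problems = [], []
    for lineno, row in _read_rows(path, columns):
        try:
            rec = build(row)
            rec.validate()
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {lineno}: {exc}")
    if problems:
        raise ValidationError(
            f"{Path(path).name}: {len(problems)} invalid row(s):\n  "
            + "\n  ".join(problems))
    return records


def read_wearable(path) -> list[DailyWearableRecord]:
    """Read ``wearable.csv``; blank cells become missing values."""
    def build(row):
        return DailyWearableRecord(
            participant_id=row["participant_id"],
            date=_parse_date(row["date"]),
            sleep_duration=_parse_float(row["sleep_duration"]),
            sleep_efficiency=_parse_float(row["sleep_efficiency"]),
            sleep_start=_parse_float(row["sleep_start"]),
            sleep_end=_parse_float(row["sleep_end"]),
            steps=_parse_int(row["steps"]),
            distance=_parse_float(row["distance"]),
            floors=_parse_int(row["floors"]),
            calories=_parse_float(row["calories"]),
            hr_mean=_parse_float(row["hr_mean"]),
            hr_sd=_parse_float(row["hr_sd"]),
        )
    return _collect(path, WEARABLE_COLUMNS, build)


def read_shifts(path) -> list[WorkShiftRecord]:
    """Read ``shifts.csv``."""
    def build(row):
        return WorkShiftRecord(
            participant_id=row["participant_id"],
            date=_parse_date(row["date"]),
            actual_start=_parse_float(row["actual_start"]),
            actual_end=_parse_float(row["actual_end"]),
            scheduled_start=float(row["scheduled_start"]),
            scheduled_end=float(row["scheduled_end"]),
            scheduled_hours=float(row["scheduled_hours"]),
            wfh=_parse_bool(row["wfh"]),
            absent=_parse_bool(row["absent"]),
        )
    return _collect(path, SHIFT_COLUMNS, build)


def read_questionnaires(path) -> list[WeeklyQuestionnaireRecord]:
    """Read ``questionnaires.csv``; recomputes and checks the K6 total."""
    def build(row):
        items = tuple(int(row[f"k6_{i}"]) for i in range(1, 7))
        return WeeklyQuestionnaireRecord(
            participant_id=row["participant_id"],
            week_index=int(row["week_index"]),
            k6_items=items,
            k6_total=int(row["k6_total"]),
            outings=int(row["outings"]),
            lunches_skipped=int(row["lunches_skipped"]),
        )
    return _collect(path, QUESTIONNAIRE_COLUMNS, build)


def assemble_participants(
    wearable: list[DailyWearableRecord],
    shifts: list[WorkShiftRecord],
    questionnaires: list[WeeklyQuestionnaireRecord],
) -> list[ParticipantData]:
    """Group the three streams by participant id.

    Participants present in only some streams are retained with the other
    streams empty (missingness is data, not an error); a warning is logged.
    Duplicate dates or week indices within one participant's stream raise.
    """
    ids: list[str] = []
    seen: set[str] = set()
    for rec in [*wearable, *shifts, *questionnaires]:
        if rec.participant_id not in seen:
            seen.add(rec.participant_id)
            ids.append(rec.participant_id)
    out = []
    for pid in ids:
        p = ParticipantData(
            participant_id=pid,
            wearable=[r for r in wearable if r.participant_id == pid],
            shifts=[r for r in shifts if r.participant_id == pid],
            questionnaires=[r for r in questionnaires if r.participant_id == pid],
        )
        p.validate()
        missing = [name for name, stream in
                   (("wearable", p.wearable), ("shifts", p.shifts),
                    ("questionnaires", p.questionnaires)) if not stream]
        if missing:
            logger.warning("participant %s has empty stream(s): %s",
                           pid, ", ".join(missing))
        out.append(p)
    return out


# ---------------------------------------------------------------- writing

def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, dt.date):
        return value.isoformat()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _write_csv(path, columns, rows) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for row in rows:
            writer.writerow([_fmt(v) for v in row])


def write_wearable(path, records: list[DailyWearableRecord]) -> None:
    _write_csv(path, WEARABLE_COLUMNS, (
        [r.participant_id, r.date, r.sleep_duration, r.sleep_efficiency,
         r.sleep_start, r.sleep_end, r.steps, r.distance, r.floors,
         r.calories, r.hr_mean, r.hr_sd] for r in records))


def write_shifts(path, records: list[WorkShiftRecord]) -> None:
    _write_csv(path, SHIFT_COLUMNS, (
        [r.participant_id, r.date, r.actual_start, r.actual_end,
         r.scheduled_start, r.scheduled_end, r.scheduled_hours,
         r.wfh, r.absent] for r in records))


def write_questionnaires(path, records: list[WeeklyQuestionnaireRecord]) -> None:
    _write_csv(path, QUESTIONNAIRE_COLUMNS, (
        [r.participant_id, r.week_index, *r.k6_items, r.k6_total,
         r.outings, r.lunches_skipped] for r in records))


def read_cohort_dir(directory) -> list[ParticipantData]:
    """Read the three stream files from a directory and assemble."""
    directory = Path(directory)
    return assemble_participants(
        read_wearable(directory / "wearable.csv"),
        read_shifts(directory / "shifts.csv"),
        read_questionnaires(directory / "questionnaires.csv"),
    )
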