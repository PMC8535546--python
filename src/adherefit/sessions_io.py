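"""Reading, cleaning and aggregating raw workout-session logs.

The base signal of the whole pipeline is one number per user per day: the
accumulated workout time in seconds.  This module turns raw session logs
(CSV or JSON, one row/object per workout session) into fixed-length
:class:`DailySeries` objects covering a 120-day longitudinal window, split
into a 90-day training window (months 1-3) and a 30-day test window
(month 4).

Day boundaries use the calendar-date component of each timestamp as logged;
no timezone conversion is applied.  Day indexing is 1-based and anchored at
the date of the user's first retained session, so "month 1" is days 1-30.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SessionRecord",
    "DailySeries",
    "CleaningReport",
    "ParseError",
    "parse_sessions",
    "clean_sessions",
    "build_daily_series",
    "split_windows",
    "cohort_from_sessions",
    "PERIOD_DAYS",
    "TRAIN_DAYS",
    "TEST_DAYS",
]

PERIOD_DAYS = 120
TRAIN_DAYS = 90
TEST_DAYS = 30

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}


class ParseError(ValueError):
    """Raised when a session stream cannot be parsed at all."""


@dataclass(frozen=True)
class SessionRecord:
    """One logged workout session.

    ``duration_s`` may be NaN and ``start_time`` None for corrupt rows;
    such records survive parsing and are removed by :func:`clean_sessions`,
    which reports how many were dropped.
    """

    user_id: str
    start_time: datetime | None
    duration_s: float
    finished: bool

    @property
    def is_corrupt(self) -> bool:
        return (
            self.start_time is None
            or not np.isfinite(self.duration_s)
            or self.duration_s < 0
        )

    @property
    def day(self) -> date | None:
        return None if self.start_time is None else self.start_time.date()


@dataclass
class DailySeries:
    """One user's accumulated workout seconds per day over 120 days.

    ``day_values[d-1]`` is day ``d`` (1-based), anchored at the date of the
    user's first retained session.  Days 1-90 are the training window,
    days 91-120 the held-out fourth month.
    """

    user_id: str
    day_values: np.ndarray
    anchor: date | None = None

    def __post_init__(self) -> None:
        self.day_values = np.asarray(self.day_values, dtype=float)
        if self.day_values.ndim != 1:
            raise ValueError("day_values must be one-dimensional")
        if np.any(self.day_values < 0):
            raise ValueError("day_values must be non-negative")

    def __len__(self) -> int:
        return len(self.day_values)

    @property
    def train(self) -> np.ndarray:
        return split_windows(self)[0]

    @property
    def test(self) -> np.ndarray:
        return split_windows(self)[1]


@dataclass
class CleaningReport:
    """Counts of records removed by each cleaning rule."""

    n_input: int = 0
    n_duplicates: int = 0
    n_corrupt: int = 0
    n_unfinished: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_duplicates + self.n_corrupt + self.n_unfinished

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"unrecognised finished flag: {value!r}")


def _parse_timestamp(value: object) -> datetime | None:
    if value is None:
        return None
    if isinstance(value, datetime):
        return value
    text = str(value).strip()
    if not text:
        return None
    try:
        return datetime.fromisoformat(text)
    except ValueError:
        return None


def _parse_duration(value: object) -> float:
    if value is None:
        return float("nan")
    try:
        return float(value)
    except (TypeError, ValueError):
        return float("nan")


def _record_from_mapping(obj: dict) -> SessionRecord:
    return SessionRecord(
        user_id=str(obj.get("user_id", "")),
        start_time=_parse_timestamp(obj.get("start_time")),
        duration_s=_parse_duration(obj.get("duration_s")),
        finished=_parse_bool(obj.get("finished", True)),
    )


def parse_sessions(source, format: str = "csv") -> list[SessionRecord]:
    """Parse a CSV or JSON session stream into :class:`SessionRecord` s.

    Parameters
    ----------
    source
        A text/byte stream, a path, or a string containing the data.
    format
        ``"csv"`` (header ``user_id,start_time,duration_s,finished``) or
        ``"json"`` (array of objects with the same keys).  Extra columns or
        keys are ignored.

    Rows with unparseable timestamps or durations are kept as corrupt
    records (NaN duration / None timestamp) so that :func:`clean_sessions`
    can count and drop them; a stream that is not decodable at all raises
    :class:`ParseError`.
    """
    text = _read_text(source)
    fmt = format.lower()
    if fmt == "csv":
        return _parse_csv(text)
    if fmt == "json":
        return _parse_json(text)
    raise ValueError(f"unknown session format {format!r}; expected 'csv' or 'json'")


def _read_text(source) -> str:
    if isinstance(source, (str, bytes)):
        data = source
    elif hasattr(source, "read"):
        data = source.read()
    else:  # pathlib.Path or similar
        with open(source, "rb") as fh:
            data = fh.read()
    if isinstance(data, bytes):
        try:
            return data.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise ParseError(f"stream is not UTF-8 decodable at byte {exc.start}") from exc
    return data


def _parse_csv(text: str) -> list[SessionRecord]:
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise ParseError("empty CSV stream: missing header line")
    missing = {"user_id", "start_time", "duration_s", "finished"} - set(reader.fieldnames)
    if missing:
        raise ParseError(f"CSV header line 1 missing columns: {sorted(missing)}")
    records = []
    for lineno, row in enumerate(reader, start=2):
        try:
            records.append(_record_from_mapping(row))
        except ValueError as exc:
            raise ParseError(f"CSV line {lineno}: {exc}") from exc
    return records


def _parse_json(text: str) -> list[SessionRecord]:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    if not isinstance(payload, list):
        raise ParseError("JSON session stream must be an array of objects")
    records = []
    for i, obj in enumerate(payload):
        if not isinstance(obj, dict):
            raise ParseError(f"JSON element {i} is not an object")
        records.append(_record_from_mapping(obj))
    return records


def clean_sessions(
    records: Iterable[SessionRecord],
    finished_only: bool = True,
) -> tuple[list[SessionRecord], CleaningReport]:
    """Remove duplicate, corrupt and (optionally) unfinished sessions.

    A duplicate is a repeated ``(user_id, start_time, duration_s)`` triple;
    the first occurrence is kept and input order is preserved.  Cleaning
    never raises: it filters and reports counts.

    By default only finished sessions are retained, matching the feature
    definitions ("completed sessions"); pass ``finished_only=False`` to also
    accumulate aborted-session time.
    """
    report = CleaningReport()
    seen: set[tuple] = set()
    kept: list[SessionRecord] = []
    for rec in records:
        report.n_input += 1
        if rec.is_corrupt:
            report.n_corrupt += 1
            continue
        key = (rec.user_id, rec.start_time, rec.duration_s)
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        if finished_only and not rec.finished:
            report.n_unfinished += 1
            continue
        kept.append(rec)
    return kept, report


def build_daily_series(
    records: Sequence[SessionRecord],
    user_id: str,
    period_days: int = PERIOD_DAYS,
) -> DailySeries:
    """Aggregate one user's cleaned sessions into a daily-seconds series.

    Day ``d`` accumulates the durations of the user's sessions dated
    ``anchor + (d - 1)`` days, where the anchor is the user's earliest
    session date.  Days with no sessions are 0; sessions dated beyond the
    period are ignored.
    """
    if period_days < 1:
        raise ValueError("period_days must be >= 1")
    mine = [r for r in records if r.user_id == user_id and not r.is_corrupt]
    if not mine:
        raise ValueError(
            f"user {user_id!r} has no retained sessions: no anchor date "
            "(users without enough history are excluded upstream)"
        )
    anchor = min(r.day for r in mine)
    values = np.zeros(period_days, dtype=float)
    for rec in mine:
        d = (rec.day - anchor).days  # 0-based offset
        if 0 <= d < period_days:
            values[d] += rec.duration_s
    return DailySeries(user_id=user_id, day_values=values, anchor=anchor)


def split_windows(series: DailySeries) -> tuple[np.ndarray, np.ndarray]:
    """Split a 120-day series into the 90-day train / 30-day test windows."""
    values = np.asarray(series.day_values, dtype=float)
    if len(values) != PERIOD_DAYS:
        raise ValueError(
            f"series for user {series.user_id!r} has length {len(values)}, "
            f"expected {PERIOD_DAYS}"
        )
    return values[:TRAIN_DAYS].copy(), values[TRAIN_DAYS:].copy()


def cohort_from_sessions(
    records: Iterable[SessionRecord],
    finished_only: bool = True,
    period_days: int = PERIOD_DAYS,
) -> tuple[list[DailySeries], CleaningReport]:
    """Clean sessions and build one :class:`DailySeries` per user.

    Users are ordered by first appearance in the cleaned stream.
    """
    kept, report = clean_sessions(records, finished_only=finished_only)
    order: dict[str, None] = {}
    for rec in kept:
        order.setdefault(rec.user_id, None)
    cohort = [build_daily_series(kept, uid, period_days=period_days) for uid in order]
    return cohort, report
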