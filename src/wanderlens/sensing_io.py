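"""Ingestion of ambient sensor event logs.

Smart-home deployments in the CASAS style log one discrete sensor event per
line: a timestamp, a sensor identifier and a value (``ON``/``OFF`` for PIR
motion sensors, ``OPEN``/``CLOSE`` for door contacts, ``PRESENT``/``ABSENT``
for RFID-tagged objects).  This module parses those logs, joins them with a
sensor-position table to obtain planar position records, and applies two
noise-reduction filters — a speed gate (default 15 m/s) and a displacement
gate (default 5 m) — that remove physically implausible jumps caused by
overlapping sensor fields and positioning error.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import os
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: Sensor values treated as "presence sensed here" — only these produce
#: position records.  Deactivation edges (OFF/CLOSE/ABSENT) carry no new
#: positional information.
DEFAULT_ACTIVATION_VALUES = frozenset({"ON", "OPEN", "PRESENT"})

#: Sensor-id prefix -> category.  Other prefixes (T temperature, P power ...)
#: are parsed but carry no position semantics downstream.
CATEGORY_BY_PREFIX = {"M": "motion", "D": "door", "I": "object"}

_TIME_FORMATS = ("%H:%M:%S.%f", "%H:%M:%S")
_DATETIME_FORMATS = ("%Y-%m-%d %H:%M:%S.%f", "%Y-%m-%d %H:%M:%S")
_DEFAULT_DATE = "1900-01-01"


class UnknownSensorError(KeyError):
    """Raised when a sensor id has no entry in the position table."""


@dataclass(frozen=True)
class RawSensorEvent:
    """One ``<t, s_id, v>`` triple from the event log."""

    t: datetime
    s_id: str
    v: str

    @property
    def category(self) -> str | None:
        return CATEGORY_BY_PREFIX.get(self.s_id[:1])


@dataclass
class EventStream:
    """Parsed event log: events in file order plus a malformed-line count."""

    events: list[RawSensorEvent]
    n_skipped: int = 0

    def __iter__(self) -> Iterator[RawSensorEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class PositionRecord:
    """A resident position fix ``<x, y, t>`` derived from one activation."""

    x: float
    y: float
    t: datetime
    s_id: str
    category: str


@dataclass
class PositionHistory:
    """Time-ordered position records for one monitored subject."""

    records: list[PositionRecord]
    subject_id: str = ""
    label: str = "unknown"  # CH, PwD or unknown
    n_unknown_sensor: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PositionRecord]:
        return iter(self.records)


class SensorPositionTable:
    """Mapping from sensor id to planar coordinates in meters."""

    def __init__(self, entries: dict[str, tuple[float, float]] | None = None):
        self._entries: dict[str, tuple[float, float]] = dict(entries or {})

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, s_id: str) -> bool:
        return s_id in self._entries

    def __setitem__(self, s_id: str, xy: tuple[float, float]) -> None:
        self._entries[s_id] = (float(xy[0]), float(xy[1]))

    def lookup(self, s_id: str) -> tuple[float, float]:
        try:
            return self._entries[s_id]
        except KeyError:
            raise UnknownSensorError(f"unknown sensor id: {s_id!r}") from None

    def get(self, s_id: str) -> tuple[float, float] | None:
        return self._entries.get(s_id)

    def items(self):
        return self._entries.items()

    def ids(self):
        return self._entries.keys()

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) over all entries."""
        if not self._entries:
            raise ValueError("empty position table has no bounding box")
        xs = [xy[0] for xy in self._entries.values()]
        ys = [xy[1] for xy in self._entries.values()]
        return min(xs), min(ys), max(xs), max(ys)

    def centroid(self) -> tuple[float, float]:
        xs = [xy[0] for xy in self._entries.values()]
        ys = [xy[1] for xy in self._entries.values()]
        return sum(xs) / len(xs), sum(ys) / len(ys)


def _parse_timestamp(fields: Sequence[str]) -> tuple[datetime, int]:
    """Parse a timestamp from the leading fields of an event line.

    Accepts ``HH:MM:SS[.ffffff]`` with an optional leading ``YYYY-MM-DD``
    date.  Returns the timestamp and the number of fields consumed.
    """
    if "-" in fields[0] and len(fields) >= 2:
        joined = f"{fields[0]} {fields[1]}"
        for fmt in _DATETIME_FORMATS:
            try:
                return datetime.strptime(joined, fmt), 2
            except ValueError:
                continue
    for fmt in _TIME_FORMATS:
        try:
            return (
                datetime.strptime(f"{_DEFAULT_DATE} {fields[0]}", f"%Y-%m-%d {fmt}"),
                1,
            )
        except ValueError:
            continue
    raise ValueError(f"unparseable timestamp: {fields[0]!r}")


def _as_line_iterable(source) -> Iterable[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            return fh.readlines()
    if isinstance(source, io.TextIOBase):
        return source.readlines()
    return source  # already an iterable of lines


def parse_event_stream(source) -> EventStream:
    """Parse a CASAS-dialect event log into an :class:`EventStream`.

    Parameters
    ----------
    source
        Path, open text file, or iterable of lines.  Each non-blank line is
        ``[YYYY-MM-DD] HH:MM:SS[.ffffff] sensor_id value [extra...]``.

    Malformed lines (fewer than the required fields, or an unparseable
    timestamp) are skipped with a logged warning and counted in
    ``EventStream.n_skipped``.  An unreadable source raises ``OSError``.
    """
    events: list[RawSensorEvent] = []
    skipped = 0
    for lineno, line in enumerate(_as_line_iterable(source), start=1):
        fields = line.split()
        if not fields:
            continue
        try:
            t, used = _parse_timestamp(fields)
            rest = fields[used:]
            if len(rest) < 2:
                raise ValueError("missing sensor id or value")
            events.append(RawSensorEvent(t=t, s_id=rest[0], v=rest[1]))
        except ValueError as exc:
            skipped += 1
            logger.warning("skipping malformed line %d: %s (%s)", lineno, line.strip(), exc)
    return EventStream(events=events, n_skipped=skipped)


def load_position_table(source) -> SensorPositionTable:
    """Load a sensor-position table from delimited text.

    Rows are ``sensor_id, x, y`` with comma, tab or whitespace separation; a
    header row is detected and skipped.  Rows with non-numeric coordinates
    are rejected with a warning; duplicated sensor ids keep the last row.
    """
    table = SensorPositionTable()
    for line in _as_line_iterable(source):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "," in line:
            fields = [f.strip() for f in next(csv.reader([line]))]
        else:
            fields = line.split()
        if len(fields) < 3:
            logger.warning("rejecting short position row: %r", line)
            continue
        s_id = fields[0]
        try:
            x, y = float(fields[1]), float(fields[2])
        except ValueError:
            if s_id.lower() in {"sensor_id", "s_id", "sensor"}:
                continue  # header row
            logger.warning("rejecting non-numeric position row: %r", line)
            continue
        if s_id in table:
            logger.warning("duplicate sensor id %s: last row wins", s_id)
        table[s_id] = (x, y)
    return table


def to_position_records(
    events: Iterable[RawSensorEvent],
    table: SensorPositionTable,
    activation_values: frozenset[str] | set[str] = DEFAULT_ACTIVATION_VALUES,
    subject_id: str = "",
    label: str = "unknown",
) -> PositionHistory:
    """Join activation events with the position table into a history.

    Only activation edges (``ON``/``OPEN``/``PRESENT`` by default) localise
    the resident; deactivations and sensors without position semantics
    (temperature, power, ...) produce no record.  Events whose id is absent
    from the table are skipped and counted in ``n_unknown_sensor``.
    """
    records: list[PositionRecord] = []
    n_unknown = 0
    for ev in events:
        category = ev.category
        if category is None or ev.v not in activation_values:
            continue
        xy = table.get(ev.s_id)
        if xy is None:
            n_unknown += 1
            logger.warning("event for sensor %s has no table entry; skipped", ev.s_id)
            continue
        records.append(PositionRecord(x=xy[0], y=xy[1], t=ev.t, s_id=ev.s_id, category=category))
    return PositionHistory(
        records=records, subject_id=subject_id, label=label, n_unknown_sensor=n_unknown
    )


def noise_filter(
    history: PositionHistory, v_max: float = 15.0, d_max: float = 5.0
) -> PositionHistory:
    """Drop physically implausible position records.

    Single left-to-right pass.  Each candidate is compared against the last
    *retained* record and dropped when the implied speed exceeds ``v_max``
    (m/s) or the displacement exceeds ``d_max`` (m).  A zero time gap with a
    nonzero displacement implies infinite speed and the record is dropped;
    the first record is always retained.  Idempotent.
    """
    kept: list[PositionRecord] = []
    for rec in history.records:
        if not kept:
            kept.append(rec)
            continue
        prev = kept[-1]
        dist = math.hypot(rec.x - prev.x, rec.y - prev.y)
        dt = (rec.t - prev.t).total_seconds()
        if dt > 0:
            speed = dist / dt
        else:
            speed = math.inf if dist > 0 else 0.0
        if speed > v_max or dist > d_max:
            continue
        kept.append(rec)
    return replace_records(history, kept)


def replace_records(history: PositionHistory, records: list[PositionRecord]) -> PositionHistory:
    return PositionHistory(
        records=records,
        subject_id=history.subject_id,
        label=history.label,
        n_unknown_sensor=history.n_unknown_sensor,
    )
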