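"""Parsers for the vendor sleep-record dialects and real-time sample streams.

Three sleep dialects are supported, each with its own segmentation model:

* **Microsoft** — one JSON object per sleep *segment*, with explicit start and
  end timestamps, an ISO-8601 duration, a segment type (``Doze``, ``Snooze``,
  ``Awake``, ``Sleep``), a sleep subtype (``Unknown``, ``RestlessSleep``,
  ``RestfulSleep``) and an optional per-segment heart-rate summary.
* **Fitbit** — a minute-by-minute array; every minute carries a clock time
  (``HH:MM:SS``, no date) and an integer state code: 1 asleep, 2 awake,
  3 really awake.
* **Jawbone** — depth-change *events* only; each event has a depth code
  (1 awake, 2 light, 3 deep) and an epoch-seconds timestamp.  The end of the
  final period is not part of the dialect and must be supplied downstream.

Real-time multi-sensor samples follow a single flat model in which a missing
sensor is encoded with the sentinel value ``-1``.

Parsing is loss-free for declared fields: every dataclass carries an
``extras`` mapping with the undeclared keys of its source object, and
``to_json`` re-emits the vendor key/value pairs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from typing import Any, Iterable, Mapping
from zoneinfo import ZoneInfo

from .errors import (
    ConsistencyError,
    DocumentParseError,
    IdentityError,
    VocabularyError,
)

__all__ = [
    "MICROSOFT_SEGMENT_TYPES",
    "MICROSOFT_SLEEP_TYPES",
    "FITBIT_STATE_CODES",
    "JAWBONE_DEPTH_CODES",
    "REALTIME_NUMERIC_FIELDS",
    "REALTIME_STRING_FIELDS",
    "HeartRateSummary",
    "MicrosoftSleepSegment",
    "FitbitMinuteRecord",
    "JawboneDepthEvent",
    "RealTimeSample",
    "RecordIdentity",
    "parse_microsoft_sleep",
    "parse_fitbit_sleep",
    "parse_jawbone_sleep",
    "parse_realtime_batch",
]

MICROSOFT_SEGMENT_TYPES = frozenset({"Doze", "Snooze", "Awake", "Sleep"})
MICROSOFT_SLEEP_TYPES = frozenset({"Unknown", "RestlessSleep", "RestfulSleep"})
#: Fitbit per-minute states: 1 asleep, 2 awake, 3 really awake.
FITBIT_STATE_CODES = frozenset({1, 2, 3})
#: Jawbone depths: 1 awake, 2 light, 3 deep.
JAWBONE_DEPTH_CODES = frozenset({1, 2, 3})

#: Numeric sensor fields of a real-time sample; absent values become -1.
REALTIME_NUMERIC_FIELDS = (
    "wear",
    "resistence",
    "tempValue",
    "speedValue",
    "disValue",
    "accelValue",
    "stepsValue",
    "caloriesValue",
    "hrValue",
)
REALTIME_STRING_FIELDS = ("uvValue", "typeWalk", "typeStudy")

_ISO_DURATION_RE = re.compile(
    r"^P(?:(?P<days>\d+)D)?"
    r"(?:T(?:(?P<hours>\d+)H)?(?:(?P<minutes>\d+)M)?"
    r"(?:(?P<seconds>\d+(?:\.\d+)?)S)?)?$"
)


def _load_documents(document: str | Mapping | Iterable) -> list[dict]:
    """Decode JSON text (or an already-decoded object) into a list of dicts.

    A single top-level object and a top-level array are both accepted; the
    result is always a list.
    """
    if isinstance(document, (str, bytes)):
        try:
            payload = json.loads(document)
        except json.JSONDecodeError as exc:
            raise DocumentParseError(f"malformed JSON: {exc}") from exc
    else:
        payload = document
    if isinstance(payload, Mapping):
        return [dict(payload)]
    if isinstance(payload, list):
        out = []
        for item in payload:
            if not isinstance(item, Mapping):
                raise DocumentParseError(
                    f"expected JSON objects, found {type(item).__name__}"
                )
            out.append(dict(item))
        return out
    raise DocumentParseError(
        f"expected a JSON object or array, found {type(payload).__name__}"
    )


def parse_iso_duration(text: str) -> timedelta:
    """Parse an ISO-8601 duration such as ``PT4M57S`` into a timedelta."""
    m = _ISO_DURATION_RE.match(text.strip())
    if not m or text.strip() in ("P", "PT"):
        raise DocumentParseError(f"unparseable ISO-8601 duration: {text!r}")
    parts = {k: float(v) for k, v in m.groupdict().items() if v is not None}
    return timedelta(
        days=parts.get("days", 0.0),
        hours=parts.get("hours", 0.0),
        minutes=parts.get("minutes", 0.0),
        seconds=parts.get("seconds", 0.0),
    )


def format_iso_duration(span: timedelta) -> str:
    """Format a non-negative timedelta as an ISO-8601 duration (``PT4M57S``)."""
    total = span.total_seconds()
    if total < 0:
        raise ValueError("negative duration")
    hours, rem = divmod(total, 3600)
    minutes, seconds = divmod(rem, 60)
    out = "PT"
    if hours:
        out += f"{int(hours)}H"
    if minutes:
        out += f"{int(minutes)}M"
    if seconds or out == "PT":
        if seconds == int(seconds):
            out += f"{int(seconds)}S"
        else:
            out += f"{seconds:.3f}".rstrip("0").rstrip(".") + "S"
    return out


def _parse_timestamp(text: str, default_tz: ZoneInfo | timezone) -> datetime:
    try:
        ts = datetime.fromisoformat(text)
    except ValueError as exc:
        raise DocumentParseError(f"unparseable timestamp: {text!r}") from exc
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=default_tz)
    return ts


def _coerce_int(value: Any, what: str) -> int:
    """Coerce vendor integers that may arrive quoted ("1") or decorated
    (``NumberLong(635780414429706039)``)."""
    if isinstance(value, bool):
        raise DocumentParseError(f"{what}: boolean is not an integer")
    if isinstance(value, int):
        return value
    if isinstance(value, float) and value.is_integer():
        return int(value)
    if isinstance(value, str):
        text = value.strip()
        m = re.fullmatch(r"NumberLong\((\-?\d+)\)", text)
        if m:
            return int(m.group(1))
        try:
            return int(text)
        except ValueError:
            pass
    raise DocumentParseError(f"{what}: cannot interpret {value!r} as integer")


# ---------------------------------------------------------------------------
# Microsoft dialect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeartRateSummary:
    """Per-segment heart-rate summary (bpm)."""

    period: str
    average: int
    peak: int
    lowest: int

    def __post_init__(self) -> None:
        if not self.lowest <= self.average <= self.peak:
            raise ConsistencyError(
                f"heart-rate summary must satisfy lowest <= average <= peak, "
                f"got {self.lowest}/{self.average}/{self.peak}"
            )

    def to_json(self) -> dict:
        return {
            "period": self.period,
            "averageHeartRate": self.average,
            "peakHeartRate": self.peak,
            "lowestHeartRate": self.lowest,
        }


@dataclass(frozen=True)
class MicrosoftSleepSegment:
    """One Microsoft sleep segment: a maximal interval of one sleep state."""

    day_id: date | None
    segment_id: int
    segment_type: str
    sleep_type: str
    start_time: datetime
    end_time: datetime
    duration: timedelta
    hr_summary: HeartRateSummary | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.segment_type not in MICROSOFT_SEGMENT_TYPES:
            raise VocabularyError(
                f"unknown Microsoft segment type {self.segment_type!r}"
            )
        if self.sleep_type not in MICROSOFT_SLEEP_TYPES:
            raise VocabularyError(
                f"unknown Microsoft sleep type {self.sleep_type!r}"
            )
        if self.end_time < self.start_time:
            raise ConsistencyError(
                f"segment end {self.end_time.isoformat()} precedes start "
                f"{self.start_time.isoformat()}"
            )
        if self.duration != self.end_time - self.start_time:
            raise ConsistencyError(
                f"declared duration {self.duration} != end - start "
                f"{self.end_time - self.start_time}"
            )

    def to_json(self) -> dict:
        doc = {
            "sleepType": self.sleep_type,
            "segmentId": self.segment_id,
            "startTime": self.start_time.isoformat(timespec="milliseconds"),
            "endTime": self.end_time.isoformat(timespec="milliseconds"),
            "duration": format_iso_duration(self.duration),
            "segmentType": self.segment_type,
        }
        if self.day_id is not None:
            doc["dayId"] = (
                datetime.combine(self.day_id, time(0), tzinfo=timezone.utc)
                .isoformat(timespec="milliseconds")
            )
        if self.hr_summary is not None:
            doc["heartRateSummary"] = self.hr_summary.to_json()
        doc.update(self.extras)
        return doc


_MS_KEYS = {
    "dayId", "sleepType", "segmentId", "startTime", "endTime",
    "duration", "heartRateSummary", "segmentType",
}


def parse_microsoft_sleep(
    document: str | Mapping | Iterable,
    *,
    timezone_name: str = "UTC",
) -> list[MicrosoftSleepSegment]:
    """Parse Microsoft-dialect sleep segments from JSON text.

    Accepts a single object or an array of objects.  The declared duration is
    cross-checked against ``end - start``; a mismatch, a reversed interval or
    an undeclared state label raises.
    """
    tz = ZoneInfo(timezone_name)
    segments: list[MicrosoftSleepSegment] = []
    for obj in _load_documents(document):
        for key in ("startTime", "endTime", "segmentType", "sleepType"):
            if key not in obj:
                raise DocumentParseError(f"Microsoft segment missing {key!r}")
        start = _parse_timestamp(str(obj["startTime"]), tz)
        end = _parse_timestamp(str(obj["endTime"]), tz)
        if "duration" in obj:
            duration = parse_iso_duration(str(obj["duration"]))
        else:
            duration = end - start
        day_id: date | None = None
        if "dayId" in obj:
            day_id = _parse_timestamp(str(obj["dayId"]), tz).date()
        hr = None
        if obj.get("heartRateSummary") is not None:
            h = obj["heartRateSummary"]
            try:
                hr = HeartRateSummary(
                    period=str(h.get("period", "Segment")),
                    average=_coerce_int(h["averageHeartRate"], "averageHeartRate"),
                    peak=_coerce_int(h["peakHeartRate"], "peakHeartRate"),
                    lowest=_coerce_int(h["lowestHeartRate"], "lowestHeartRate"),
                )
            except KeyError as exc:
                raise DocumentParseError(
                    f"heartRateSummary missing {exc.args[0]!r}"
                ) from exc
        extras = {k: v for k, v in obj.items() if k not in _MS_KEYS}
        segments.append(
            MicrosoftSleepSegment(
                day_id=day_id,
                segment_id=_coerce_int(obj.get("segmentId", 0), "segmentId"),
                segment_type=str(obj["segmentType"]),
                sleep_type=str(obj["sleepType"]),
                start_time=start,
                end_time=end,
                duration=duration,
                hr_summary=hr,
                extras=extras,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# Fitbit dialect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitbitMinuteRecord:
    """One Fitbit minute: clock time plus state code 1/2/3."""

    clock_time: time
    state_code: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state_code not in FITBIT_STATE_CODES:
            raise VocabularyError(
                f"Fitbit state code {self.state_code!r} outside {{1,2,3}}"
            )

    def to_json(self) -> dict:
        doc = {
            "dateTime": self.clock_time.isoformat(),
            "value": str(self.state_code),
        }
        doc.update(self.extras)
        return doc


def parse_fitbit_sleep(document: str | Mapping | Iterable) -> list[FitbitMinuteRecord]:
    """Parse Fitbit minute-by-minute sleep records, preserving input order.

    ``value`` may be a quoted digit or a bare integer; both are coerced.
    """
    records: list[FitbitMinuteRecord] = []
    for obj in _load_documents(document):
        if "dateTime" not in obj or "value" not in obj:
            raise DocumentParseError("Fitbit record missing dateTime/value")
        try:
            clock = time.fromisoformat(str(obj["dateTime"]))
        except ValueError as exc:
            raise DocumentParseError(
                f"unparseable clock time {obj['dateTime']!r}"
            ) from exc
        code = _coerce_int(obj["value"], "value")
        if code not in FITBIT_STATE_CODES:
            raise VocabularyError(f"Fitbit state code {code} outside {{1,2,3}}")
        extras = {k: v for k, v in obj.items() if k not in ("dateTime", "value")}
        records.append(FitbitMinuteRecord(clock, code, extras))
    return records


# ---------------------------------------------------------------------------
# Jawbone dialect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JawboneDepthEvent:
    """A Jawbone depth-change event (epoch seconds; depth 1/2/3)."""

    depth_code: int
    event_time: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth_code not in JAWBONE_DEPTH_CODES:
            raise VocabularyError(
                f"Jawbone depth code {self.depth_code!r} outside {{1,2,3}}"
            )
        if self.event_time <= 0:
            raise DocumentParseError(
                f"Jawbone event time must be positive epoch seconds, "
                f"got {self.event_time}"
            )

    def to_json(self) -> dict:
        doc = {"depth": self.depth_code, "time": self.event_time}
        doc.update(self.extras)
        return doc


def parse_jawbone_sleep(document: str | Mapping | Iterable) -> list[JawboneDepthEvent]:
    """Parse Jawbone depth events, returned sorted by time (stable)."""
    events: list[JawboneDepthEvent] = []
    for obj in _load_documents(document):
        if "depth" not in obj or "time" not in obj:
            raise DocumentParseError("Jawbone event missing depth/time")
        depth = _coerce_int(obj["depth"], "depth")
        if depth not in JAWBONE_DEPTH_CODES:
            raise VocabularyError(f"Jawbone depth code {depth} outside {{1,2,3}}")
        when = _coerce_int(obj["time"], "time")
        extras = {k: v for k, v in obj.items() if k not in ("depth", "time")}
        events.append(JawboneDepthEvent(depth, when, extras))
    events.sort(key=lambda e: e.event_time)
    return events


# ---------------------------------------------------------------------------
# Real-time samples and identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RealTimeSample:
    """A real-time multi-sensor sample; missing sensors carry sentinel -1."""

    device: str
    date: int  # epoch milliseconds
    wear: int = -1
    resistence: int = -1
    uvValue: str = ""
    typeWalk: str = ""
    tempValue: float = -1
    speedValue: float = -1
    disValue: float = -1
    accelValue: float = -1
    stepsValue: int = -1
    caloriesValue: int = -1
    hrValue: float = -1
    typeStudy: str = ""
    extras: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        doc = {"device": self.device, "date": self.date}
        for name in REALTIME_NUMERIC_FIELDS:
            doc[name] = getattr(self, name)
        for name in REALTIME_STRING_FIELDS:
            doc[name] = getattr(self, name)
        doc.update(self.extras)
        return doc

    def replace(self, **changes) -> "RealTimeSample":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class RecordIdentity:
    """Provenance of a record: who, which device, which day."""

    record_id: str
    student_id: str
    date: int  # epoch milliseconds
    student_id_api: str = ""
    device: str = ""

    def __post_init__(self) -> None:
        if not self.student_id:
            raise IdentityError("student_id must be non-empty")
        if not self.device:
            raise IdentityError("device must be non-empty")

    def to_json(self) -> dict:
        return {
            "_id": self.record_id,
            "student_id": self.student_id,
            "date": self.date,
            "student_id_api": self.student_id_api,
            "device": self.device,
        }


_RT_KEYS = set(REALTIME_NUMERIC_FIELDS) | set(REALTIME_STRING_FIELDS) | {
    "device", "date",
}


def parse_realtime_batch(document: str | Mapping | Iterable) -> list[RealTimeSample]:
    """Parse a batch of real-time samples.

    Absent numeric sensors are populated with the sentinel ``-1``.  Within a
    single device's stream the timestamps must be strictly increasing; the
    returned batch is ordered by timestamp (stable across devices).
    """
    samples: list[RealTimeSample] = []
    for obj in _load_documents(document):
        if "device" not in obj or not obj["device"]:
            raise IdentityError("real-time sample missing device")
        if "date" not in obj:
            raise IdentityError("real-time sample missing date")
        kwargs: dict[str, Any] = {
            "device": str(obj["device"]),
            "date": _coerce_int(obj["date"], "date"),
        }
        for name in REALTIME_NUMERIC_FIELDS:
            if name in obj and obj[name] is not None:
                value = obj[name]
                if not isinstance(value, (int, float)) or isinstance(value, bool):
                    value = float(value)
                kwargs[name] = value
        for name in REALTIME_STRING_FIELDS:
            if name in obj and obj[name] is not None:
                kwargs[name] = str(obj[name])
        extras = {k: v for k, v in obj.items() if k not in _RT_KEYS}
        samples.append(RealTimeSample(extras=extras, **kwargs))

    last_by_device: dict[str, int] = {}
    for sample in samples:
        prev = last_by_device.get(sample.device)
        if prev is not None and sample.date <= prev:
            raise ConsistencyError(
                f"timestamps not strictly increasing for device "
                f"{sample.device!r}: {sample.date} after {prev}"
            )
        last_by_device[sample.device] = sample.date
    samples.sort(key=lambda s: s.date)
    return samples
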