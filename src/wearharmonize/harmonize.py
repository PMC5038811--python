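"""Homogenize vendor sleep records into one unified per-night model.

The unified vocabulary has three states — ``AWAKE``, ``LIGHT`` and
``RELAXED`` (deep/restful sleep) — and one record shape: a per-night summary
(total time, sleep-onset latency, per-state minute totals, awakenings,
efficiency, HR minimum, mean skin temperature) plus per-minute one-hot state
lists, timestamps and heart rate.  This module resolves the four families of
vendor differences:

* **vocabulary** — each vendor's state labels/codes map onto the unified
  triple (:func:`map_state`); Fitbit's "awake"/"really awake" merge into
  AWAKE because Fitbit carries no depth information, so its sleep maps to
  LIGHT;
* **segmentation** — Fitbit minute codes are run-length encoded
  (:func:`fitbit_minutes_to_segments`), Jawbone depth events are paired so
  that consecutive events delimit a segment
  (:func:`jawbone_events_to_segments`), Microsoft segments are remapped with
  gaps filled as AWAKE (:func:`microsoft_segments_to_unified`);
* **day assignment** — a sleep period belongs to the evening on which it
  began: starts before the noon cutoff are assigned to the previous calendar
  day (:func:`assign_day`); the longest period of a day is the main sleep,
  the rest are naps (:func:`label_main_and_naps`);
* **counters** — cumulative step/calorie counters are reconciled to daily
  totals under the device's reset policy
  (:func:`daily_total_from_cumulative`).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Iterable, Mapping, Sequence

from .errors import ConsistencyError, VocabularyError
from .vendor_ingest import (
    FitbitMinuteRecord,
    JawboneDepthEvent,
    MicrosoftSleepSegment,
    RealTimeSample,
    RecordIdentity,
    REALTIME_NUMERIC_FIELDS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UnifiedState",
    "SleepSegment",
    "SleepPeriod",
    "UnifiedSleepRecord",
    "CounterPolicy",
    "map_state",
    "fitbit_minutes_to_segments",
    "jawbone_events_to_segments",
    "microsoft_segments_to_unified",
    "split_into_periods",
    "assign_day",
    "label_main_and_naps",
    "build_unified_record",
    "daily_total_from_cumulative",
    "merge_missing",
]


class UnifiedState(str, enum.Enum):
    """The unified three-state sleep vocabulary."""

    AWAKE = "awake"
    LIGHT = "light"
    RELAXED = "relaxed"  # deep / restful sleep


class CounterPolicy(str, enum.Enum):
    """How a device resets its cumulative counters."""

    SINCE_FOREVER = "since_forever"      # e.g. Microsoft Band: never resets
    RESET_ON_REBOOT = "reset_on_reboot"  # e.g. Android Wear: resets on reboot
    DAILY_RESET = "daily_reset"          # e.g. Fitbit: resets every day


#: Per-vendor state mapping onto the unified vocabulary.  Fitbit codes are
#: integers; the remaining vendors use labels.  Fitbit sleep maps to LIGHT
#: (no depth information) and both of its awake flavours merge into AWAKE.
STATE_MAP: dict[str, dict[object, UnifiedState]] = {
    "microsoft": {
        "Awake": UnifiedState.AWAKE,
        "Doze": UnifiedState.AWAKE,
        "Snooze": UnifiedState.AWAKE,
        "Unknown": UnifiedState.AWAKE,
        "RestlessSleep": UnifiedState.LIGHT,
        "RestfulSleep": UnifiedState.RELAXED,
    },
    "fitbit": {
        1: UnifiedState.LIGHT,   # asleep
        2: UnifiedState.AWAKE,   # awake
        3: UnifiedState.AWAKE,   # really awake (merged)
    },
    "jawbone": {
        1: UnifiedState.AWAKE,
        2: UnifiedState.LIGHT,
        3: UnifiedState.RELAXED,  # deep
    },
    "googlefit": {
        "light": UnifiedState.LIGHT,
        "deep": UnifiedState.RELAXED,
        "awake": UnifiedState.AWAKE,
        "rem": UnifiedState.RELAXED,
    },
}


def map_state(
    vendor: str,
    vendor_state: object,
    overrides: Mapping[object, UnifiedState] | None = None,
) -> UnifiedState:
    """Map a vendor state label/code to the unified vocabulary.

    ``overrides`` lets a deployment retarget individual entries (e.g. route
    Google Fit REM elsewhere) without editing the built-in table.
    """
    try:
        table = STATE_MAP[vendor.lower()]
    except KeyError:
        raise VocabularyError(f"unknown vendor dialect {vendor!r}") from None
    if overrides and vendor_state in overrides:
        return overrides[vendor_state]
    try:
        return table[vendor_state]
    except KeyError:
        raise VocabularyError(
            f"state {vendor_state!r} is not in the {vendor} vocabulary"
        ) from None


@dataclass(frozen=True)
class SleepSegment:
    """A maximal contiguous interval of one unified sleep state."""

    state: UnifiedState
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConsistencyError(
                f"segment must have positive span: {self.start} .. {self.end}"
            )

    @property
    def duration(self) -> timedelta:
        return self.end - self.start


@dataclass
class SleepPeriod:
    """A contiguous block of sleep segments assigned to one calendar day."""

    segments: list[SleepSegment]
    assigned_day: date
    is_main: bool = False
    device: str = ""

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start < a.end:
                raise ConsistencyError("period segments overlap or are unordered")

    @property
    def start(self) -> datetime:
        return self.segments[0].start

    @property
    def end(self) -> datetime:
        return self.segments[-1].end

    @property
    def duration(self) -> timedelta:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def fitbit_minutes_to_segments(
    minutes: Sequence[FitbitMinuteRecord],
    day: date,
    *,
    tzinfo=None,
) -> list[SleepSegment]:
    """Run-length encode Fitbit minute codes into unified segments.

    Each record covers one whole minute starting at its clock time.  Clock
    times carry no date: ``day`` anchors the first record, and a backwards
    jump in clock time is interpreted as wrapping past midnight (at most
    once in a night).  A missing minute closes the current run.
    """
    if not minutes:
        return []
    segments: list[SleepSegment] = []
    minute = timedelta(minutes=1)
    prev_ts: datetime | None = None
    day_offset = timedelta(0)
    run_state: UnifiedState | None = None
    run_start: datetime | None = None
    run_end: datetime | None = None
    for record in minutes:
        ts = datetime.combine(day, record.clock_time, tzinfo=tzinfo) + day_offset
        if prev_ts is not None and ts < prev_ts:
            day_offset += timedelta(days=1)
            ts += timedelta(days=1)
        prev_ts = ts
        state = map_state("fitbit", record.state_code)
        if run_state == state and run_end == ts:
            run_end = ts + minute
        else:
            if run_state is not None:
                segments.append(SleepSegment(run_state, run_start, run_end))
            run_state, run_start, run_end = state, ts, ts + minute
    segments.append(SleepSegment(run_state, run_start, run_end))
    return segments


def jawbone_events_to_segments(
    events: Sequence[JawboneDepthEvent],
    wake_time: datetime,
) -> list[SleepSegment]:
    """Pair consecutive Jawbone depth events into segments.

    Event *i* opens a segment that the next event closes; the dialect never
    records the end of the last period, so the caller supplies ``wake_time``
    to close it.  Zero-length segments (repeated timestamps) are dropped.
    """
    if not events:
        return []
    tz = wake_time.tzinfo
    times = [datetime.fromtimestamp(e.event_time, tz=tz) for e in events]
    if wake_time < times[-1]:
        raise ConsistencyError(
            f"wake time {wake_time} precedes last event {times[-1]}"
        )
    bounds = times + [wake_time]
    segments = []
    for event, start, end in zip(events, bounds, bounds[1:]):
        if end == start:
            continue
        segments.append(
            SleepSegment(map_state("jawbone", event.depth_code), start, end)
        )
    return segments


def microsoft_segments_to_unified(
    segments: Sequence[MicrosoftSleepSegment],
    *,
    gap_fill_max: timedelta = timedelta(minutes=180),
) -> list[SleepSegment]:
    """Map Microsoft segments to the unified vocabulary, filling gaps.

    Sleep segments map through their subtype (restless -> LIGHT, restful ->
    RELAXED); Doze/Snooze/Awake map to AWAKE.  A gap between consecutive
    segments up to ``gap_fill_max`` is filled as AWAKE; a longer gap is left
    open and :func:`split_into_periods` will split the night there.
    """
    out: list[SleepSegment] = []
    prev_end: datetime | None = None
    for seg in segments:
        if prev_end is not None:
            if seg.start_time < prev_end:
                raise ConsistencyError(
                    f"Microsoft segments overlap at {seg.start_time}"
                )
            gap = seg.start_time - prev_end
            if timedelta(0) < gap <= gap_fill_max:
                out.append(SleepSegment(UnifiedState.AWAKE, prev_end, seg.start_time))
        if seg.end_time == seg.start_time:
            prev_end = seg.end_time
            continue
        vendor_state = (
            seg.sleep_type if seg.segment_type == "Sleep" else seg.segment_type
        )
        out.append(
            SleepSegment(
                map_state("microsoft", vendor_state), seg.start_time, seg.end_time
            )
        )
        prev_end = seg.end_time
    return out


def _merge_adjacent(segments: list[SleepSegment]) -> list[SleepSegment]:
    """Coalesce touching segments of equal state."""
    merged: list[SleepSegment] = []
    for seg in segments:
        if merged and merged[-1].state == seg.state and merged[-1].end == seg.start:
            merged[-1] = SleepSegment(seg.state, merged[-1].start, seg.end)
        else:
            merged.append(seg)
    return merged


def split_into_periods(segments: Sequence[SleepSegment]) -> list[list[SleepSegment]]:
    """Split a segment list into contiguous blocks at remaining gaps."""
    periods: list[list[SleepSegment]] = []
    current: list[SleepSegment] = []
    for seg in segments:
        if current and seg.start != current[-1].end:
            periods.append(current)
            current = []
        current.append(seg)
    if current:
        periods.append(current)
    return [_merge_adjacent(p) for p in periods]


# ---------------------------------------------------------------------------
# Day assignment
# ---------------------------------------------------------------------------

def assign_day(
    period_start: datetime,
    period_end: datetime,
    *,
    cutoff: time = time(12, 0),
) -> date:
    """Assign a sleep period to a calendar day by its start time.

    A night that begins in the evening of day *d* belongs to day *d* even
    when the user falls asleep after midnight: any start before the local
    noon cutoff is assigned to the previous calendar day, so an afternoon
    nap stays on its own day.
    """
    if period_end <= period_start:
        raise ConsistencyError("period end must follow period start")
    local = period_start.timetz().replace(tzinfo=None)
    if local >= cutoff:
        return period_start.date()
    return period_start.date() - timedelta(days=1)


def label_main_and_naps(periods: list[SleepPeriod]) -> list[SleepPeriod]:
    """Flag the longest period of a day as the main sleep, the rest as naps.

    Ties break toward the earliest start.  All periods must share one
    assigned day.
    """
    if not periods:
        return []
    days = {p.assigned_day for p in periods}
    if len(days) > 1:
        raise ConsistencyError(f"periods span multiple assigned days: {days}")
    main = max(periods, key=lambda p: (p.duration, -p.start.timestamp()))
    return [replace(p, is_main=(p is main)) for p in periods]


# ---------------------------------------------------------------------------
# Unified record
# ---------------------------------------------------------------------------

def _round_half_up(value: float, ndigits: int = 0) -> float:
    scale = 10 ** ndigits
    out = math.floor(value * scale + 0.5) / scale
    return out if ndigits > 0 else int(out)


def _fmt_hms(span: timedelta) -> str:
    total = int(round(span.total_seconds()))
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


@dataclass
class UnifiedSleepRecord:
    """The homogenized per-night sleep record.

    ``data`` carries the summary block and ``lists`` the per-minute block
    (one-hot state sequences, epoch-ms timestamps as strings, heart rate).
    Missing sensor summaries carry the sentinel ``-1``.
    """

    identity: RecordIdentity
    date_string: str
    total_time_data: int
    time_to_sleep_data: int
    temp_mean: float
    hr_min: int
    num_awake: int
    awake: int
    light: int
    relaxed: int
    sleep_efficiency: int
    efficiency_proposal: int
    start_hour: str
    end_hour: str
    total_time: str
    time_to_sleep: str
    minutes_awake: list[int] = field(default_factory=list, repr=False)
    minutes_light: list[int] = field(default_factory=list, repr=False)
    minutes_relaxed: list[int] = field(default_factory=list, repr=False)
    minutes_time: list[str] = field(default_factory=list, repr=False)
    minutes_hr: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.awake + self.light + self.relaxed != self.total_time_data:
            raise ConsistencyError(
                "per-state minutes must sum to total_time_data: "
                f"{self.awake}+{self.light}+{self.relaxed} != {self.total_time_data}"
            )
        n = len(self.minutes_awake)
        if not (len(self.minutes_light) == len(self.minutes_relaxed) == n):
            raise ConsistencyError("one-hot lists must have equal length")
        for i in range(n):
            if self.minutes_awake[i] + self.minutes_light[i] + self.minutes_relaxed[i] != 1:
                raise ConsistencyError(f"minute {i} is not one-hot")
        if self.minutes_hr and len(self.minutes_hr) != n:
            raise ConsistencyError("hr list length differs from one-hot lists")
        if self.minutes_time and len(self.minutes_time) != n:
            raise ConsistencyError("time list length differs from one-hot lists")
        # elapsed(start_hour -> end_hour) must equal total_time (mod 24 h)
        sh = time.fromisoformat(self.start_hour)
        eh = time.fromisoformat(self.end_hour)
        elapsed = (
            datetime.combine(date(2000, 1, 2), eh)
            - datetime.combine(date(2000, 1, 1), sh)
        ) % timedelta(days=1)
        tt = time.fromisoformat(self.total_time)
        tt_span = timedelta(hours=tt.hour, minutes=tt.minute, seconds=tt.second)
        if elapsed != tt_span % timedelta(days=1):
            raise ConsistencyError(
                f"elapsed {self.start_hour}->{self.end_hour} != total_time "
                f"{self.total_time}"
            )

    def to_json(self) -> dict:
        return {
            **self.identity.to_json(),
            "date_string": self.date_string,
            "data": {
                "total_time_data": self.total_time_data,
                "time_to_sleep_data": self.time_to_sleep_data,
                "temp_mean": self.temp_mean,
                "hr_min": self.hr_min,
                "num_awake": self.num_awake,
                "awake": self.awake,
                "light": self.light,
                "relaxed": self.relaxed,
                "sleep_efficiency": self.sleep_efficiency,
                "efficiency_proposal": self.efficiency_proposal,
                "start_hour": self.start_hour,
                "end_hour": self.end_hour,
                "total_time": self.total_time,
                "time_to_sleep": self.time_to_sleep,
            },
            "list": {
                "awake": self.minutes_awake,
                "light": self.minutes_light,
                "relaxed": self.minutes_relaxed,
                "time": self.minutes_time,
                "hr": self.minutes_hr,
            },
        }

    @classmethod
    def from_json(cls, doc: Mapping) -> "UnifiedSleepRecord":
        data = doc["data"]
        lists = doc.get("list", {})
        identity = RecordIdentity(
            record_id=str(doc.get("_id", "")),
            student_id=str(doc["student_id"]),
            date=int(doc["date"]),
            student_id_api=str(doc.get("student_id_api", "")),
            device=str(doc.get("device", "unknown")),
        )
        return cls(
            identity=identity,
            date_string=str(doc["date_string"]),
            total_time_data=int(data["total_time_data"]),
            time_to_sleep_data=int(data["time_to_sleep_data"]),
            temp_mean=float(data["temp_mean"]),
            hr_min=int(data["hr_min"]),
            num_awake=int(data["num_awake"]),
            awake=int(data["awake"]),
            light=int(data["light"]),
            relaxed=int(data["relaxed"]),
            sleep_efficiency=int(data["sleep_efficiency"]),
            efficiency_proposal=int(data["efficiency_proposal"]),
            start_hour=str(data["start_hour"]),
            end_hour=str(data["end_hour"]),
            total_time=str(data["total_time"]),
            time_to_sleep=str(data["time_to_sleep"]),
            minutes_awake=[int(v) for v in lists.get("awake", [])],
            minutes_light=[int(v) for v in lists.get("light", [])],
            minutes_relaxed=[int(v) for v in lists.get("relaxed", [])],
            minutes_time=[str(v) for v in lists.get("time", [])],
            minutes_hr=[int(v) for v in lists.get("hr", [])],
        )


def _state_at(segments: Sequence[SleepSegment], instant: datetime) -> UnifiedState:
    for seg in segments:
        if seg.start <= instant < seg.end:
            return seg.state
    # instants past the last boundary (rounding fringe) take the last state
    return segments[-1].state


def _sleep_minutes_of(period: SleepPeriod) -> tuple[int, int]:
    """(sleep minutes, total minutes) of a period by midpoint sampling."""
    n = int(period.duration.total_seconds() // 60)
    sleep = 0
    for i in range(n):
        mid = period.start + timedelta(minutes=i, seconds=30)
        if _state_at(period.segments, mid) is not UnifiedState.AWAKE:
            sleep += 1
    return sleep, n


def build_unified_record(
    identity: RecordIdentity,
    period: SleepPeriod,
    hr_series: Sequence[int] | None = None,
    temp_series: Sequence[float] | None = None,
    *,
    naps: Sequence[SleepPeriod] = (),
) -> UnifiedSleepRecord:
    """Build the unified per-night record from a sleep period.

    The per-minute one-hot expansion samples the state at each minute's
    midpoint; the minute count is the whole-minute truncation of the period
    span.  ``hr_series``/``temp_series``, when given, must cover the period
    at one sample per minute; absent sensors yield summary sentinel ``-1``.
    ``naps`` (other periods of the same day) enter ``sleep_efficiency``,
    while ``efficiency_proposal`` is the same ratio over this period only.
    """
    if not period.segments:
        raise ConsistencyError("cannot build a record from an empty period")
    n = int(period.duration.total_seconds() // 60)
    if hr_series is not None and len(hr_series) != n:
        raise ConsistencyError(
            f"hr series length {len(hr_series)} != {n} period minutes"
        )
    if temp_series is not None and len(temp_series) != n:
        raise ConsistencyError(
            f"temperature series length {len(temp_series)} != {n} period minutes"
        )

    one_hot = {s: [0] * n for s in UnifiedState}
    times: list[str] = []
    for i in range(n):
        minute_start = period.start + timedelta(minutes=i)
        state = _state_at(period.segments, minute_start + timedelta(seconds=30))
        one_hot[state][i] = 1
        times.append(str(int(minute_start.timestamp() * 1000)))

    counts = {s: sum(one_hot[s]) for s in UnifiedState}

    # Sleep-onset latency: span from period start to the first non-AWAKE
    # segment; a night that never leaves AWAKE gets latency == total span.
    onset: datetime | None = None
    for seg in period.segments:
        if seg.state is not UnifiedState.AWAKE:
            onset = seg.start
            break
    tts_span = (onset - period.start) if onset is not None else period.duration

    # Awakenings: AWAKE segments strictly after onset, excluding the final
    # wake at the very end of the period.
    num_awake = 0
    if onset is not None:
        for seg in period.segments:
            if (
                seg.state is UnifiedState.AWAKE
                and seg.start >= onset
                and seg.end != period.end
            ):
                num_awake += 1

    valid_hr = [v for v in (hr_series or []) if v >= 0]
    hr_min = min(valid_hr) if valid_hr else -1
    valid_temp = [v for v in (temp_series or []) if v >= 0]
    temp_mean = _round_half_up(sum(valid_temp) / len(valid_temp), 2) if valid_temp else -1

    sleep_minutes = counts[UnifiedState.LIGHT] + counts[UnifiedState.RELAXED]
    proposal = _round_half_up(100 * sleep_minutes / n) if n else 0
    all_sleep, all_total = sleep_minutes, n
    for nap in naps:
        s, t = _sleep_minutes_of(nap)
        all_sleep += s
        all_total += t
    efficiency = _round_half_up(100 * all_sleep / all_total) if all_total else 0

    local_day = period.assigned_day
    return UnifiedSleepRecord(
        identity=identity,
        date_string=local_day.isoformat(),
        total_time_data=n,
        time_to_sleep_data=int(tts_span.total_seconds() // 60),
        temp_mean=temp_mean,
        hr_min=hr_min,
        num_awake=num_awake,
        awake=counts[UnifiedState.AWAKE],
        light=counts[UnifiedState.LIGHT],
        relaxed=counts[UnifiedState.RELAXED],
        sleep_efficiency=efficiency,
        efficiency_proposal=proposal,
        start_hour=period.start.strftime("%H:%M:%S"),
        end_hour=period.end.strftime("%H:%M:%S"),
        total_time=_fmt_hms(period.duration),
        time_to_sleep=_fmt_hms(tts_span),
        minutes_awake=one_hot[UnifiedState.AWAKE],
        minutes_light=one_hot[UnifiedState.LIGHT],
        minutes_relaxed=one_hot[UnifiedState.RELAXED],
        minutes_time=times,
        minutes_hr=[int(v) for v in hr_series] if hr_series is not None else [],
    )


# ---------------------------------------------------------------------------
# Counters and sensor fusion
# ---------------------------------------------------------------------------

def daily_total_from_cumulative(
    samples: Sequence,
    policy: CounterPolicy,
) -> int | float:
    """Reconcile one day of cumulative counter readings into a daily total.

    ``samples`` is a time-ordered list of ``(timestamp, value)`` pairs (bare
    values are accepted too).  Semantics per reset policy:

    * ``SINCE_FOREVER`` — the counter never resets; the total is
      ``last - first``.
    * ``DAILY_RESET`` — the counter restarts at midnight; the last reading
      is the total.
    * ``RESET_ON_REBOOT`` — a drop in value signals a reboot that zeroed the
      counter; the total is the sum of increments, where the reading right
      after a drop counts in full (it accrued from zero).  Equivalently
      ``(last - first) + sum(values immediately before each drop)``.
    """
    values = [
        (s[1] if isinstance(s, (tuple, list)) else s) for s in samples
    ]
    if not values:
        return 0
    if policy is CounterPolicy.SINCE_FOREVER:
        total = values[-1] - values[0]
    elif policy is CounterPolicy.DAILY_RESET:
        total = values[-1]
    elif policy is CounterPolicy.RESET_ON_REBOOT:
        total = 0
        for prev, cur in zip(values, values[1:]):
            total += (cur - prev) if cur >= prev else cur
    else:  # pragma: no cover - exhaustive over enum
        raise ValueError(f"unknown policy {policy!r}")
    if total < 0:
        raise ConsistencyError(
            f"negative daily total {total} under {policy.value}"
        )
    return total


def merge_missing(
    sample: RealTimeSample,
    fallback: RealTimeSample,
    *,
    tolerance: timedelta = timedelta(seconds=60),
) -> RealTimeSample:
    """Fill a sample's missing sensors (-1) from a co-temporal fallback.

    The wearable sample wins wherever it has a reading; only sentinel fields
    are filled, and only when the two samples lie within ``tolerance`` of
    each other.  Beyond the tolerance the sample is returned unchanged and a
    warning is logged.
    """
    gap_ms = abs(sample.date - fallback.date)
    if gap_ms > tolerance.total_seconds() * 1000:
        logger.warning(
            "merge_missing: fallback %.1f s away exceeds tolerance %.1f s; "
            "sample kept unchanged",
            gap_ms / 1000,
            tolerance.total_seconds(),
        )
        return sample
    changes = {}
    for name in REALTIME_NUMERIC_FIELDS:
        if getattr(sample, name) == -1 and getattr(fallback, name) != -1:
            changes[name] = getattr(fallback, name)
    return sample.replace(**changes) if changes else sample
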