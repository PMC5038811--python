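"""End-to-end homogenization: vendor document -> unified sleep records.

This is the seam the store, the CLI and the tests share: one call takes a
raw vendor payload plus the envelope facts the dialect itself cannot carry
(calendar date for Fitbit, wake time for Jawbone, optional per-minute HR and
skin-temperature series) and returns unified per-night records, one per
sleep period, main period and naps labeled.
"""

from __future__ import annotations

from datetime import date, datetime, time, timedelta
from typing import Sequence
from zoneinfo import ZoneInfo

from .errors import ParameterError
from .harmonize import (
    SleepPeriod,
    UnifiedSleepRecord,
    assign_day,
    build_unified_record,
    fitbit_minutes_to_segments,
    jawbone_events_to_segments,
    label_main_and_naps,
    microsoft_segments_to_unified,
    split_into_periods,
)
from .vendor_ingest import (
    RecordIdentity,
    parse_fitbit_sleep,
    parse_jawbone_sleep,
    parse_microsoft_sleep,
)

__all__ = ["harmonize_document", "DIALECTS"]

DIALECTS = ("microsoft", "fitbit", "jawbone")


def _epoch_ms(day: date) -> int:
    return int(
        datetime.combine(day, time(0), tzinfo=ZoneInfo("UTC")).timestamp() * 1000
    )


def harmonize_document(
    document: str,
    dialect: str,
    *,
    student_id: str,
    device: str,
    day: date | None = None,
    wake_time: datetime | None = None,
    hr_series: Sequence[int] | None = None,
    temp_series: Sequence[float] | None = None,
    timezone_name: str = "UTC",
    gap_fill_max: timedelta = timedelta(minutes=180),
    cutoff: time = time(12, 0),
) -> list[UnifiedSleepRecord]:
    """Parse, segment and homogenize one vendor sleep document.

    ``day`` anchors Fitbit clock times (required for that dialect);
    ``wake_time`` closes the final Jawbone period (required there).  The
    optional per-minute series must cover the main period to be attached;
    mismatched series are dropped rather than guessed at.  Returns one
    record per sleep period of each assigned day, main period first.
    """
    tz = ZoneInfo(timezone_name)
    if dialect == "microsoft":
        segments = microsoft_segments_to_unified(
            parse_microsoft_sleep(document, timezone_name=timezone_name),
            gap_fill_max=gap_fill_max,
        )
    elif dialect == "fitbit":
        if day is None:
            raise ParameterError("fitbit documents need an anchoring date")
        segments = fitbit_minutes_to_segments(
            parse_fitbit_sleep(document), day, tzinfo=tz
        )
    elif dialect == "jawbone":
        if wake_time is None:
            raise ParameterError("jawbone documents need a wake time")
        if wake_time.tzinfo is None:
            wake_time = wake_time.replace(tzinfo=tz)
        segments = jawbone_events_to_segments(
            parse_jawbone_sleep(document), wake_time
        )
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    if not segments:
        return []

    by_day: dict[date, list[SleepPeriod]] = {}
    for block in split_into_periods(segments):
        assigned = assign_day(block[0].start, block[-1].end, cutoff=cutoff)
        by_day.setdefault(assigned, []).append(
            SleepPeriod(block, assigned, device=device)
        )

    records: list[UnifiedSleepRecord] = []
    for assigned in sorted(by_day):
        periods = label_main_and_naps(by_day[assigned])
        periods.sort(key=lambda p: (not p.is_main, p.start))
        naps = [p for p in periods if not p.is_main]
        for p in periods:
            n = int(p.duration.total_seconds() // 60)
            hr = hr_series if hr_series is not None and len(hr_series) == n else None
            temp = (
                temp_series
                if temp_series is not None and len(temp_series) == n
                else None
            )
            identity = RecordIdentity(
                record_id=f"{student_id}-{assigned.isoformat()}-{device}"
                + ("" if p.is_main else f"-nap{p.start.strftime('%H%M')}"),
                student_id=student_id,
                date=_epoch_ms(assigned),
                device=device,
            )
            records.append(
                build_unified_record(
                    identity, p, hr, temp, naps=naps if p.is_main else ()
                )
            )
    return records
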