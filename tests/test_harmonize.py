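"""Homogenization tests: state mapping, segmentation, day assignment,
unified-record construction and counter reconciliation — each non-trivial
operation checked against an independent brute-force oracle."""

import json
from datetime import date, datetime, time, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearharmonize.errors import ConsistencyError, VocabularyError
from wearharmonize.harmonize import (
    CounterPolicy,
    SleepPeriod,
    SleepSegment,
    UnifiedState,
    assign_day,
    build_unified_record,
    daily_total_from_cumulative,
    fitbit_minutes_to_segments,
    jawbone_events_to_segments,
    label_main_and_naps,
    map_state,
    merge_missing,
    microsoft_segments_to_unified,
    split_into_periods,
)
from wearharmonize.vendor_ingest import (
    FitbitMinuteRecord,
    JawboneDepthEvent,
    RealTimeSample,
    RecordIdentity,
    parse_microsoft_sleep,
)

UTC = timezone.utc
AWAKE, LIGHT, RELAXED = (UnifiedState.AWAKE, UnifiedState.LIGHT,
                         UnifiedState.RELAXED)


def minute_expansion(segments):
    """Oracle: expand segments minute by minute (state at minute midpoint)."""
    if not segments:
        return []
    out = []
    start = segments[0].start
    n = int((segments[-1].end - start).total_seconds() // 60)
    for i in range(n):
        mid = start + timedelta(minutes=i, seconds=30)
        out.append(next(s.state for s in segments if s.start <= mid < s.end))
    return out


class TestStateMapping:
    @pytest.mark.parametrize("vendor,state,expected", [
        ("fitbit", 1, LIGHT),
        ("fitbit", 2, AWAKE),
        ("fitbit", 3, AWAKE),        # "really awake" merges into awake
        ("jawbone", 1, AWAKE),
        ("jawbone", 2, LIGHT),
        ("jawbone", 3, RELAXED),
        ("microsoft", "Awake", AWAKE),
        ("microsoft", "Doze", AWAKE),
        ("microsoft", "Snooze", AWAKE),
        ("microsoft", "RestlessSleep", LIGHT),
        ("microsoft", "RestfulSleep", RELAXED),
        ("googlefit", "rem", RELAXED),
    ])
    def test_mapping_table(self, vendor, state, expected):
        assert map_state(vendor, state) is expected

    def test_undeclared_state(self):
        with pytest.raises(VocabularyError):
            map_state("fitbit", 4)
        with pytest.raises(VocabularyError):
            map_state("polar", 1)

    def test_override(self):
        assert map_state("googlefit", "rem",
                         overrides={"rem": LIGHT}) is LIGHT


def _fitbit_minutes(codes, start=time(23, 38)):
    base = datetime.combine(date(2016, 1, 5), start)
    return [
        FitbitMinuteRecord(((base + timedelta(minutes=i)).time()), code)
        for i, code in enumerate(codes)
    ]


class TestFitbitSegmentation:
    def test_run_length_example(self):
        segments = fitbit_minutes_to_segments(
            _fitbit_minutes([1, 1, 2]), date(2016, 1, 5)
        )
        assert [(s.state, s.start.time(), s.end.time()) for s in segments] == [
            (LIGHT, time(23, 38), time(23, 40)),
            (AWAKE, time(23, 40), time(23, 41)),
        ]

    def test_awake_codes_merge(self):
        segments = fitbit_minutes_to_segments(
            _fitbit_minutes([2, 3]), date(2016, 1, 5)
        )
        assert len(segments) == 1
        assert segments[0].state is AWAKE
        assert segments[0].duration == timedelta(minutes=2)

    def test_empty(self):
        assert fitbit_minutes_to_segments([], date(2016, 1, 5)) == []

    def test_midnight_wrap(self):
        segments = fitbit_minutes_to_segments(
            _fitbit_minutes([1, 1, 1], start=time(23, 59)), date(2016, 1, 5)
        )
        assert segments[0].start == datetime(2016, 1, 5, 23, 59)
        assert segments[0].end == datetime(2016, 1, 6, 0, 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_minute_oracle(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.integers(1, 4, size=480).tolist()
        segments = fitbit_minutes_to_segments(
            _fitbit_minutes(codes), date(2016, 1, 5)
        )
        assert minute_expansion(segments) == [
            map_state("fitbit", c) for c in codes
        ]
        changes = sum(
            map_state("fitbit", a) != map_state("fitbit", b)
            for a, b in zip(codes, codes[1:])
        )
        assert len(segments) == changes + 1


class TestJawboneSegmentation:
    T0 = 1442278000

    def test_two_record_rule(self):
        events = [JawboneDepthEvent(1, self.T0),
                  JawboneDepthEvent(2, self.T0 + 600)]
        wake = datetime.fromtimestamp(self.T0 + 1200, tz=UTC)
        segments = jawbone_events_to_segments(events, wake)
        assert [(s.state, int(s.start.timestamp()), int(s.end.timestamp()))
                for s in segments] == [
            (AWAKE, self.T0, self.T0 + 600),
            (LIGHT, self.T0 + 600, self.T0 + 1200),
        ]

    def test_zero_span(self):
        events = [JawboneDepthEvent(3, self.T0)]
        wake = datetime.fromtimestamp(self.T0, tz=UTC)
        assert jawbone_events_to_segments(events, wake) == []

    def test_wake_before_last_event(self):
        events = [JawboneDepthEvent(1, self.T0)]
        with pytest.raises(ConsistencyError):
            jawbone_events_to_segments(
                events, datetime.fromtimestamp(self.T0 - 60, tz=UTC)
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_span_conservation(self, seed):
        rng = np.random.default_rng(seed)
        times = self.T0 + np.cumsum(rng.integers(60, 1800, size=50))
        events = [
            JawboneDepthEvent(int(rng.integers(1, 4)), int(t)) for t in times
        ]
        wake = datetime.fromtimestamp(int(times[-1]) + 600, tz=UTC)
        segments = jawbone_events_to_segments(events, wake)
        covered = sum(s.duration.total_seconds() for s in segments)
        assert covered == wake.timestamp() - times[0]


class TestMicrosoftSegments:
    def _segment(self, start_min, end_min, segment_type="Sleep",
                 sleep_type="RestlessSleep"):
        base = datetime(2016, 1, 5, 23, 0, tzinfo=UTC)
        from wearharmonize.vendor_ingest import MicrosoftSleepSegment

        return MicrosoftSleepSegment(
            day_id=None, segment_id=start_min, segment_type=segment_type,
            sleep_type=sleep_type,
            start_time=base + timedelta(minutes=start_min),
            end_time=base + timedelta(minutes=end_min),
            duration=timedelta(minutes=end_min - start_min),
        )

    def test_worked_segment_maps_to_light(self, microsoft_segment_json):
        segments = microsoft_segments_to_unified(
            parse_microsoft_sleep(microsoft_segment_json)
        )
        assert len(segments) == 1
        assert segments[0].state is LIGHT
        assert segments[0].duration.total_seconds() == 297

    def test_adjacent_share_boundary(self):
        segs = microsoft_segments_to_unified([
            self._segment(0, 30), self._segment(30, 60, sleep_type="RestfulSleep"),
        ])
        assert len(segs) == 2
        assert segs[0].end == segs[1].start

    def test_gap_filled_as_awake(self):
        segs = microsoft_segments_to_unified([
            self._segment(0, 30), self._segment(33, 60),
        ])
        assert [s.state for s in segs] == [LIGHT, AWAKE, LIGHT]
        assert segs[1].duration == timedelta(minutes=3)

    def test_long_gap_splits_periods(self):
        segs = microsoft_segments_to_unified([
            self._segment(0, 30), self._segment(300, 360),
        ])
        periods = split_into_periods(segs)
        assert len(periods) == 2

    def test_overlap_rejected(self):
        with pytest.raises(ConsistencyError):
            microsoft_segments_to_unified([
                self._segment(0, 30), self._segment(20, 60),
            ])


class TestDayAssignment:
    @pytest.mark.parametrize("start,expected", [
        (datetime(2016, 1, 6, 23, 30), date(2016, 1, 6)),   # evening
        (datetime(2016, 1, 7, 1, 26), date(2016, 1, 6)),    # after midnight
        (datetime(2016, 1, 7, 14, 0), date(2016, 1, 7)),    # afternoon nap
        (datetime(2016, 1, 7, 12, 0), date(2016, 1, 7)),    # cutoff boundary
        (datetime(2016, 1, 7, 11, 59), date(2016, 1, 6)),
    ])
    def test_noon_cutoff(self, start, expected):
        assert assign_day(start, start + timedelta(hours=1)) == expected

    def test_degenerate_period(self):
        with pytest.raises(ConsistencyError):
            assign_day(datetime(2016, 1, 7), datetime(2016, 1, 7))


def _period(start, minutes, state=LIGHT, day=date(2016, 1, 6)):
    return SleepPeriod(
        [SleepSegment(state, start, start + timedelta(minutes=minutes))], day
    )


class TestMainAndNaps:
    def test_longest_is_main(self):
        night = _period(datetime(2016, 1, 6, 23, 0), 394)
        nap = _period(datetime(2016, 1, 7, 15, 0), 45)
        labeled = label_main_and_naps([night, nap])
        assert [p.is_main for p in labeled] == [True, False]

    def test_single_period_is_main(self):
        (p,) = label_main_and_naps([_period(datetime(2016, 1, 6, 23, 0), 100)])
        assert p.is_main

    def test_tie_breaks_to_earlier_start(self):
        first = _period(datetime(2016, 1, 6, 22, 0), 60)
        second = _period(datetime(2016, 1, 7, 2, 0), 60)
        labeled = label_main_and_naps([second, first])
        assert {p.start: p.is_main for p in labeled} == {
            first.start: True, second.start: False,
        }

    def test_empty(self):
        assert label_main_and_naps([]) == []


class TestUnifiedRecord:
    IDENTITY = RecordIdentity("r1", "student-1", 1437523200000,
                              device="Microsoft_Api")

    def _reference_period(self):
        base = datetime(2016, 1, 6, 23, 0, tzinfo=UTC)

        def seg(state, start_min, end_min):
            return SleepSegment(state, base + timedelta(minutes=start_min),
                                base + timedelta(minutes=end_min))

        # 86 awake / 221 light / 87 relaxed = 394 total
        return SleepPeriod(
            [seg(AWAKE, 0, 11), seg(LIGHT, 11, 150), seg(AWAKE, 150, 225),
             seg(RELAXED, 225, 312), seg(LIGHT, 312, 394)],
            date(2016, 1, 6),
            is_main=True,
        )

    def test_reference_counts(self):
        record = build_unified_record(self.IDENTITY, self._reference_period())
        assert record.total_time_data == 394
        assert (record.awake, record.light, record.relaxed) == (86, 221, 87)
        assert len(record.minutes_awake) == 394
        assert record.time_to_sleep_data == 11
        assert record.time_to_sleep == "00:11:00"
        assert record.num_awake == 1          # one interior awakening
        assert record.sleep_efficiency == 78  # round(100 * 308/394)
        assert record.hr_min == -1            # no HR series supplied
        assert record.temp_mean == -1

    def test_one_hot_and_conservation(self):
        record = build_unified_record(self.IDENTITY, self._reference_period())
        for i in range(record.total_time_data):
            assert (record.minutes_awake[i] + record.minutes_light[i]
                    + record.minutes_relaxed[i]) == 1
        assert sum(record.minutes_light) == record.light

    def test_hr_and_temp_series(self):
        period = self._reference_period()
        hr = [64] * 394
        hr[100] = 56
        temp = [34.56] * 394
        record = build_unified_record(self.IDENTITY, period, hr, temp)
        assert record.hr_min == 56
        assert record.temp_mean == 34.56
        assert record.minutes_hr == hr

    def test_series_length_mismatch(self):
        with pytest.raises(ConsistencyError):
            build_unified_record(self.IDENTITY, self._reference_period(),
                                 hr_series=[64] * 10)

    def test_all_awake_night(self):
        base = datetime(2016, 1, 6, 23, 0, tzinfo=UTC)
        period = SleepPeriod(
            [SleepSegment(AWAKE, base, base + timedelta(minutes=30))],
            date(2016, 1, 6),
        )
        record = build_unified_record(self.IDENTITY, period)
        assert record.time_to_sleep_data == record.total_time_data == 30
        assert record.num_awake == 0
        assert record.light == record.relaxed == 0
        assert record.sleep_efficiency == 0

    def test_time_to_sleep_truncates_subminute_span(self):
        base = datetime(2016, 1, 6, 23, 0, 36, tzinfo=UTC)
        onset = datetime(2016, 1, 6, 23, 12, 0, tzinfo=UTC)
        period = SleepPeriod(
            [SleepSegment(AWAKE, base, onset),
             SleepSegment(LIGHT, onset, base + timedelta(minutes=100))],
            date(2016, 1, 6),
        )
        record = build_unified_record(self.IDENTITY, period)
        assert record.time_to_sleep == "00:11:24"
        assert record.time_to_sleep_data == 11

    def test_trailing_wake_not_an_awakening(self):
        base = datetime(2016, 1, 6, 23, 0, tzinfo=UTC)

        def seg(state, a, b):
            return SleepSegment(state, base + timedelta(minutes=a),
                                base + timedelta(minutes=b))

        period = SleepPeriod(
            [seg(AWAKE, 0, 10), seg(LIGHT, 10, 100), seg(AWAKE, 100, 105),
             seg(LIGHT, 105, 200), seg(AWAKE, 200, 210)],
            date(2016, 1, 6),
        )
        record = build_unified_record(self.IDENTITY, period)
        assert record.num_awake == 1

    def test_naps_enter_efficiency_only(self):
        period = self._reference_period()
        nap = _period(datetime(2016, 1, 7, 15, 0, tzinfo=UTC), 60, AWAKE)
        record = build_unified_record(self.IDENTITY, period, naps=[nap])
        # proposal covers the main period only; efficiency covers the day
        assert record.efficiency_proposal == 78
        assert record.sleep_efficiency == round(100 * 308 / 454)
        assert record.total_time_data == 394

    def test_json_round_trip(self):
        from wearharmonize.harmonize import UnifiedSleepRecord

        record = build_unified_record(self.IDENTITY, self._reference_period(),
                                      [60] * 394, [34.5] * 394)
        doc = json.loads(json.dumps(record.to_json()))
        assert set(doc["data"]) == {
            "total_time_data", "time_to_sleep_data", "temp_mean", "hr_min",
            "num_awake", "awake", "light", "relaxed", "sleep_efficiency",
            "efficiency_proposal", "start_hour", "end_hour", "total_time",
            "time_to_sleep",
        }
        assert set(doc["list"]) == {"awake", "light", "relaxed", "time", "hr"}
        assert UnifiedSleepRecord.from_json(doc) == record


def counter_oracle(increments, reboots, policy, base):
    """Oracle: reconstruct readings from ground-truth increments, return
    (readings, true total between first and last sample)."""
    readings = [base]
    for inc, reboot in zip(increments, reboots):
        readings.append(inc if reboot else readings[-1] + inc)
    return readings, sum(increments)


class TestCounters:
    def test_since_forever(self):
        assert daily_total_from_cumulative(
            [100000, 100820, 103150], CounterPolicy.SINCE_FOREVER
        ) == 3150

    def test_daily_reset(self):
        assert daily_total_from_cumulative(
            [340, 2100, 8817], CounterPolicy.DAILY_RESET
        ) == 8817

    def test_reset_on_reboot_counts_increments(self):
        # 150 before the reboot, then 10 accrued from zero, then 50 more
        assert daily_total_from_cumulative(
            [100, 250, 10, 60], CounterPolicy.RESET_ON_REBOOT
        ) == 210

    def test_empty(self):
        for policy in CounterPolicy:
            assert daily_total_from_cumulative([], policy) == 0

    def test_timestamped_pairs_accepted(self):
        samples = [(0, 100), (60, 150)]
        assert daily_total_from_cumulative(
            samples, CounterPolicy.SINCE_FOREVER
        ) == 50

    def test_negative_total_rejected(self):
        with pytest.raises(ConsistencyError):
            daily_total_from_cumulative([500, 100],
                                        CounterPolicy.SINCE_FOREVER)

    @given(
        steps=st.lists(
            st.tuples(st.integers(min_value=0, max_value=500), st.booleans()),
            min_size=1, max_size=40,
        ),
        base=st.integers(min_value=501, max_value=5000),
    )
    @settings(max_examples=100, deadline=None)
    def test_reboot_policy_recovers_true_event_count(self, steps, base):
        """Ground truth: a known number of events occurs between samples and
        the counter occasionally reboots at a sampling instant.  The
        reconciled daily total must equal the number of events that occurred
        (reboots are only injected where the drop is detectable)."""
        readings = [base]
        true_events = 0
        for events, want_reboot in steps:
            if want_reboot and events < readings[-1]:
                readings.append(events)  # counter zeroed, then accrued
            else:
                readings.append(readings[-1] + events)
            true_events += events
        assert daily_total_from_cumulative(
            readings, CounterPolicy.RESET_ON_REBOOT
        ) == true_events


class TestMergeMissing:
    BAND = RealTimeSample(device="band-1", date=1000_000, hrValue=64)
    PHONE = RealTimeSample(device="phone-1", date=1000_000, hrValue=70,
                           speedValue=1.4)

    def test_fill_rule(self):
        merged = merge_missing(self.BAND, self.PHONE)
        assert merged.speedValue == 1.4
        assert merged.hrValue == 64  # wearable preferred

    def test_both_missing_stays_missing(self):
        merged = merge_missing(self.BAND, RealTimeSample("phone-1", 1000_000))
        assert merged.speedValue == -1

    def test_beyond_tolerance_unchanged(self, caplog):
        far = RealTimeSample(device="phone-1", date=1000_000 + 120_000,
                             speedValue=2.0)
        with caplog.at_level("WARNING"):
            merged = merge_missing(self.BAND, far)
        assert merged == self.BAND
        assert any("tolerance" in r.message for r in caplog.records)
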