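"""Synthetic wearable-data simulator.

Everything downstream of the parsers is testable without any real device:
this module generates ground-truth nights as semi-Markov state timelines,
renders them into each supported vendor dialect (so parser + harmonizer can
be checked against the truth), simulates real-time sensor streams, and
builds labeled cohorts for the indicator-recovery experiments.

The night model alternates AWAKE -> LIGHT <-> RELAXED with exponential-like
integer-minute dwell times: an initial sleep-onset latency in bed, then
light/deep sleep cycles, with interior awakenings inserted after a sleep
dwell with a fixed probability.  Heart rate is sampled per state with
RELAXED mean < LIGHT mean < AWAKE mean; skin temperature and accelerometer
magnitude follow the same per-state structure.  All draws flow from one
seeded generator per call, so every output is a pure function of
(parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta, timezone
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .harmonize import SleepSegment, UnifiedState, assign_day
from .indicators import QuizAnswer
from .vendor_ingest import RealTimeSample, format_iso_duration

__all__ = [
    "NightParams",
    "TruthTimeline",
    "CohortSpec",
    "SimulatedNight",
    "SimulatedStudent",
    "SimulatedCohort",
    "simulate_night",
    "render_microsoft",
    "render_fitbit",
    "render_jawbone",
    "render_document",
    "simulate_sensor_stream",
    "simulate_state_windows",
    "simulate_cohort",
    "sq_true_label",
    "sleepiness_label",
    "stress_label",
]

_MINUTE = timedelta(minutes=1)

#: Per-state heart-rate means (bpm): relaxed < light < awake.
HR_MEANS = {UnifiedState.AWAKE: 70.0, UnifiedState.LIGHT: 60.0,
            UnifiedState.RELAXED: 52.0}
#: Per-state accelerometer magnitude means (g).
ACCEL_MEANS = {UnifiedState.AWAKE: 0.30, UnifiedState.LIGHT: 0.05,
               UnifiedState.RELAXED: 0.02}


@dataclass(frozen=True)
class NightParams:
    """Parameters of the semi-Markov night generator.

    Dwell means are in minutes; ``awakening_rate`` is the probability of an
    interior awakening after each sleep dwell.  Defaults emulate a typical
    adult night: ~7 h asleep, 10 min onset latency, 20/15-min light/deep
    cycles, a few brief awakenings.
    """

    bedtime: time = time(23, 30)
    bedtime_sd_min: float = 40.0
    latency_mean_min: float = 10.0
    light_dwell_mean_min: float = 20.0
    relaxed_dwell_mean_min: float = 15.0
    awake_dwell_mean_min: float = 3.0
    awakening_rate: float = 0.15
    sleep_duration_mean_min: float = 420.0
    sleep_duration_sd_min: float = 30.0
    hr_sd: float = 2.0
    temp_base: float = 34.5
    temp_night_sd: float = 0.3
    temp_minute_sd: float = 0.05

    def validate(self) -> None:
        for name in ("latency_mean_min", "light_dwell_mean_min",
                     "relaxed_dwell_mean_min", "awake_dwell_mean_min",
                     "sleep_duration_mean_min"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 <= self.awakening_rate <= 1:
            raise ParameterError("awakening_rate must lie in [0, 1]")


@dataclass
class TruthTimeline:
    """Ground-truth night: contiguous state segments plus per-minute traces."""

    night_id: str
    segments: list[SleepSegment]
    hr_trace: list[int]
    temp_trace: list[float]
    accel_trace: list[float]
    seed: int

    @property
    def start(self) -> datetime:
        return self.segments[0].start

    @property
    def end(self) -> datetime:
        return self.segments[-1].end

    @property
    def n_minutes(self) -> int:
        return int((self.end - self.start).total_seconds() // 60)

    def per_state_minutes(self) -> dict[UnifiedState, int]:
        counts = {s: 0 for s in UnifiedState}
        for seg in self.segments:
            counts[seg.state] += int(seg.duration.total_seconds() // 60)
        return counts

    def num_interior_awakenings(self) -> int:
        return sum(
            1 for seg in self.segments[1:-1] if seg.state is UnifiedState.AWAKE
        )

    def to_json(self) -> dict:
        return {
            "night_id": self.night_id,
            "seed": self.seed,
            "segments": [
                {
                    "state": seg.state.value,
                    "start": seg.start.isoformat(),
                    "end": seg.end.isoformat(),
                }
                for seg in self.segments
            ],
            "hr": self.hr_trace,
            "temp": self.temp_trace,
            "accel": self.accel_trace,
        }


def _dwell(rng: np.random.Generator, mean_min: float) -> int:
    """Exponential-like integer dwell: geometric minutes with the given mean."""
    return int(rng.geometric(min(1.0, 1.0 / mean_min)))


def simulate_night(
    params: NightParams = NightParams(),
    seed: int = 0,
    *,
    night_id: str = "night",
    day: date = date(2016, 1, 4),
    tzinfo=timezone.utc,
) -> TruthTimeline:
    """Generate one ground-truth night.

    The timeline starts with the in-bed latency (AWAKE), alternates LIGHT
    and RELAXED dwells until the drawn sleep budget is spent, and inserts an
    AWAKE dwell after a sleep dwell with probability ``awakening_rate``.
    ``day`` is the evening's calendar date; a bedtime before noon is placed
    on the following morning.
    """
    params.validate()
    rng = np.random.default_rng(seed)

    offset = rng.normal(0.0, params.bedtime_sd_min)
    offset = float(np.clip(offset, -3 * params.bedtime_sd_min,
                           3 * params.bedtime_sd_min))
    bed_naive = datetime.combine(day, params.bedtime) + timedelta(
        minutes=round(offset)
    )
    if params.bedtime < time(12, 0):  # after-midnight bedtime -> next morning
        bed_naive += timedelta(days=1)
    bed = bed_naive.replace(tzinfo=tzinfo)

    budget = int(
        max(
            60,
            round(rng.normal(params.sleep_duration_mean_min,
                             params.sleep_duration_sd_min)),
        )
    )

    states: list[tuple[UnifiedState, int]] = [
        (UnifiedState.AWAKE, _dwell(rng, params.latency_mean_min))
    ]
    slept = 0
    sleep_state = UnifiedState.LIGHT
    while slept < budget:
        dwell = min(_dwell(
            rng,
            params.light_dwell_mean_min
            if sleep_state is UnifiedState.LIGHT
            else params.relaxed_dwell_mean_min,
        ), budget - slept)
        states.append((sleep_state, dwell))
        slept += dwell
        if slept < budget and rng.random() < params.awakening_rate:
            states.append((UnifiedState.AWAKE, _dwell(rng, params.awake_dwell_mean_min)))
        sleep_state = (
            UnifiedState.RELAXED
            if sleep_state is UnifiedState.LIGHT
            else UnifiedState.LIGHT
        )

    segments: list[SleepSegment] = []
    cursor = bed
    for state, dwell in states:
        if dwell <= 0:
            continue
        end = cursor + dwell * _MINUTE
        if segments and segments[-1].state == state:
            segments[-1] = SleepSegment(state, segments[-1].start, end)
        else:
            segments.append(SleepSegment(state, cursor, end))
        cursor = end

    truth = TruthTimeline(night_id, segments, [], [], [], seed)
    _fill_traces(truth, rng, params)
    return truth


def _fill_traces(truth: TruthTimeline, rng: np.random.Generator,
                 params: NightParams) -> None:
    night_temp = params.temp_base + float(
        rng.normal(0.0, params.temp_night_sd)
    )
    hr, temp, accel = [], [], []
    for i in range(truth.n_minutes):
        mid = truth.start + i * _MINUTE + timedelta(seconds=30)
        state = next(s.state for s in truth.segments if s.start <= mid < s.end)
        hr.append(int(np.clip(round(rng.normal(HR_MEANS[state], params.hr_sd)),
                              35, 180)))
        temp.append(round(night_temp + float(rng.normal(0, params.temp_minute_sd)), 2))
        accel.append(round(max(0.0, float(rng.normal(ACCEL_MEANS[state], 0.02))), 4))
    truth.hr_trace, truth.temp_trace, truth.accel_trace = hr, temp, accel


# ---------------------------------------------------------------------------
# Vendor renderers
# ---------------------------------------------------------------------------

_MS_VENDOR_STATE = {
    UnifiedState.AWAKE: ("Awake", "Unknown"),
    UnifiedState.LIGHT: ("Sleep", "RestlessSleep"),
    UnifiedState.RELAXED: ("Sleep", "RestfulSleep"),
}
_JAWBONE_CODE = {UnifiedState.AWAKE: 1, UnifiedState.LIGHT: 2,
                 UnifiedState.RELAXED: 3}

#: Interior awakenings at least this long render as Fitbit "really awake".
REALLY_AWAKE_MIN = 3


def render_microsoft(
    truth: TruthTimeline,
    *,
    seed: int | None = None,
    boundary_jitter_s: float = 0.0,
) -> str:
    """Render a truth timeline as a Microsoft-dialect JSON array.

    One object per segment with vendor vocabulary, ISO timestamps, ISO-8601
    duration and a per-segment HR summary from the trace.  With a seed, a
    sub-minute phase offset is applied to every boundary (the vendor's
    timestamps are not minute-aligned), and interior boundaries may get
    extra jitter up to ``boundary_jitter_s`` seconds.
    """
    bounds = [truth.segments[0].start] + [s.end for s in truth.segments]
    if seed is not None:
        rng = np.random.default_rng(seed)
        phase = timedelta(seconds=float(rng.uniform(0, 59)))
        bounds = [b + phase for b in bounds]
        if boundary_jitter_s > 0:
            for i in range(1, len(bounds) - 1):
                jitter = timedelta(seconds=float(
                    rng.uniform(-boundary_jitter_s, boundary_jitter_s)
                ))
                shifted = bounds[i] + jitter
                if bounds[i - 1] < shifted < bounds[i + 1]:
                    bounds[i] = shifted
        # timestamps are serialized at millisecond precision
        bounds = [b.replace(microsecond=(b.microsecond // 1000) * 1000)
                  for b in bounds]
    day_id = truth.end.date()
    docs = []
    for idx, (seg, start, end) in enumerate(
        zip(truth.segments, bounds, bounds[1:])
    ):
        segment_type, sleep_type = _MS_VENDOR_STATE[seg.state]
        first = int((seg.start - truth.start).total_seconds() // 60)
        last = max(first, int((seg.end - truth.start).total_seconds() // 60) - 1)
        hr_slice = truth.hr_trace[first : last + 1] or [60]
        avg = int(round(sum(hr_slice) / len(hr_slice)))
        docs.append(
            {
                "dayId": datetime.combine(day_id, time(0), tzinfo=timezone.utc)
                .isoformat(timespec="milliseconds"),
                "sleepType": sleep_type,
                "segmentId": 635780414429706039 + idx,
                "startTime": start.isoformat(timespec="milliseconds"),
                "endTime": end.isoformat(timespec="milliseconds"),
                "duration": format_iso_duration(end - start),
                "heartRateSummary": {
                    "period": "Segment",
                    "averageHeartRate": avg,
                    "peakHeartRate": max(max(hr_slice), avg),
                    "lowestHeartRate": min(min(hr_slice), avg),
                },
                "segmentType": segment_type,
            }
        )
    return json.dumps(docs)


def render_fitbit(truth: TruthTimeline) -> str:
    """Render a truth timeline as Fitbit minute-by-minute codes.

    Sleep minutes (LIGHT and RELAXED alike: the dialect has no depth) render
    as code 1; AWAKE minutes render as 3 ("really awake") when their segment
    lasts at least ``REALLY_AWAKE_MIN`` minutes and as 2 otherwise.
    """
    records = []
    for i in range(truth.n_minutes):
        ts = truth.start + i * _MINUTE
        mid = ts + timedelta(seconds=30)
        seg = next(s for s in truth.segments if s.start <= mid < s.end)
        if seg.state is UnifiedState.AWAKE:
            code = 3 if seg.duration >= REALLY_AWAKE_MIN * _MINUTE else 2
        else:
            code = 1
        records.append({"dateTime": ts.strftime("%H:%M:%S"), "value": str(code)})
    return json.dumps(records)


def render_jawbone(truth: TruthTimeline) -> str:
    """Render a truth timeline as Jawbone depth events.

    One event per state change (the reverse of the two-record segmentation
    rule); the final wake time is withheld, as the dialect requires.
    """
    events = [
        {"depth": _JAWBONE_CODE[seg.state], "time": int(seg.start.timestamp())}
        for seg in truth.segments
    ]
    return json.dumps(events)


def render_document(truth: TruthTimeline, dialect: str, *,
                    seed: int | None = None) -> str:
    """Render ``truth`` in the named dialect."""
    if dialect == "microsoft":
        return render_microsoft(truth, seed=seed)
    if dialect == "fitbit":
        return render_fitbit(truth)
    if dialect == "jawbone":
        return render_jawbone(truth)
    raise ParameterError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Real-time sensor streams
# ---------------------------------------------------------------------------

def simulate_sensor_stream(
    truth: TruthTimeline,
    *,
    device: str = "band-0",
    dropout_p: float = 0.0,
    policy: str = "since_forever",
    reboot_p: float = 0.01,
    seed: int = 0,
) -> list[RealTimeSample]:
    """One real-time sample per minute of the truth timeline.

    HR/temperature/acceleration come from the traces; steps and calories
    are cumulative counters following the given reset policy (lower-case
    :class:`~wearharmonize.harmonize.CounterPolicy` value).  Each sensor
    reading is independently replaced by the -1 sentinel with probability
    ``dropout_p`` (counters and the worn flag are not subject to dropout).
    """
    if not 0 <= dropout_p <= 1:
        raise ParameterError("dropout_p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if policy == "since_forever":
        steps = int(rng.integers(50_000, 150_000))
        calories = int(rng.integers(200_000, 400_000))
    else:
        steps = 0
        calories = 0
    samples = []
    distance = 0.0
    for i in range(truth.n_minutes):
        ts = truth.start + i * _MINUTE
        mid = ts + timedelta(seconds=30)
        state = next(s.state for s in truth.segments if s.start <= mid < s.end)
        if policy == "reset_on_reboot" and i > 0 and rng.random() < reboot_p:
            steps = 0
            calories = 0
        step_inc = int(rng.integers(0, 30)) if state is UnifiedState.AWAKE else 0
        steps += step_inc
        calories += 1 + (2 if state is UnifiedState.AWAKE else 0)
        distance += step_inc * 0.7

        def _drop(value):
            return -1 if rng.random() < dropout_p else value

        samples.append(
            RealTimeSample(
                device=device,
                date=int(ts.timestamp() * 1000),
                wear=1,
                resistence=_drop(int(rng.normal(320, 25))),
                uvValue="low",
                typeWalk="none",
                tempValue=_drop(truth.temp_trace[i]),
                speedValue=_drop(round(step_inc * 0.7 / 60, 3)),
                disValue=_drop(round(distance, 1)),
                accelValue=_drop(truth.accel_trace[i]),
                stepsValue=steps,
                caloriesValue=calories,
                hrValue=_drop(truth.hr_trace[i]),
                typeStudy="sleep",
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Label functions (the cohort's injected ground truth)
# ---------------------------------------------------------------------------

def sq_true_label(duration_min: int, awake_min: int) -> int:
    """The injected rest-feeling label: monotone in sleep duration, penalized
    by time awake (the observable footprint of awakenings).

    8 for an adequate night (>= 6.5 h), 6 for a shortened one (>= 5.5 h), 4
    below, minus 1 for a heavily disrupted night (45+ awake minutes).
    """
    base = 8 if duration_min >= 390 else 6 if duration_min >= 330 else 4
    penalty = 1 if awake_min >= 45 else 0
    return max(0, min(10, base - penalty))


def sleepiness_label(hr_mean: float) -> int:
    """Injected sleepiness level 0..4 by heart-rate thresholds (lower HR,
    sleepier)."""
    for level, bound in ((4, 55.5), (3, 60.5), (2, 65.5), (1, 70.5)):
        if hr_mean < bound:
            return level
    return 0


def stress_label(gsr_mean: float, accel_mean: float | None = None) -> int:
    """Injected stress level 0..4 from galvanic skin resistance (lower
    resistance, more stressed); accelerometer activity thresholds apply when
    GSR is unavailable (higher activity, more stressed)."""
    if gsr_mean == -1:
        if accel_mean is None:
            raise ParameterError("need accel_mean when GSR is unavailable")
        for level, bound in ((0, 0.10), (1, 0.20), (2, 0.30), (3, 0.40)):
            if accel_mean < bound:
                return level
        return 4
    for level, bound in ((4, 280.0), (3, 320.0), (2, 360.0), (1, 400.0)):
        if gsr_mean < bound:
            return level
    return 0


#: Per-level generator means for the state windows.
_SLEEPINESS_HR = {0: 73.0, 1: 68.0, 2: 63.0, 3: 58.0, 4: 52.0}
_STRESS_GSR = {0: 420.0, 1: 380.0, 2: 340.0, 3: 300.0, 4: 260.0}
_STRESS_ACCEL = {0: 0.05, 1: 0.15, 2: 0.25, 3: 0.35, 4: 0.45}


def simulate_state_windows(
    kind: str,
    n_windows: int,
    seed: int = 0,
    *,
    window_min: int = 10,
    device: str = "band-0",
    gsr_available: bool = True,
) -> list[tuple[list[RealTimeSample], int]]:
    """Generate labeled 10-minute sensor windows for sleepiness/stress.

    Each window draws a target level 0..4, samples the sensors around that
    level, and labels the window by the stated threshold function applied to
    the realized window statistics — so the label is a deterministic
    function of what a feature extractor can observe.
    """
    kind = kind.upper()
    if kind not in ("SLEEPINESS", "STRESS"):
        raise ParameterError(f"kind must be SLEEPINESS or STRESS, got {kind!r}")
    rng = np.random.default_rng(seed)
    base = datetime(2016, 1, 4, 0, 0, tzinfo=timezone.utc)
    windows = []
    for w in range(n_windows):
        level = int(rng.integers(0, 5))
        hr_mu = _SLEEPINESS_HR[level] if kind == "SLEEPINESS" else float(
            rng.uniform(55, 75)
        )
        samples = []
        hr_values, gsr_values, accel_values = [], [], []
        for m in range(window_min):
            ts = base + timedelta(minutes=w * (window_min + 5) + m)
            hr = round(float(rng.normal(hr_mu, 1.5)), 1)
            if kind == "STRESS":
                gsr = int(round(rng.normal(_STRESS_GSR[level], 8.0)))
                accel = max(0.0, round(float(
                    rng.normal(_STRESS_ACCEL[level], 0.01)), 4))
            else:
                gsr = int(round(rng.normal(330, 10)))
                accel = max(0.0, round(float(
                    rng.normal(0.05 + 0.05 * (4 - level), 0.01)), 4))
            st = round(33.5 + 0.2 * level + float(rng.normal(0, 0.1)), 2)
            hr_values.append(hr)
            gsr_values.append(gsr)
            accel_values.append(accel)
            samples.append(
                RealTimeSample(
                    device=device,
                    date=int(ts.timestamp() * 1000),
                    wear=1,
                    resistence=gsr if gsr_available else -1,
                    tempValue=st,
                    accelValue=accel,
                    hrValue=hr,
                    stepsValue=0,
                    caloriesValue=0,
                    speedValue=0.0,
                    disValue=0.0,
                )
            )
        if kind == "SLEEPINESS":
            label = sleepiness_label(sum(hr_values) / len(hr_values))
        else:
            gsr_mean = (
                sum(gsr_values) / len(gsr_values) if gsr_available else -1
            )
            label = stress_label(gsr_mean, sum(accel_values) / len(accel_values))
        windows.append((samples, label))
    return windows


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Persona bedtime windows (uniform draw) and wake-time clamp ranges.  The
#: morning persona goes to bed before 21:30 and is up before 05:00; the
#: evening persona after 02:00 / 10:00; the intermediate persona in between.
_PERSONAS = {
    "morning": {
        "bed_lo": time(20, 30), "bed_hi": time(21, 10),
        "wake_lo": time(4, 0), "wake_hi": time(4, 55),
    },
    "evening": {
        "bed_lo": time(2, 30), "bed_hi": time(3, 30),
        "wake_lo": time(10, 5), "wake_hi": time(11, 30),
    },
    "intermediate": {
        "bed_lo": time(23, 0), "bed_hi": time(0, 30),
        "wake_lo": time(6, 45), "wake_hi": time(8, 15),
    },
}

_VENDOR_CYCLE = ("microsoft", "fitbit", "jawbone")
_DEVICE_NAME = {"microsoft": "Microsoft_Api", "fitbit": "Fitbit_Api",
                "jawbone": "Jawbone_Api"}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a simulated cohort."""

    n_students: int = 4
    nights_per_student: int = 30
    persona: str = "intermediate"
    start_day: date = date(2016, 1, 4)  # a Monday
    hr_sd: float = 2.0
    dropout_p: float = 0.05
    quiz_noise_p: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_students < 1 or self.nights_per_student < 1:
            raise ParameterError("cohort sizes must be >= 1")
        if not 0 <= self.dropout_p <= 1 or not 0 <= self.quiz_noise_p <= 1:
            raise ParameterError("probabilities must lie in [0, 1]")
        if self.persona not in _PERSONAS:
            raise ParameterError(f"unknown persona {self.persona!r}")


@dataclass
class SimulatedNight:
    """One simulated night of one student, plus its vendor rendering."""

    day: date  # assigned calendar day (the evening the night belongs to)
    truth: TruthTimeline
    dialect: str
    document: str
    wake_time: datetime
    quiz: QuizAnswer
    true_rest: int


@dataclass
class SimulatedStudent:
    student_id: str
    device: str
    dialect: str
    nights: list[SimulatedNight] = field(default_factory=list)


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    students: list[SimulatedStudent]
    calendar: dict[str, str]  # date -> "working" | "nonworking"
    sleepiness_windows: list[tuple[list[RealTimeSample], int]]
    stress_windows: list[tuple[list[RealTimeSample], int]]

    def write(self, out_dir: str | Path) -> dict[str, int]:
        """Write vendor documents plus truth/quiz/calendar/label sidecars."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        counts = {"documents": 0, "nights": 0}
        with (
            open(out / "truth.jsonl", "w") as truth_f,
            open(out / "quiz.jsonl", "w") as quiz_f,
            open(out / "labels.jsonl", "w") as labels_f,
            open(out / "nights.jsonl", "w") as nights_f,
        ):
            for student in self.students:
                for night in student.nights:
                    stem = f"{student.student_id}_{night.day.isoformat()}_{night.dialect}"
                    (out / f"{stem}.json").write_text(night.document)
                    counts["documents"] += 1
                    counts["nights"] += 1
                    truth_f.write(json.dumps({
                        "student_id": student.student_id,
                        "date": night.day.isoformat(),
                        **night.truth.to_json(),
                    }) + "\n")
                    quiz_f.write(json.dumps(night.quiz.to_json()) + "\n")
                    labels_f.write(json.dumps({
                        "kind": "SQ",
                        "student_id": student.student_id,
                        "date": night.day.isoformat(),
                        "label": night.true_rest,
                    }) + "\n")
                    nights_f.write(json.dumps({
                        "student_id": student.student_id,
                        "device": student.device,
                        "dialect": night.dialect,
                        "date": night.day.isoformat(),
                        # calendar date of the first sample: anchors the
                        # date-less Fitbit clock times
                        "start_date": night.truth.start.date().isoformat(),
                        "wake_time": night.wake_time.isoformat(),
                        "hr": night.truth.hr_trace,
                        "temp": night.truth.temp_trace,
                        "payload": json.loads(night.document),
                        "document_file": f"{stem}.json",
                    }) + "\n")
            for kind, windows in (("SLEEPINESS", self.sleepiness_windows),
                                  ("STRESS", self.stress_windows)):
                for i, (samples, label) in enumerate(windows):
                    labels_f.write(json.dumps({
                        "kind": kind, "window": i, "label": label,
                    }) + "\n")
                    (out / f"windows_{kind.lower()}_{i:03d}.json").write_text(
                        json.dumps([s.to_json() for s in samples])
                    )
        (out / "calendar.json").write_text(json.dumps(self.calendar, indent=1))
        return counts


def _clamp_end(truth: TruthTimeline, lo: datetime, hi: datetime,
               rng: np.random.Generator, params: NightParams) -> TruthTimeline:
    """Force the night to end inside [lo, hi] by trimming or extending the
    final sleep segment, keeping traces aligned."""
    target = truth.end
    if target > hi:
        target = hi
    elif target < lo:
        target = lo
    if target == truth.end:
        return truth
    segments = []
    for seg in truth.segments:
        if seg.end <= target:
            segments.append(seg)
        elif seg.start < target:
            segments.append(SleepSegment(seg.state, seg.start, target))
    if not segments:
        raise ParameterError("clamp window precedes the whole night")
    if segments[-1].end < target:  # extend the final segment
        last = segments[-1]
        segments[-1] = SleepSegment(last.state, last.start, target)
    clamped = TruthTimeline(truth.night_id, segments, [], [], [], truth.seed)
    n = clamped.n_minutes
    if n <= len(truth.hr_trace):
        clamped.hr_trace = truth.hr_trace[:n]
        clamped.temp_trace = truth.temp_trace[:n]
        clamped.accel_trace = truth.accel_trace[:n]
    else:
        clamped.hr_trace = list(truth.hr_trace)
        clamped.temp_trace = list(truth.temp_trace)
        clamped.accel_trace = list(truth.accel_trace)
        state = segments[-1].state
        night_temp = truth.temp_trace[-1] if truth.temp_trace else params.temp_base
        for _ in range(n - len(truth.hr_trace)):
            clamped.hr_trace.append(int(np.clip(
                round(rng.normal(HR_MEANS[state], params.hr_sd)), 35, 180)))
            clamped.temp_trace.append(
                round(night_temp + float(rng.normal(0, params.temp_minute_sd)), 2))
            clamped.accel_trace.append(
                round(max(0.0, float(rng.normal(ACCEL_MEANS[state], 0.02))), 4))
    return clamped


def _noisy_quiz(true_label: int, p: float, rng: np.random.Generator) -> int:
    if rng.random() < p:
        return int(np.clip(true_label + rng.choice([-1, 1]), 0, 10))
    return true_label


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> SimulatedCohort:
    """Simulate a labeled cohort in every vendor dialect.

    Students cycle through the three dialects; each night carries its truth
    timeline, its rendered vendor document, the (noisy) quiz answer, and the
    noise-free injected rest-feeling label.  A working/non-working calendar
    (weekdays vs weekends) and labeled sleepiness/stress windows round out
    the collections.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    persona = _PERSONAS[spec.persona]

    students = []
    calendar: dict[str, str] = {}
    for s in range(spec.n_students):
        dialect = _VENDOR_CYCLE[s % len(_VENDOR_CYCLE)]
        student = SimulatedStudent(
            student_id=f"student-{s:02d}",
            device=_DEVICE_NAME[dialect],
            dialect=dialect,
        )
        for d in range(spec.nights_per_student):
            day = spec.start_day + timedelta(days=d)
            calendar[day.isoformat()] = (
                "working" if day.weekday() < 5 else "nonworking"
            )
            bed_lo = datetime.combine(day, persona["bed_lo"])
            bed_hi = datetime.combine(day, persona["bed_hi"])
            if persona["bed_lo"] < time(12, 0):
                bed_lo += timedelta(days=1)
                bed_hi += timedelta(days=1)
            elif persona["bed_hi"] < time(12, 0):
                bed_hi += timedelta(days=1)
            span_min = int((bed_hi - bed_lo).total_seconds() // 60)
            bed = (bed_lo + timedelta(minutes=int(rng.integers(0, span_min + 1))))
            # Nights are a calm/disrupted mixture: disrupted nights awaken
            # often and for longer, so total awake time is bimodal around
            # the rest-feeling penalty boundary.
            disrupted = rng.random() < 0.15
            params = NightParams(
                bedtime=bed.time(),
                bedtime_sd_min=0.0,
                hr_sd=spec.hr_sd,
                sleep_duration_mean_min=430.0,
                sleep_duration_sd_min=25.0,
                awakening_rate=0.5 if disrupted else 0.10,
                awake_dwell_mean_min=6.0 if disrupted else 2.5,
            )
            night_seed = int(rng.integers(0, 2**31 - 1))
            truth = simulate_night(
                params, night_seed,
                night_id=f"{student.student_id}-{day.isoformat()}",
                day=bed.date() if bed.time() >= time(12, 0) else
                bed.date() - timedelta(days=1),
            )
            morning = truth.start.date() if truth.start.time() < time(12, 0) \
                else truth.start.date() + timedelta(days=1)
            wake_lo = datetime.combine(morning, persona["wake_lo"],
                                       tzinfo=truth.start.tzinfo)
            wake_hi = datetime.combine(morning, persona["wake_hi"],
                                       tzinfo=truth.start.tzinfo)
            truth = _clamp_end(truth, wake_lo, wake_hi, rng, params)

            counts = truth.per_state_minutes()
            duration = truth.n_minutes
            awake_min = counts[UnifiedState.AWAKE]
            true_rest = sq_true_label(duration, awake_min)
            quiz = QuizAnswer(
                student_id=student.student_id,
                date=day.isoformat(),
                rest_feeling=_noisy_quiz(true_rest, spec.quiz_noise_p, rng),
            )
            document = render_document(
                truth, dialect,
                seed=night_seed if dialect == "microsoft" else None,
            )
            student.nights.append(SimulatedNight(
                day=assign_day(truth.start, truth.end),
                truth=truth,
                dialect=dialect,
                document=document,
                wake_time=truth.end,
                quiz=quiz,
                true_rest=true_rest,
            ))
        students.append(student)

    window_seed = int(rng.integers(0, 2**31 - 1))
    sleepiness = simulate_state_windows("SLEEPINESS", 60, window_seed)
    stress = simulate_state_windows("STRESS", 60, window_seed + 1)
    return SimulatedCohort(spec, students, calendar, sleepiness, stress)
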