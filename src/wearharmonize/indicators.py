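"""The four learner indicators: chronotype, sleep quality, sleepiness, stress.

* **Chronotype** scores habitual bed and wake times on a morningness/
  eveningness axis: each is mapped to an integer in {-2..2} by the
  hour/score table (2 = extreme morning, -2 = definitively evening), a day's
  score is the mean of the two, and scores are averaged overall and per
  working/non-working day class.
* **Sleep quality (SQ)** is a PSQI-inspired 0-100 daily score predicted by a
  classifier trained on each user's own history: the label is the user's
  0-10 "rest feeling" quiz answer, the features are the night's summary
  statistics.  For the first 3 days the indicator abstains; after 30 days
  the quiz is no longer required and the score is fully automatic.
* **Sleepiness** and **stress** are ordinal levels (0..4) predicted from
  short (default 10-minute) real-time sensor windows: accelerometer, heart
  rate and skin temperature for sleepiness; HR, skin temperature and
  galvanic skin response for stress, with accelerometer activity standing in
  when GSR is unavailable.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from datetime import date, time
from statistics import fmean
from typing import Callable, Mapping, Sequence

from .classifiers import ClassifierKind, fit_classifier, predict
from .errors import ConsistencyError, ParameterError
from .harmonize import UnifiedSleepRecord
from .vendor_ingest import RealTimeSample

logger = logging.getLogger(__name__)

__all__ = [
    "ABSTAIN",
    "ChronotypeResult",
    "QuizAnswer",
    "FeatureVector",
    "IndicatorResult",
    "score_start_bedtime",
    "score_end_bedtime",
    "chronotype",
    "extract_sq_features",
    "sleep_quality",
    "extract_state_features",
    "SQ_WARMUP_DAYS",
    "SQ_TRAINING_DAYS",
]

#: Days 1..SQ_WARMUP_DAYS produce no sleep-quality value.
SQ_WARMUP_DAYS = 3
#: After this many days the quiz answer is no longer required.
SQ_TRAINING_DAYS = 30


class _Abstain:
    """Sentinel: the indicator declines to produce a value."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSTAIN"

    def __bool__(self) -> bool:
        return False


ABSTAIN = _Abstain()


# ---------------------------------------------------------------------------
# Chronotype
# ---------------------------------------------------------------------------

def _axis_minutes(t: time) -> float:
    """Minutes since 12:00 on the circadian axis (so 21:00 sorts before 01:00)."""
    minutes = t.hour * 60 + t.minute + t.second / 60
    return (minutes - 720) % 1440

# Hour/score table: half-open intervals [lower, upper) on the circadian
# axis; the open-ended first and last rows extend to the axis ends.
# Bedtime rows:  2: -/21:30   1: 21:30/22:45   0: 22:45/00:45
#               -1: 00:45/02:00   -2: 02:00/-
_START_BOUNDS = [_axis_minutes(time(21, 30)), _axis_minutes(time(22, 45)),
                 _axis_minutes(time(0, 45)), _axis_minutes(time(2, 0))]
# Wake rows:     2: -/05:00   1: 05:00/06:30   0: 06:30/08:30
#               -1: 08:30/10:00   -2: 10:00/-
_END_BOUNDS = [_axis_minutes(time(5, 0)), _axis_minutes(time(6, 30)),
               _axis_minutes(time(8, 30)), _axis_minutes(time(10, 0))]
_SCORES = (2, 1, 0, -1, -2)


def score_start_bedtime(t: time) -> int:
    """Score a bedtime on the morningness axis (2 early .. -2 late)."""
    return _SCORES[bisect_right(_START_BOUNDS, _axis_minutes(t))]


def score_end_bedtime(t: time) -> int:
    """Score a wake time on the morningness axis (2 early .. -2 late)."""
    return _SCORES[bisect_right(_END_BOUNDS, _axis_minutes(t))]


@dataclass(frozen=True)
class ChronotypeResult:
    """Aggregate chronotype scores; all values lie in [-2, 2]."""

    overall: float
    n_days: int
    working_days: float | None = None
    nonworking_days: float | None = None


def chronotype(
    records: Sequence[UnifiedSleepRecord],
    calendar: Callable[[date], bool] | Mapping[str, str] | None = None,
) -> ChronotypeResult | None:
    """Aggregate per-night bed/wake scores into a chronotype.

    Each record (main periods only) contributes the mean of its start-hour
    and end-hour scores; ``calendar`` classifies dates as working days
    (a predicate, or a mapping date-string -> "working"/"nonworking").
    Returns ``None`` for an empty record list.
    """
    if not records:
        return None

    if calendar is None:
        is_working = None
    elif callable(calendar):
        is_working = calendar
    else:
        mapping = calendar

        def is_working(day: date) -> bool:
            return mapping.get(day.isoformat(), "working") == "working"

    day_scores: list[float] = []
    working: list[float] = []
    nonworking: list[float] = []
    for record in records:
        start = time.fromisoformat(record.start_hour)
        end = time.fromisoformat(record.end_hour)
        score = (score_start_bedtime(start) + score_end_bedtime(end)) / 2
        day_scores.append(score)
        if is_working is not None:
            day = date.fromisoformat(record.date_string)
            (working if is_working(day) else nonworking).append(score)
    return ChronotypeResult(
        overall=fmean(day_scores),
        n_days=len(day_scores),
        working_days=fmean(working) if working else None,
        nonworking_days=fmean(nonworking) if nonworking else None,
    )


# ---------------------------------------------------------------------------
# Feature vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuizAnswer:
    """Daily sleep-feeling questionnaire answer (0 = awful .. 10 = great)."""

    student_id: str
    date: str
    rest_feeling: int

    def __post_init__(self) -> None:
        if not 0 <= self.rest_feeling <= 10:
            raise ParameterError(
                f"rest_feeling must lie in [0, 10], got {self.rest_feeling}"
            )

    def to_json(self) -> dict:
        return {
            "student_id": self.student_id,
            "date": self.date,
            "rest_feeling": self.rest_feeling,
        }


@dataclass(frozen=True)
class FeatureVector:
    """Named numeric features for one indicator; missing entries are -1."""

    kind: str  # "SQ", "SLEEPINESS" or "STRESS"
    features: Mapping[str, float]
    label: int | None = None
    substitutions: tuple[str, ...] = ()

    def with_label(self, label: int | None) -> "FeatureVector":
        return FeatureVector(self.kind, dict(self.features), label,
                             self.substitutions)


@dataclass(frozen=True)
class IndicatorResult:
    """An indicator value with its provenance."""

    kind: str
    student_id: str
    device: str
    date: str
    value: float | int | None

    def to_json(self) -> dict:
        return {
            "kind": self.kind,
            "student_id": self.student_id,
            "device": self.device,
            "date": self.date,
            "value": None if self.value is ABSTAIN else self.value,
        }


def extract_sq_features(
    record: UnifiedSleepRecord,
    quiz: QuizAnswer | None = None,
) -> FeatureVector:
    """Sleep-quality features of one night.

    Six features: sleep duration, sleep-onset latency and awake time in
    minutes, night HR minimum, mean skin temperature, and the quiz answer
    (-1 when absent).  The quiz answer, when present, also becomes the
    training label.
    """
    features = {
        "duration_min": float(record.total_time_data),
        "fall_asleep_min": float(record.time_to_sleep_data),
        "awake_min": float(record.awake),
        "hr_min": float(record.hr_min),
        "temp_mean": float(record.temp_mean),
        "quiz": float(quiz.rest_feeling) if quiz is not None else -1.0,
    }
    label = quiz.rest_feeling if quiz is not None else None
    return FeatureVector("SQ", features, label)


def sleep_quality(
    history: Sequence[FeatureVector],
    today: FeatureVector,
    model_kind: ClassifierKind = ClassifierKind.INSTANCE_BASED,
    seed: int = 0,
):
    """Predict today's sleep quality (0-100) from the user's history.

    The current day number is ``len(history) + 1``.  Days 1-3 abstain
    (nothing to learn from yet); afterwards a classifier trained on the
    labeled history predicts today's 0-10 rest feeling and SQ is ten times
    that, clamped to [0, 100].  Past day 30 the user need not answer the
    quiz any more; prediction proceeds identically (today's quiz feature is
    never used: it is reset to the -1 sentinel before predicting).
    """
    day = len(history) + 1
    if day <= SQ_WARMUP_DAYS:
        return ABSTAIN
    labeled = [fv for fv in history if fv.label is not None]
    if not labeled:
        logger.warning("sleep_quality: no labeled history on day %d", day)
        return ABSTAIN

    # The quiz answer is the label; as a *feature* it is withheld both at
    # fit and at predict time so the training rows look like the query
    # (whose answer is unknown or, past the training period, not collected).
    def _mask(fv: FeatureVector) -> FeatureVector:
        features = dict(fv.features)
        features["quiz"] = -1.0
        return FeatureVector(fv.kind, features, fv.label, fv.substitutions)

    model = fit_classifier([_mask(fv) for fv in labeled], model_kind, seed=seed)
    query = _mask(today)
    level = predict(model, query)
    return max(0, min(100, 10 * level))


# ---------------------------------------------------------------------------
# Real-time state features (sleepiness / stress)
# ---------------------------------------------------------------------------

def _valid(values: Sequence[float]) -> list[float]:
    return [v for v in values if v != -1]


def extract_state_features(
    window: Sequence[RealTimeSample],
    kind: str,
) -> FeatureVector:
    """Summarize a short sensor window (default use: 10 min) into features.

    Features: mean/min/max heart rate, mean skin temperature, accelerometer
    magnitude mean and variance.  For stress, mean galvanic skin resistance
    is added; when GSR is -1 throughout, the accelerometer activity level is
    substituted and the substitution is flagged.  Sentinel values are
    excluded from every statistic; an all-sentinel signal yields -1.
    """
    if not window:
        raise ParameterError("empty sensor window")
    kind = kind.upper()
    if kind not in ("SLEEPINESS", "STRESS"):
        raise ParameterError(f"kind must be SLEEPINESS or STRESS, got {kind!r}")
    devices = {s.device for s in window}
    if len(devices) > 1:
        raise ConsistencyError(f"window mixes devices: {sorted(devices)}")

    hr = _valid([s.hrValue for s in window])
    st = _valid([s.tempValue for s in window])
    accel = _valid([s.accelValue for s in window])
    features: dict[str, float] = {
        "hr_mean": fmean(hr) if hr else -1.0,
        "hr_min": min(hr) if hr else -1.0,
        "hr_max": max(hr) if hr else -1.0,
        "st_mean": fmean(st) if st else -1.0,
        "accel_mean": fmean(accel) if accel else -1.0,
    }
    if accel:
        mu = features["accel_mean"]
        features["accel_var"] = fmean([(a - mu) ** 2 for a in accel])
    else:
        features["accel_var"] = -1.0

    substitutions: tuple[str, ...] = ()
    if kind == "STRESS":
        gsr = _valid([s.resistence for s in window])
        if gsr:
            features["gsr_mean"] = fmean(gsr)
        else:
            # GSR unavailable: accelerometer activity level stands in
            features["gsr_mean"] = features["accel_mean"]
            substitutions = ("gsr_mean<-accel_mean",)
            logger.info("stress features: GSR absent, accelerometer substituted")
    return FeatureVector(kind, features, substitutions=substitutions)
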