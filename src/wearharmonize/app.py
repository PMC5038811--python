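"""Engineering shell: configuration, JSON-lines collection store, batch runs.

The store mirrors the analytic engine's database layout as flat append-only
JSON-lines files: raw vendor collections (``sleep_fitbit``,
``sleep_microsoft``, ``sleep_jawbone``), the homogenized ``sleep_analytics``
collection keyed by (student, device, date) with the newest record winning,
real-time ``band_sensors`` and questionnaire ``sleep_quiz``.  ``ingest``
feeds raw night envelopes through the homogenization pipeline into the
store idempotently; ``run_daily`` replaces the original morning scheduler
with an explicit batch command that recomputes the non-real-time
indicators.  Structured log lines carry operation names and counts only —
raw sensor values stay at debug level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .classifiers import ClassifierKind
from .errors import WearHarmonizeError
from .harmonize import CounterPolicy, UnifiedSleepRecord
from .indicators import (
    ABSTAIN,
    IndicatorResult,
    QuizAnswer,
    chronotype,
    extract_sq_features,
    sleep_quality,
)
from .pipeline import harmonize_document

logger = logging.getLogger(__name__)

__all__ = ["AppConfig", "CollectionStore", "ingest", "export", "run_daily"]

COLLECTIONS = (
    "sleep_fitbit",
    "sleep_microsoft",
    "sleep_jawbone",
    "sleep_analytics",
    "band_sensors",
    "sleep_quiz",
)


@dataclass
class AppConfig:
    """Deployment configuration.

    ``token_metadata`` (per-platform token lifetimes) is informational only:
    no network client consumes it here.
    """

    timezone: str = "UTC"
    counter_policies: dict[str, CounterPolicy] = field(
        default_factory=lambda: {
            "microsoft": CounterPolicy.SINCE_FOREVER,
            "androidwear": CounterPolicy.RESET_ON_REBOOT,
            "fitbit": CounterPolicy.DAILY_RESET,
        }
    )
    day_cutoff: time = time(12, 0)
    gap_split_min: int = 180
    classifier_kind: ClassifierKind = ClassifierKind.INSTANCE_BASED
    seed: int = 0
    calendar_path: str | None = None
    token_metadata: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "AppConfig":
        raw = json.loads(Path(path).read_text())
        kwargs: dict = {}
        if "timezone" in raw:
            kwargs["timezone"] = raw["timezone"]
        if "counter_policies" in raw:
            kwargs["counter_policies"] = {
                device: CounterPolicy(policy)
                for device, policy in raw["counter_policies"].items()
            }
        if "day_cutoff" in raw:
            kwargs["day_cutoff"] = time.fromisoformat(raw["day_cutoff"])
        if "gap_split_min" in raw:
            kwargs["gap_split_min"] = int(raw["gap_split_min"])
        if "classifier_kind" in raw:
            kwargs["classifier_kind"] = ClassifierKind(raw["classifier_kind"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "calendar_path" in raw:
            kwargs["calendar_path"] = raw["calendar_path"]
        if "token_metadata" in raw:
            kwargs["token_metadata"] = dict(raw["token_metadata"])
        return cls(**kwargs)

    def load_calendar(self) -> dict[str, str] | None:
        if self.calendar_path is None:
            return None
        return json.loads(Path(self.calendar_path).read_text())


class CollectionStore:
    """Append-only JSON-lines collections under one root directory."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, collection: str) -> Path:
        if collection not in COLLECTIONS:
            raise WearHarmonizeError(f"unknown collection {collection!r}")
        return self.root / f"{collection}.jsonl"

    def read(self, collection: str) -> list[dict]:
        path = self._path(collection)
        if not path.exists():
            return []
        with open(path) as handle:
            return [json.loads(line) for line in handle if line.strip()]

    def append(self, collection: str, record: Mapping) -> bool:
        """Append a record unless an identical one is already stored."""
        canonical = json.dumps(record, sort_keys=True)
        for existing in self.read(collection):
            if json.dumps(existing, sort_keys=True) == canonical:
                return False
        with open(self._path(collection), "a") as handle:
            handle.write(json.dumps(record) + "\n")
        return True

    def size(self, collection: str) -> int:
        return len(self.read(collection))

    def analytics(self) -> list[dict]:
        """sleep_analytics with newest-wins resolution per (student, device,
        date), chronological."""
        latest: dict[tuple, dict] = {}
        for record in self.read("sleep_analytics"):
            key = (record.get("student_id"), record.get("device"),
                   record.get("date_string"))
            latest[key] = record
        return sorted(latest.values(), key=lambda r: (
            str(r.get("student_id")), str(r.get("date_string"))))


_RAW_COLLECTION = {
    "microsoft": "sleep_microsoft",
    "fitbit": "sleep_fitbit",
    "jawbone": "sleep_jawbone",
}


def _iter_envelopes(path: Path) -> Iterator[dict]:
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.count("\n") == 0:
        payload = json.loads(text)
        yield from (payload if isinstance(payload, list) else [payload])
    else:
        for line in text.splitlines():
            if line.strip():
                yield json.loads(line)


def ingest(
    files: Iterable[str | Path],
    dialect: str | None,
    config: AppConfig,
    store: CollectionStore,
) -> dict[str, int]:
    """Ingest night envelopes: raw record + homogenized night per envelope.

    Each envelope is a JSON object with ``student_id``, ``device``,
    ``date`` (YYYY-MM-DD), the vendor ``payload``, optionally ``dialect``
    (overriding the argument), ``wake_time`` (Jawbone) and per-minute
    ``hr``/``temp`` series.  Parse failures are logged and skipped; the
    returned counts report stored and failed envelopes.
    """
    counts = {c: 0 for c in COLLECTIONS}
    counts["failed"] = 0
    total = 0
    for path in map(Path, files):
        for envelope in _iter_envelopes(path):
            total += 1
            try:
                night_dialect = envelope.get("dialect", dialect)
                if night_dialect not in _RAW_COLLECTION:
                    raise WearHarmonizeError(
                        f"unknown dialect {night_dialect!r}"
                    )
                # Fitbit clock times anchor on the calendar date of the
                # first sample, which for an after-midnight bedtime is not
                # the night's assigned day.
                anchor = envelope.get("start_date") or envelope.get("date")
                day = date.fromisoformat(anchor) if anchor else None
                wake = (
                    datetime.fromisoformat(envelope["wake_time"])
                    if "wake_time" in envelope
                    else None
                )
                records = harmonize_document(
                    json.dumps(envelope["payload"]),
                    night_dialect,
                    student_id=envelope["student_id"],
                    device=envelope["device"],
                    day=day,
                    wake_time=wake,
                    hr_series=envelope.get("hr"),
                    temp_series=envelope.get("temp"),
                    timezone_name=config.timezone,
                    gap_fill_max=timedelta(minutes=config.gap_split_min),
                    cutoff=config.day_cutoff,
                )
            except (WearHarmonizeError, KeyError, ValueError) as exc:
                logger.error("ingest: envelope %d of %s failed: %s",
                             total, path.name, exc)
                counts["failed"] += 1
                continue
            raw_collection = _RAW_COLLECTION[night_dialect]
            if store.append(raw_collection, envelope):
                counts[raw_collection] += 1
            for record in records:
                # the analytics collection is keyed per (student, device,
                # date): only the day's main period lives there
                if "-nap" in record.identity.record_id:
                    continue
                if store.append("sleep_analytics", record.to_json()):
                    counts["sleep_analytics"] += 1
            if "quiz" in envelope:
                quiz_record = {
                    "student_id": envelope["student_id"],
                    "date": envelope["date"],
                    "rest_feeling": envelope["quiz"],
                }
                if store.append("sleep_quiz", quiz_record):
                    counts["sleep_quiz"] += 1
    logger.info(
        "ingest: op=ingest dialect=%s envelopes=%d failed=%d stored=%s",
        dialect, total, counts["failed"],
        {k: v for k, v in counts.items() if v and k != "failed"},
    )
    if total and counts["failed"] == total:
        raise WearHarmonizeError("all envelopes failed to ingest")
    return counts


def export(
    store: CollectionStore,
    collection: str,
    *,
    student_id: str | None = None,
    date_from: str | None = None,
    date_to: str | None = None,
) -> list[dict]:
    """Export matching records of a collection, chronological."""
    records = (
        store.analytics()
        if collection == "sleep_analytics"
        else store.read(collection)
    )

    def _date_of(record: dict) -> str:
        return str(record.get("date_string") or record.get("date") or "")

    out = []
    for record in records:
        if student_id is not None and record.get("student_id") != student_id:
            continue
        when = _date_of(record)
        if date_from is not None and when < date_from:
            continue
        if date_to is not None and when > date_to:
            continue
        out.append(record)
    out.sort(key=_date_of)
    logger.info("export: op=export collection=%s matched=%d", collection, len(out))
    return out


def run_daily(
    store: CollectionStore,
    config: AppConfig,
    calendar: Mapping[str, str] | None = None,
) -> list[IndicatorResult]:
    """Recompute the non-real-time indicators from the store.

    For every student: the chronotype over all main-period nights, and the
    sleep-quality score for the latest night given the preceding labeled
    history.  This is the batch replacement for the original scheduled
    morning run.
    """
    if calendar is None:
        calendar = config.load_calendar()
    quiz_by_key = {
        (q["student_id"], q["date"]): QuizAnswer(
            q["student_id"], q["date"], int(q["rest_feeling"])
        )
        for q in store.read("sleep_quiz")
    }
    by_student: dict[str, list[UnifiedSleepRecord]] = {}
    for doc in store.analytics():
        record = UnifiedSleepRecord.from_json(doc)
        if "-nap" in record.identity.record_id:
            continue
        by_student.setdefault(record.identity.student_id, []).append(record)

    results: list[IndicatorResult] = []
    for student, records in sorted(by_student.items()):
        records.sort(key=lambda r: r.date_string)
        chrono = chronotype(records, calendar)
        device = records[-1].identity.device
        if chrono is not None:
            results.append(IndicatorResult(
                "CHRONOTYPE", student, device, records[-1].date_string,
                round(chrono.overall, 3),
            ))
        features = [
            extract_sq_features(
                r, quiz_by_key.get((student, r.date_string))
            )
            for r in records
        ]
        sq = sleep_quality(
            features[:-1], features[-1],
            model_kind=config.classifier_kind, seed=config.seed,
        )
        results.append(IndicatorResult(
            "SQ", student, device, records[-1].date_string,
            None if sq is ABSTAIN else sq,
        ))
    logger.info("run_daily: op=run_daily students=%d results=%d",
                len(by_student), len(results))
    return results
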