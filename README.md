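# wearharmonize

Consumer wearables report sleep in incompatible ways: one vendor emits
explicit sleep *segments* with start/end timestamps and a depth label,
another tags every minute of the night with a numeric state code and no
calendar date, a third records only depth-change *events* and never says
when the last one ended.  They also disagree on vocabularies (doze/snooze
vs. awake/really-awake vs. awake/light/deep), on which calendar day a night
that crosses midnight belongs to, and on when cumulative counters such as
steps reset (never, on reboot, or daily).  Anyone who wants to analyze
sleep across a mixed-device cohort — here, students wearing whatever
tracker they own, feeding learning-analytics indicators — has to
homogenize all of this first.

`wearharmonize` is that pipeline as a Python library and CLI:

* **parsers** for the three sleep-record dialects (segment-based,
  minute-by-minute, event-based) and for real-time multi-sensor samples in
  which a missing sensor carries the sentinel `-1`;
* a **harmonizer** that maps every vendor vocabulary onto the unified
  three-state model `awake` / `light` / `relaxed` (deep), run-length- or
  event-pairs the minutes/events into segments, assigns each sleep period
  to a calendar day (noon cutoff: a night started after midnight belongs to
  the previous day), labels the longest period of a day as the main sleep
  and the rest as naps, and emits one unified per-night record — summary
  statistics plus per-minute one-hot state lists, timestamps and heart
  rate;
* **counter reconciliation** turning cumulative step/calorie readings into
  daily totals under each vendor's reset policy;
* four **indicators**: chronotype (a morningness score in [-2, 2] from the
  bed/wake hour-score table), sleep quality (a PSQI-inspired 0-100 score
  predicted per-user by a classifier trained on the daily "rest feeling"
  quiz), and sleepiness/stress levels classified from short real-time
  sensor windows (with accelerometer activity standing in when galvanic
  skin response is unavailable);
* a **synthetic simulator** that generates ground-truth nights (semi-Markov
  awake/light/deep alternation with per-state heart rate), renders them
  into every vendor dialect, and builds labeled cohorts — so the whole
  pipeline is testable end to end without any device data;
* a flat JSON-lines **collection store** (`sleep_fitbit`,
  `sleep_microsoft`, `sleep_jawbone`, `sleep_analytics`, `band_sensors`,
  `sleep_quiz`) with idempotent ingest and filtered export.

## The core model

A night is a sequence of maximal single-state segments.  The unified
record conserves, by construction,

```
awake + light + relaxed = total_time_data        (minutes)
elapsed(start_hour -> end_hour) = total_time
```

with exactly one state per minute (one-hot lists).  Sleep-onset latency
(`time_to_sleep`) is the span from period start to the first non-awake
minute, truncated to whole minutes in `time_to_sleep_data`; `num_awake`
counts awakenings strictly after sleep onset (the final wake is not an
awakening); `sleep_efficiency = round(100 * (light + relaxed) /
total_time_data)`.

The chronotype scoring table (half-open intervals on a circadian axis
anchored at noon):

| score | bedtime        | wake time      |
|------:|----------------|----------------|
|  2    | before 21:30   | before 05:00   |
|  1    | 21:30 – 22:45  | 05:00 – 06:30  |
|  0    | 22:45 – 00:45  | 06:30 – 08:30  |
| -1    | 00:45 – 02:00  | 08:30 – 10:00  |
| -2    | 02:00 onward   | 10:00 onward   |

A day scores the mean of its two entries; days average into the overall
score and into working/non-working-day groups.

## Worked example

Simulate a night, render it in the minute-by-minute dialect, harmonize it
back, and score it:

```python
import json
from wearharmonize.synthetic import NightParams, simulate_night, render_fitbit
from wearharmonize.pipeline import harmonize_document
from wearharmonize.indicators import chronotype

truth = simulate_night(NightParams(), seed=42)
document = render_fitbit(truth)          # [{"dateTime": "23:42:00", "value": "3"}, ...]
(record,) = harmonize_document(
    document, "fitbit", student_id="student-01", device="Fitbit_Api",
    day=truth.start.date(), hr_series=truth.hr_trace,
    temp_series=truth.temp_trace,
)
print(json.dumps(record.to_json()["data"], indent=2))
print("chronotype overall:", chronotype([record]).overall)
```

prints

```
{
  "total_time_data": 431,
  "time_to_sleep_data": 23,
  "temp_mean": 34.67,
  "hr_min": 48,
  "num_awake": 5,
  "awake": 42,
  "light": 389,
  "relaxed": 0,
  "sleep_efficiency": 90,
  "efficiency_proposal": 90,
  "start_hour": "23:42:00",
  "end_hour": "06:53:00",
  "total_time": "07:11:00",
  "time_to_sleep": "00:23:00"
}
chronotype overall: 0.0
```

The 431-minute night went to bed at 23:42 (day score 0: between 22:45 and
00:45) and woke at 06:53 (score 0), spent 23 minutes falling asleep and
42 minutes awake in total across 5 awakenings.  All sleep surfaces as
`light` because this dialect carries no depth information.  The same truth
rendered through the segment- or event-based dialects recovers the full
light/relaxed split — that round trip is one of the package's core tests.

The same flows are available from the shell:

```sh
wearharmonize simulate cohort --seed 1 --out data/
wearharmonize ingest data/nights.jsonl --store store/
wearharmonize export sleep_analytics --store store/ --student student-00
wearharmonize run-daily --store store/ --calendar data/calendar.json
```

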