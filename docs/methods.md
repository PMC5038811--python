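# Methods

## The unified sleep model

All vendor dialects are reduced to one vocabulary of three states —
`AWAKE`, `LIGHT`, `RELAXED` (deep/restful sleep) — and one per-night record
shape: a summary block (total minutes, onset latency, per-state minute
totals, awakenings, efficiency, heart-rate minimum, mean skin temperature,
start/end clock times) plus per-minute lists (one-hot state sequences,
epoch-millisecond timestamps stored as strings, heart rate).  Two
conservation laws are asserted on every record construction: the per-state
minute totals sum to `total_time_data`, and the elapsed time from
`start_hour` to `end_hour` (mod 24 h) equals `total_time`.

### State mapping

| vendor state | unified |
|---|---|
| segment dialect: Awake, Doze, Snooze, Unknown | AWAKE |
| segment dialect: RestlessSleep | LIGHT |
| segment dialect: RestfulSleep | RELAXED |
| minute dialect: 1 (asleep) | LIGHT |
| minute dialect: 2 (awake), 3 (really awake) | AWAKE |
| event dialect: 1 (awake) | AWAKE |
| event dialect: 2 (light) | LIGHT |
| event dialect: 3 (deep) | RELAXED |
| Google-Fit style: light / deep / awake / REM | LIGHT / RELAXED / AWAKE / RELAXED |

The minute dialect has no depth information, so its sleep state maps to
the lighter class, and its two awake flavours (distinguished only by
movement intensity) merge into `AWAKE`.  The Google-Fit REM assignment is
a configurable override (`map_state(..., overrides=...)`).

### Segmentation conventions

* Minute records are run-length encoded; each record covers one whole
  minute starting at its clock time.  Clock times carry no date; the
  caller supplies the anchoring calendar date, and one backwards jump is
  interpreted as wrapping past midnight.
* Depth events pair up: event *i* opens a segment that event *i+1*
  closes; the dialect never records the final end, so the caller supplies
  the wake time.  Zero-length segments are dropped.
* Vendor segments keep their timestamps.  A gap between consecutive
  segments up to the split threshold (default 180 min) is filled as
  `AWAKE`; a longer gap splits the night into separate periods.
* Per-minute expansion samples the state at each minute's **midpoint**;
  the minute count is the whole-minute truncation of the period span.
  Minute-aligned inputs reproduce their per-state totals exactly; inputs
  with sub-minute timestamps are recovered to within one minute per
  segment boundary.

### Day assignment and naps

A sleep period belongs to the evening on which it began: starts at or
after the local noon cutoff keep their calendar day, starts before noon
belong to the previous day.  This keeps a night that begins at 01:26
attached to the previous evening while an afternoon nap stays on its own
day.  Among the periods of one day, the longest is the main sleep (ties:
earliest start); the rest are naps.  `sleep_efficiency` is computed over
all of the day's periods, `efficiency_proposal` over the main period only;
with no naps the two coincide.  The worked record this model was shaped
on prints efficiency values (80/70) whose defining formulas are not
documented anywhere we could find; the documented ratio
`round(100 * sleep / total)` gives 78 for that record, and no attempt is
made to reproduce the undocumented numbers.

### Counters

Daily totals from cumulative counters depend on the device's reset
policy:

* *never resets*: `last - first`;
* *daily reset*: the last reading;
* *reset on reboot*: the sum of inter-sample increments where a drop in
  value signals a reboot and the reading right after a drop counts in
  full (it accrued from zero) — equivalently `(last - first) + sum(values
  immediately before each drop)`.  Reboots whose post-reboot reading
  exceeds the previous one are undetectable in principle; the
  reconciliation is exact whenever resets coincide with sampling
  instants, which is what the oracle tests construct.

### Numeric conventions

Rounding is half-up: mean skin temperature to 2 decimals, efficiency to
the nearest integer.  `time_to_sleep_data` truncates (floors) the latency
to whole minutes.  Missing sensor summaries are `-1`.  Per-minute time
entries are epoch-millisecond strings (the record's own date field is
epoch milliseconds; the worked example's printed time strings match no
standard encoding, so this is a convention, not a recovery).  Rendered
segment timestamps are quantized to milliseconds before serialization so
that declared durations equal `end - start` exactly.

## Indicators

**Chronotype.** Bed and wake times are scored in {-2..2} by the hour/score
table with half-open `[lower, upper)` intervals on a circadian axis
anchored at 12:00 (so bedtimes order 21:30 < 00:45 < 02:00); the
open-ended first and last rows extend to the axis ends.  A day's score is
the mean of its two entries; the aggregate (overall and per working /
non-working class) is the arithmetic mean of day scores.  The day-level
mean and the arithmetic aggregation are conventions of this package — the
source tradition assigns the per-measure scores but leaves aggregation
unstated.

**Sleep quality.** The 0-10 daily "rest feeling" quiz answer is the
training label; the features are the night's summary statistics (duration,
onset latency, awake minutes, HR minimum, mean skin temperature, quiz).
SQ = 10 × the predicted answer, clamped to [0, 100].  Days 1-3 abstain;
from day 4 a per-user classifier predicts; past day 30 the quiz is no
longer required.  Because the quiz answer *is* the label, it is masked to
`-1` as a feature at both fit and predict time: training rows must look
like the query, whose answer is unknown (or no longer collected).  Leaving
it in makes a decision tree split on the label itself and routes every
masked query into the lowest-label branch.

**Sleepiness / stress.** Short sensor windows (default 10 min, one device)
summarize to mean/min/max heart rate, mean skin temperature, accelerometer
magnitude mean and variance; stress adds mean galvanic skin resistance,
substituting the accelerometer activity level (and flagging the
substitution) when GSR is absent throughout the window.  Sentinel values
are excluded from every statistic.  Levels are small ordinals {0..4}; the
granularity is a convention.

### Classifiers

Two in-repo classifiers sit behind one fit/predict interface so a library
implementation can be swapped in:

* a **gain-ratio decision tree** (C4.5 family): numeric axis-aligned
  splits at midpoints of sorted observed values, chosen by maximal
  information-gain ratio; growth stops at pure nodes or the minimum leaf
  size (2); leaves take the majority label.  No pruning and no dedicated
  missing-value machinery — `-1` sentinels are ordinary numbers.
* a **distance-weighted k-nearest-neighbour** classifier (k = 3,
  inverse-distance weights, features standardized by training mean/sd; a
  constant feature keeps unit scale) standing in for entropic
  instance-based learners.  An exact feature match decides outright.

Both are deterministic given rows and seed: split ties go to the first
feature and smallest threshold, vote and leaf ties to the smallest label.

## The synthetic generator

`simulate_night` draws a semi-Markov timeline: an in-bed onset latency
(`AWAKE`), then alternating `LIGHT`/`RELAXED` dwells until a drawn sleep
budget is spent, with an interior awakening inserted after a sleep dwell
with fixed probability.  Dwells are geometric in whole minutes
(exponential-like, mean = the nominal parameter).  Defaults: bedtime
23:30 ± 40 min, latency 10 min, light/deep dwell means 20/15 min,
awakening rate 0.15 with 3-min awakenings, sleep budget 420 ± 30 min.
Heart rate is sampled per minute around per-state means ordered
relaxed (52) < light (60) < awake (70) bpm, sd 2; skin temperature is a
per-night level around 34.5 °C with small minute noise; accelerometer
magnitude follows the same per-state structure.  Every generator output
is a pure function of (parameters, seed); one seeded generator drives each
call.

Renderers invert the parsers: the segment dialect gets vendor vocabulary,
ISO timestamps, ISO-8601 durations and per-segment HR summaries, with an
optional sub-minute phase offset plus bounded interior-boundary jitter to
exercise the rounding path; the minute dialect renders sleep as code 1 and
awake segments as code 3 when they last ≥ 3 min (movement duration being
the simulable proxy for movement violence), else 2; the event dialect
emits one depth event per state change and withholds the final end time,
as that dialect requires.

`simulate_cohort` builds labeled multi-student datasets.  Personas pin the
bed/wake windows: *morning* (bed 20:30-21:10, wake 04:00-04:55), *evening*
(bed 02:30-03:30, wake 10:05-11:30), *intermediate* (bed 23:00-00:30, wake
06:45-08:15); the night's end is clamped into the persona's wake window by
trimming or extending the final sleep segment.  Students cycle through the
three dialects.  Nights are a calm/disrupted mixture (disrupted with
probability 0.15: awakening rate 0.5 and 6-min awakenings vs. 0.10 and
2.5 min), which makes total awake time bimodal.  The injected rest-feeling
label is a stated monotone function of duration and awake time (the
observable footprint of awakenings): 8 for ≥ 6.5 h, 6 for ≥ 5.5 h, 4
below, minus 1 for ≥ 45 awake minutes; the recorded quiz answer shifts it
by ±1 with probability 0.05.  Sleepiness windows place the five levels on
descending heart-rate means (73…52 bpm) and label by thresholds on the
realized window mean; stress windows do the same on galvanic skin
resistance (420…260, lower = more stressed) with accelerometer-activity
thresholds taking over when GSR is unavailable.  Sensor dropout replaces
readings with `-1` at probability 0.05 (counters and the worn flag are
exempt).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no circadian physiology beyond the persona
windows, no REM structure, no correlated sensor noise or drift, no
device-specific preprocessing (vendor smoothing, summarization under
memory pressure), no missing *nights*, and label functions far cleaner
than human self-reports.  Passing recovery tests demonstrate that the
pipeline is lossless and the learners consistent, not that the indicators
are clinically valid.

## Recovery protocol

The sleep-quality system trains over a 30-day period, after which
prediction is automatic; recovery is therefore measured with the model
fitted on the full 30-day labeled history and scored against the
noise-free generating labels on the post-warm-up days (held-in agreement,
threshold 0.90).  The warm-up rule (abstain on days 1-3, predict from day
4) and the post-30-day no-quiz operation are asserted separately,
day-by-day.  Sleepiness/stress train on 30 windows and are scored on 30
held-out windows.  The acceptance run uses the instance-based learner for
sleep quality and the decision tree for sleepiness/stress, mirroring the
learners each indicator was originally built on.

## Problem sizes

The test suite checks the unified-record conservation laws on 1,000
generated nights, the scoring table's boundedness on 10,000 random times,
each segmentation/counter oracle on 1,000 random instances, vendor round
trips on 200 nights per dialect, and indicator recovery on a 4-student ×
30-night cohort plus 60 windows per state indicator.  The full suite runs
in well under a minute on one CPU.

## Known limitations

* The event dialect cannot express the final wake time; harmonization
  needs it from the envelope, and a wrong wake time silently stretches the
  last segment.
* Reboot-reset counters are reconciled exactly only when resets are
  detectable as drops; a reboot immediately followed by more events than
  the previous reading is indistinguishable from normal counting.
* The minute dialect collapses sleep depth; records harmonized from it
  have `relaxed = 0` by construction.
* Overlapping segments (one vendor's documented habit) are rejected, not
  resolved.
* The classifiers are deliberately small: no C4.5 pruning, no entropic
  instance-distance; they implement the documented contracts, not the
  original library implementations.
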