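# Methods

This note records the models, conventions and numerical choices behind
obskit, and what the synthetic fixtures do and do not establish about
real observational data.

## Session timing model

A session has two clocks. *Wall time* is real elapsed seconds; the
*session clock* starts at 0 when `ESC` is pressed and freezes during
pauses. All event times are session seconds, so an episode spanning a
pause automatically excludes the paused span. The recorder maintains the
identity

```
wall span of session = session duration + total pause seconds
```

exactly, because the final duration is computed as that difference; the
acceptance script measures the worst-case residual over random paused
streams (it is 0 up to floating-point subtraction).

With a session cap, the session ends the instant the clock reaches the
cap — *before* the token that revealed the crossing takes effect — and
any episode still open is closed at the cap. The cap-crossing wall time
is reconstructed by shifting the cap through the recorded pauses, so the
conservation identity holds in the capped case too.

Decisions where the behavior was genuinely open:

* **Keys during a pause are ignored, not queued.** The session clock is
  stopped, so there is no session time to attach them to.
* **An open duration episode stays open across a pause.** Freezing the
  clock already removes paused time from its span.
* **Undo targets commit order** (most recently committed event), not the
  latest timestamp, and the redo stack clears on any new commit —
  ordinary editor semantics.
* **Interval-timer marks** are derived data (`interval_marks`), every
  positive multiple of the interval up to the session duration; the
  headless core produces no audio.

## Session files and naming

Session records serialize to a single UTF-8 JSON document with a fixed
field order and a `format_version` field for forward compatibility. The
schema snapshot is embedded so a session file needs nothing else on disk
to be processed. Event times are stored as full-precision reals;
truncation to whole seconds is a display concern, not a storage one.

File names follow
`{number} {assessment[:2]} {condition[:2]}{date}{_R?}`. The date renders
as two-digit zero-padded day + unpadded month + four-digit year
(5 March 2023 → `0532023`). A `DDMYYYY` layout is ambiguous for
October–December; fixing the day at two digits makes the month the only
variable-width field, so the parser disambiguates by total digit count
(7 or 8). Session numbers that parse as integers participate in the
duplicate-check that promotes a repeat number to a reliability session;
any other string bypasses the check.

## KSF workbooks

The key-binding sheet is named `Keys` with header-matched columns
`Key | Behavior | Type` and a `Conditions` sheet with one label per row —
a minimal encoding of the published template's content; the loader
tolerates column reordering. Keys are case-sensitive (keystroke capture
distinguishes case) and the four control keys can never be bound.
Regenerating a revision writes *only* those two sheets — user formulas,
charts and extra sheets are deliberately dropped — into
`<name>_rev<k>.xlsx` with `k` strictly increasing within the directory.

## Agreement coefficients

The coefficient trio (total-count, exact count-per-interval,
block-by-block) is the standard behavior-analytic set; all three are
reported per key rather than privileging one. Conventions:

* Windows are half-open `[kw, (k+1)w)`; an event at exactly `kw` belongs
  to window `k`, and an event at exactly the session end is kept in the
  final partial window rather than dropped.
* `0/0 → 100 %`, documented prominently because it inflates agreement
  for rare behaviors.
* Duration keys get total and block-by-block coefficients over overlap
  seconds; exact equality of continuous overlap is not a meaningful
  statistic, so no exact coefficient is reported for them.
* Observer pairs with different window counts are padded with zero
  windows (with a warning); pairs with different durations are windowed
  over the longer duration. Schema mismatches are errors that name the
  offending keys.

All coefficients are symmetric in the two observers, and the
block-by-block coefficient is 100 iff every window agrees exactly. The
vectorized implementation is checked against a naive per-window loop on
hundreds of random small session pairs.

## Physiological features

Channels are fixed-rate series; sample *i* of a channel lies at wall
time `start + i/rate`. Alignment crops each channel to the session's
half-open wall window (pauses included in the span but carried as
annotations). Fixture sampling rates follow wrist-device convention —
EDA 4 Hz, BVP 64 Hz, ACC 32 Hz, TEMP 4 Hz — but are always read from the
recording, never assumed.

* **EDA**: mean/sd/min/max/median, least-squares slope (µS/s), and a
  skin-conductance-response count: local maxima of a 0.5 s moving-average
  smoothed series with prominence above 0.01 µS. Both the smoothing
  window and threshold are configurable; the defaults are conventions,
  not measured constants.
* **BVP/PPG**: pulse peaks via prominence-based detection (prominence
  0.3 × the series range) with minimum separation of one beat period at
  a maximum heart rate of 180 bpm (configurable). Heart rate is 60 over
  the mean inter-beat interval; IBI mean/sd and RMSSD accompany it.
  Fewer than two detected beats is an error, not a silent zero.
* **ACC3/TEMP** receive generic statistics only (ACC3 on the vector
  magnitude).

`sd` uses the n−1 denominator and is reported as 0 for single-sample
series; `slope` is absent below two samples.

## Synthetic fixtures and what they show

Generators are pure functions of their arguments including the seed.

* Keypress logs draw per-key times from homogeneous Poisson processes,
  so expected counts are known (`rate × duration`) and calibration is
  testable by replication.
* The BVP fixture is a train of narrow Gaussian pulses (σ = 5 % of the
  beat period) plus Gaussian noise (SD 0.02 of unit amplitude); the EDA
  fixture is a 0.5 µS baseline plus an SCR-shaped bump per onset — 1 s
  linear rise to 0.2 µS, exponential decay with a 4 s time constant — and
  noise of SD 0.001 µS. These shapes make detection falsifiable; they are
  fixture conventions, not physiological claims.
* The observer-error model drops each base event independently with
  probability `drop_prob`, jitters surviving times by clamped Gaussian
  noise, and inserts spurious frequency events at `add_rate` per second.
  Under pure drops the total-count coefficient has a closed binomial
  structure, which an independent Monte-Carlo simulation reproduces.

Passing tests on these fixtures establish the arithmetic and the
contracts — clock accounting, round trips, coefficient definitions,
peak-detection recovery under clean, well-separated signals. They do not
establish performance on real recordings: real EDA drifts and overlaps
responses, real PPG has motion artifacts well above the fixture noise
(heart-rate recovery degrades gracefully with noise but is only asserted
on clean pulses), and real observer disagreement is not independent per
event.

## Problem sizes

The default study conditions used by the tests and the acceptance
script: 200 random sessions for the JSON round trip; 50 random paused
streams for clock conservation; 500 random small session pairs
(≈ 60 s, ≤ 20 events, 6 windows) for the coefficient oracle; heart-rate
recovery at 48–150 bpm over 60 s of 64 Hz signal; 1–5 SCRs spaced 15 s;
and 500 replicates of the 40-event, 50 %-drop Monte-Carlo comparison.
These sizes give stable statistics (3-standard-error bands) while the
whole suite runs in seconds.
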