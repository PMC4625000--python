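# Methods

This note records the conventions, models and numerical choices behind
`screenuse`, in the order the pipeline applies them.

## Event model and time handling

An event is one screen-state transition: participant id, timestamp,
state ∈ {ON, OFF}. Timestamps may arrive as epoch seconds, epoch
milliseconds (auto-detected by magnitude, threshold 1e11 — configurable
through `Dialect.epoch_ms_threshold`) or ISO-8601 strings; state tokens
`true/false`, `1/0`, `on/off` (case-insensitive) are accepted and
extensible per dialect. All instants are converted to wall-clock time in
one configured zone (default UTC) and stored timezone-naive; every
day/window computation afterwards is pure clock arithmetic. On a DST
transition day the wall clock covers 23 or 25 hours; sessions are not
re-split or re-weighted for this, and the affected day simply has a
shorter or longer span. Parsing is conservative: malformed rows are
counted and logged, never silently dropped, and `valid + malformed =
total` is an invariant the tests enforce. Duplicate consecutive
identical states are retained at parse time — resolving them is the
sessionizer's job, which keeps parsing lossless.

## Sessionization

Events are processed per participant in ascending time order (stable
sort, ON before OFF at equal instants):

* ON followed by OFF → clean session `[on, off)`;
* ON followed by ON → the first session is closed at the second ON and
  flagged `MALFORMED_PAIRING` (its true end was unobserved);
* final ON with no OFF → closed at the observation end (default: the
  participant's last event) and flagged `UNTERMINATED`;
* orphan OFF → discarded with a counter (no interaction start is
  attested, and imputing one would fabricate data).

Under these rules every ON opens exactly one session, so session count
equals ON count — a property test. The pairing is checked against an
independent stack-based oracle on randomly corrupted streams.

**Power-off artifacts.** Sessions strictly longer than 18 000 s (5 h)
are flagged `SUSPECTED_POWER_OFF`; those whose interval intersects any
night window additionally get `OVERNIGHT_POWER_OFF`. The inequality
directions are deliberate: checks are "up to 15 s" (≤ 15.0 inclusive),
artifacts "more than 5 hours" (strictly > 18 000 s). Flagged sessions
are retained in every analysis; `include_power_off=False` exists on the
metric functions purely as a sensitivity switch.

**Day and window assignment.** The day is partitioned into night
[00:00, 06:00), morning [06:00, 12:00), afternoon [12:00, 18:00) and
evening [18:00, 24:00). Intervals are half-open, so 06:00:00.0 is
morning; the partition property (no gaps, no overlaps) is validated on
construction. A session belongs wholly to the calendar day and window
containing its *start* — the origin rule. It is stated for windows in
the source analyses; we apply it to days as well for internal
consistency, so sessions are never split at midnight either.

## Metrics

Daily summaries cover each participant's first 14 *observed* calendar
dates (enrolment times of day vary, so "first 14 days" is defined by
dates with any data; the horizon is configurable). Calendar gaps inside
that span yield rows with `n_uses = 0` and an undefined median
(`median_defined = False`): an empty day contributes 0 to mean daily
uses but is excluded from the mean of daily medians, since a median of
nothing is undefined. Participant summaries are arithmetic means of
daily values — in particular the "mean use length" is a mean of daily
medians, the robustness rationale above. Daily totals are reported in
hours at the participant level.

Checks (duration ≤ 15 s) are histogrammed in half-open 0.5 s bins with
the top edge of the last bin inclusive, so a 15.0 s use is counted.
The duration-category table uses half-open bands with default edges
15 s / 30 s / 60 s / 5 min / 30 min; only the under-30 s aggregate is
anchored to external findings, the finer edges are presentation
defaults.

## Comparison statistics

* Paired t: t = d̄/(s_d/√n), df = n − 1, two-sided p. Zero-variance
  differences are reported as t = 0 (p = 1) when d̄ = 0 and as signed
  infinity (p = 0) otherwise, never NaN.
* Pearson r with df = n − 2 and p from t = r√(df/(1 − r²)).
* One-way repeated-measures ANOVA by definitional sums of squares
  (subject, condition, error); F = MS_cond/MS_err, partial η² =
  SS_cond/(SS_cond + SS_err). No sphericity correction is applied —
  a documented limitation; p-values for the 4-level factor should be
  read accordingly. Follow-ups are Fisher's LSD: uncorrected pairwise
  paired t-tests (what "LSD" denotes, despite the occasional
  "Tukey's LSD" label in the applied literature).
* Standardized Cronbach's alpha k·r̄/(1 + (k−1)·r̄) with r̄ the mean
  pairwise inter-item correlation; zero-variance items are an error.
* The comparison matrix uses pairwise-complete deletion per cell, so
  n and df can differ between cells and are always reported; cells
  with < 3 complete pairs are reported unavailable, not fabricated.
  All p-values are two-sided and uncorrected for multiplicity; any
  correction is left to the user.
* MPPUS problem-use flags require the normative mean and SD as inputs;
  no default norms are shipped, because they are sample statistics of
  a normative study, not constants of the method. The flag rule is
  strictly greater than mean + 2 SD.

Every statistic is tested against an independently coded definitional
oracle (explicit-loop sums), and the RM-ANOVA and alpha additionally
against `pingouin` where available.

## Visualisation

Barcode occupancy is *any overlap*: a bin is dark iff at least one
session intersects it, so 1 s checks remain visible at the default
60 s resolution. A session ending exactly on a bin edge does not enter
the next bin; a zero-length session marks its start bin. Suspected
power-off sessions are painted by default (they are retained in the
analyses); callers can exclude them. Heatmap folds average binary cells
into [0, 1] occupancies; the week starts Monday and the weekend is
Saturday + Sunday; a fold group with no days yields NaN rather than a
fabricated zero. SVG output pins file metadata and the element-id hash
salt so identical matrices render byte-identically.

## Synthetic cohort generator

The generator's job is to emulate the *structure* of real screen logs
with known truth, not to imitate any particular dataset. Defaults (all
configurable in `SimConfig`):

* **Intensity.** Session starts follow an inhomogeneous Poisson
  process with piecewise-constant rates per window: night 6, morning
  19, afternoon 30, evening 30 starts/day (sum 85), matching the
  afternoon ≈ evening > morning > night ordering and the ~85 uses/day
  magnitude reported for real cohorts. A per-participant lognormal
  rate multiplier (σ = 0.45, mean 1) supplies the large between-person
  spread; it is truncated to [0.3, 2.5] because an untruncated upper
  tail occasionally demands more busy-time than a day contains once
  counts and durations both scale.
* **Durations.** A seven-component mixture: uniform check modes at
  1–3 s (w = .12), 5–6 s (.10), 10–11 s (.10), other checks 0.5–15 s
  (.13), short uses 15–30 s (.10), a truncated-lognormal body 30 s–30
  min (.43, μ = 5.0, σ = 1.0 in log-seconds), and long uses 30–90 min
  (.02). By construction 55 % of uses fall under 30 s, ordinary use
  totals ≈ 4 h/day, and no ordinary component can cross the 5 h
  artifact threshold. The tail shape beyond the check range is a
  simulator choice — no distributional form for long uses is attested
  in the source analyses.
* **Scheduling.** Drawn starts are serialised by forward-shifting:
  starts are sorted and each session begins no earlier than the
  previous end + 1 s. Durations are never altered, so the planted
  mixture survives exactly; if any start would move by more than 6 h
  the configuration is rejected as infeasible rather than silently
  distorted. (Rejection-resampling was considered and discarded: it
  re-draws durations, biasing the planted mixture, and need not
  terminate at high intensities.)
* **Alarms.** Weekday sessions of 2–8 s at 07:00 sharp, with a 50 %
  snooze repeat at 07:09 — the vertical band a barcode plot shows.
* **Power-off artifacts.** Each night with probability 0.15, a block
  of 6–8.5 h starting between 23:00 and 00:30 replaces any ordinary
  session it overlaps (the phone was off), and appears in the event
  stream as one long session — exactly how the logger failure
  manifests. Retained artifacts lift observed daily totals from ≈ 4
  toward ≈ 5 h/day.
* **Self-reports.** Estimates are constructed so the *sample*
  correlation with true use equals the planted value exactly (noise
  orthogonalised in-sample — the empirical-correlation construction
  familiar from `MASS::mvrnorm(empirical = TRUE)`): duration estimates
  at ρ = 0.5 (mean 4.12 h, SD 1.5), use-count estimates at ρ = 0
  (mean 37.2, SD 15). Exact planting makes recovery tests sharp: at
  n = 23, independently drawn "near-zero" estimates would yield
  E|r| ≈ 0.17 of pure sampling noise.
* **Questionnaire.** One-factor exchangeable items,
  x_ij = √r̄·f_i + √(1−r̄)·e_ij, scaled to a 1–10 integer response;
  latent r̄ = 0.3 yields standardized alpha ≈ .89 after discretisation
  attenuates the realised inter-item correlation. Norm parameters for
  the problem-use flag (mean 102, SD 20) are generator conventions
  chosen so a plausible minority of a default cohort is flagged.

One seed drives a single `numpy` Generator for everything; the same
`SimConfig` regenerates byte-identical fixtures. Ground truth restricts
per-participant metrics to the first `n_days` observed origin dates —
the same day rule the metrics stage applies — so truth and pipeline are
comparable without artifact-driven edge effects at the final midnight.

**What the generator does not emulate:** app-level content,
notification-driven use bursts, day-of-week structure beyond the alarm
schedule, device clock drift, or missing-data patterns other than the
power-off artifact. Tests passing on synthetic cohorts therefore
demonstrate correctness of the *computations* under a realistic event
structure, not validity of any substantive claim about human behaviour.

## Problem sizes in the test suite

Unit tests run on hand-built micro-fixtures; pipeline-level tests use a
shared 23-participant × 14-day cohort (~28 000 sessions). The
effect-recovery test runs 100 seeded replicates of that cohort; the
pairing-oracle test checks 1 000 randomly corrupted streams. These
sizes keep the full suite near a minute while leaving Monte-Carlo
tolerances comfortably wide.

## Known limitations

* The probe cannot distinguish screen use from calls or music; a
  "session" is any interactive period.
* No sphericity correction in the RM-ANOVA; no multiplicity correction
  in the correlation matrix (raw p-values are exposed).
* Day-level handling of DST is by wall clock, as noted above.
* `UNTERMINATED`/`TRUNCATED_AT_BOUNDARY` closing conventions at the
  study boundary are package conventions; other toolchains may close
  the final session differently.
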