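# Methods

This note records the models, conventions and design choices behind
`smartrct`, in the order the data flow through the engine.

## Timekeeping

All clocks are whole days, 0-based, counted per participant from first
app open. Trial-phase days are measured from registration: week *k*
covers trial days [7(*k*−1), 7*k*) for *k* ≥ 1, so week 1 (baseline and
run-in) is days 0–6 and the trial spans days 0–34 with the follow-up
window opening at day 35. Message schedules quoted as "day N of a
phase" are 1-based within that phase (day 3 of week 1 = trial day 2).
The participant clock is monotone; `advance_to` catches up day by day,
so skipping from day 3 to day 40 fires every intermediate timeline
event exactly once, in order. Hour-of-day is deliberately out of scope:
every schedule resolves to a due *day*.

## Participant lifecycle

States: INSTALLED → CONSENTED → SCREENED_{ELIGIBLE,INELIGIBLE} →
REGISTERED → BASELINE → {RANDOMIZED → INTERVENTION → FOLLOW_UP_DUE →
COMPLETED, EXCLUDED_RUN_IN}, with WITHDRAWN reachable from any active
state. Consent requires both the consent statement and the terms and
conditions; refusal leaves the participant at INSTALLED with the
refusal logged. Screening is an opaque configurable predicate
(`required_true` keys over the questionnaire answers) because the
substantive criteria live in the trial protocols, not in the engine.
Registration fingerprints the e-mail address (SHA-256 of the
lower-cased, stripped string) and rejects duplicates case-insensitively;
the raw address is never stored, and outcome exports are keyed by
participant id only.

Duplicate questionnaire submissions (screening, baseline, follow-up)
collapse to the earliest stored record. This is a deliberate guard: in
field use, client-side retries can otherwise deposit multiple identical
survey copies.

### Run-in and randomization

The second eligibility check requires at least `run_in_min_items` (= 15)
barcoded items recorded before randomization. Two counters are kept:

* `items_recorded_week1` — item quantities on lists transmitted during
  trial days 0–6 (the week-1 statistic used in reporting and in the
  under-threshold reminder);
* `run_in_items` — quantities accumulated while the participant is
  still in BASELINE, i.e. week 1 plus the grace window.

Randomization fires at the first clock advance at/after day 7 with
`run_in_items` ≥ 15. The design is silent on participants who reach the
threshold only after day 7, so the engine grants a configurable grace
window (`run_in_grace_days` = 7): items recorded during days 7–13 still
count toward the check, and a participant still short at day 14 is
excluded. Counting item *quantities* rather than distinct barcodes is
also a choice: a shopper buying 15 units of one product passes.

The intervention phase runs `intervention_days` (= 28) from the
randomization day, and the follow-up window opens when it ends — day 35
for the on-time flow, later for participants randomized during grace.
Anchoring follow-up to the actual intervention end (rather than a fixed
day 35 from registration) preserves a full four-week exposure for
late-randomized participants.

## Blocked stratified randomization

Allocation is central and strictly sequential per stratum. Each block
contains every arm exactly `size/|arms|` times in uniformly shuffled
order; the block size is drawn uniformly from the configured set
(default {1×, 2×} the arm count — standard practice for hiding block
boundaries, overridable in config). Within any stratum, arm counts can
therefore never differ by `max(block_sizes)` or more. The stratified
profile crosses ethnicity (3 levels) × interest in healthy eating
(2 levels) into 6 strata; the level sets are configuration, not code.
Each stratum's random sub-stream is spawned from the master seed by
stratum index (`numpy` `SeedSequence.spawn`), so assignments in one
stratum never perturb another's sequence and any replay of the same
seed and per-stratum request order reproduces the allocations. Every
assignment appends to a JSON-lines audit log (participant, stratum,
arm, block id, position, day).

## Label engine

All scheme numbers are configuration data; the shipped defaults are
editable transcriptions in the style of the public labelling guides,
since the design itself prints no thresholds.

* **Traffic Lights** — per-100 g/mL cutoffs for fat, saturated fat,
  sugars, sodium, with a separate (stricter) beverage table. GREEN iff
  amount ≤ low, AMBER iff low < amount ≤ high, RED above; colour
  severity is therefore monotone in the amount.
* **Daily Intake Guide** — %DI = per-serving amount / reference × 100,
  displayed to one decimal place, rounded half away from zero (a
  display-level choice; linearity in serving size and content holds
  exactly on the unrounded amounts and to ±0.15 pp after rounding).
  References: 8700 kJ energy, 70 g fat, 24 g saturated fat, 90 g
  sugars, 2300 mg sodium.
* **Health Star Rating** — band tables are ascending threshold lists;
  points = number of thresholds strictly exceeded, which makes every
  table exhaustive over [0, ∞) and monotone by construction. Final
  score = baseline points (energy, saturated fat, sugars, sodium) −
  modifying points (fvnl %, protein, fibre); stars = 5.0 − 0.5 × (number
  of star cutoffs exceeded), floored at 0.5. Missing optional
  components (fibre, fvnl) contribute zero modifying points — the
  conservative convention. Food and beverage table variants are
  selected by the product's beverage flag; finer category forms are out
  of scope.
* **NIP (control)** — seven rows (energy, protein, fat, saturated fat,
  carbohydrate, sugars, sodium) × (per 100 g/mL, per serving), with no
  interpretive element whatsoever; control-arm purity is asserted in
  the tests.
* **Warning label** — strict `>` at each per-100 threshold. The strict
  boundary is a fixed documented choice; the underlying protocol is not
  reproduced here, so "exactly at threshold" not triggering is the
  engine's convention.

Per-serving amounts are always derived on demand as
`per_100 × serving_size / 100`; nutrients are stored per 100 g/mL only.
Beverage records use the per-100 mL convention with the same field
names — the beverage flag, not a unit field, selects scheme variants.

## Food database

CSV rows are validated independently: malformed barcodes, negative
nutrients, non-positive serving sizes and out-of-range fvnl percentages
reject the row (never the file) and are listed with reasons in a JSON
validation report; a missing header column is a format error. Duplicate
barcodes keep the first occurrence and report the rest — deterministic
and auditable. EAN check-digit mismatches are warnings, not rejections,
because real composition databases contain nonconforming codes. The
database is static for a run; a barcode miss is a normal outcome that
feeds the crowdsourcing path, not an error.

## Notification rules

The ten rules are split into time-driven (anchor event + strictly
increasing day offsets, evaluated by `due_messages`) and event-driven
(fired directly on screening failure, list transmission, follow-up
completion). Records are unique on (rule, participant, due day);
delivery is idempotent; and a per-rule repeat cap bounds total firings
per participant — the structural fix for runaway reminder streams.
Interpretations fixed here:

* "once a month" in the registration-reminder cascade = every 28 days,
  capped at five weeks before the end of the configured recruitment
  window (540 days by default); the cascade also covers a registered
  participant whose baseline questionnaire is outstanding.
* The intervention keep-recording offsets (4, 6, 9, 12, 18, 24 days)
  anchor on the later of the last transmitted list and the intervention
  start, so each new list resets the stream.
* Follow-up reminders (6, 12, 18, 24, 30 days after intervention end)
  halt permanently at completion.

Offsets, channels and caps are serializable data; reloading the table
reproduces identical behaviour on a replayed trace (tested).

## Cohort simulator

The behaviour model exists to exercise the engine at realistic volumes,
not to model human shopping. Per participant: Bernoulli completion of
each enrolment stage; shopping as a daily Poisson trip process (rate =
`trips_per_week`/7, starting the day after registration) with
`max(1, Poisson(items_per_trip_mean))` items per trip; a per-list
receipt probability; a small probability of scanning a barcode absent
from the database (feeding the crowdsource path); and a daily Bernoulli
dropout hazard per phase. Defaults (consent 0.90, screening pass 0.80,
registration 0.90, baseline questionnaire 0.95, follow-up 0.80, 2
trips/week of ~11 items, receipt 0.70, hazards 0.010/0.005/0.005 per
day) were chosen once so that roughly half of installers reach
randomization and a transmitted list carries on the order of ten items —
the funnel shape and list size a national recruitment campaign of this
kind produces. The zero-attrition variant (`compliant_behavior`) sets
every probability to 1, daily shopping and zero hazards; in that limit
the funnel is exactly flat from registration to completion.

What the simulator does *not* emulate: purchase realism (products are
drawn uniformly from the database), within-household correlation,
staggered recruitment dates (all participants install on day 0),
device/connectivity failures beyond the explicit transmission-failure
path, and any behavioural response to the labels themselves. Passing
tests therefore demonstrate that the trial *machinery* — eligibility,
timelines, allocation balance, messaging, data capture and export — is
correct under load, not that any labelling effect would be detected.

## Problem sizes and numerics

Test cohorts run at n = 25–400 participants over a 77-day horizon with
databases of 60–300 products; the acceptance script uses n = 400 per
profile. Determinism everywhere: one master seed fans out through
`SeedSequence.spawn` to the allocator, the capture sampler and the
simulator, and all exports sort deterministically so repeated runs are
byte-identical. Statistical checks (block-size frequencies, permutation
uniformity via chi-square against the enumerated permutation universe,
mean week-1 item volume) run at fixed seeds with tolerances set from
the Monte-Carlo standard error at the simulated sizes.

## Known limitations

* The shipped scheme tables are stylistic transcriptions, editable per
  deployment; they are not a certified implementation of any specific
  regulatory algorithm revision.
* Whole-day granularity means same-day orderings are conventions
  (shopping before dropout before messages in the simulator).
* Withdrawal retains previously captured data in the exports; purging
  on withdrawal would be a policy layer above the engine.
* Transport of notifications (push vs in-app) is a tag on the record;
  no delivery infrastructure is modelled.
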