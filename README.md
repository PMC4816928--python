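# smartrct

A desk-scale engine for **fully automated ("smart") randomized controlled
trials of nutrition labelling**, delivered through a smartphone app.

Real-world RCTs of front-of-pack nutrition labels are hard: the
intervention (a label format) has to reach participants inside ordinary
supermarkets, and the outcome (what they actually buy) has to be captured
item by item. A smart-trial app solves both by scanning product barcodes —
matched against a food composition database, a scan either records a
purchase in an electronic shopping list (data collection) or displays the
participant's randomly allocated nutrition label (intervention delivery).
The entire trial workflow — consent, two-stage eligibility, registration,
randomization, notifications, follow-up — runs without any manual input
from the research team.

`smartrct` re-creates that logic core as a library plus CLI, exercised
end-to-end by a synthetic participant-cohort simulator. It is intended for
methodologists and trial engineers who want to prototype, test and audit
smart-trial logic (timelines, eligibility rules, allocation, reminder
schedules) before anything touches real participants.

## What is inside

| Module | Role |
| --- | --- |
| `smartrct.food_db` | Barcode-keyed (EAN-8/13) food composition database: CSV loading with a validation report, exact barcode lookup, seeded same-category product sampling |
| `smartrct.labels` | The five label formats: Daily Intake Guide (%DI per serving), Traffic Lights (GREEN/AMBER/RED per nutrient), Health Star Rating (0.5–5 stars from a points algorithm), Nutrition Information Panel (control), Warning Label — all driven by configurable threshold/point tables |
| `smartrct.randomization` | Server-side central blocked randomization with variable block sizes and optional stratification, with a JSON-lines audit log |
| `smartrct.trial` | The participant lifecycle state machine: consent → screening → registration → baseline/run-in (≥ 15 barcoded items in week 1) → randomization (end of week 1) → 4-week intervention → follow-up (end of week 5) |
| `smartrct.notifications` | The ten-rule notification/reminder engine (in-app and push), with per-rule repeat caps and idempotent delivery |
| `smartrct.capture` | Scan events, electronic shopping lists, till-receipt metadata, label views, crowdsource submissions; privacy-separated outcome exports |
| `smartrct.simulator` | Synthetic cohort generator (behaviour model: stage probabilities, Poisson shopping, phase-specific dropout) and funnel reporting |
| `smartrct.cli` | `smartrct` command: `validate-db`, `label`, `simulate`, `report`, `notify-debug` |

Two country profiles ship as configuration: a 5-arm design
(DIG, TLL, HSR, WARNING, NIP control; unstratified) and a 3-arm design
(TLL, HSR, NIP; allocation stratified by ethnicity × interest in healthy
eating). Both use a 1-week baseline/run-in plus 4-week intervention.

The Health Star Rating at the core of the HSR arm is the standard
points-based algorithm: baseline risk points from energy, saturated fat,
total sugars and sodium per 100 g/mL, minus modifying points from
fruit/vegetable/nut/legume content, protein and fibre; the final score
maps monotonically onto stars in {0.5, 1.0, …, 5.0}. All band tables and
the traffic-light / warning cutoffs are editable YAML data, not code.

## Worked example

Generate a synthetic food database, then label one product under three
different allocations:

```bash
python -c "from smartrct import make_synthetic_db; from smartrct.simulator import write_db_csv; \
           write_db_csv(make_synthetic_db(n_products=40, seed=2), 'foods.csv')"
smartrct label foods.csv 9300000000002 HSR
```

```json
{"arm": "HSR", "payload": {"baseline_points": {"energy": 6, "satfat": 0, "sodium": 8, "sugars": 2},
 "final_score": 13, "modifying_points": {"fibre": 1, "fvnl": 0, "protein": 2}, "stars": 2.0}}
```

This product accrues 16 baseline risk points (6 energy + 8 sodium + 2
sugars) against 3 modifying points, a final score of 13 and hence 2.0
stars. The same barcode under `TLL` colours sodium RED (789 mg/100 g is
above the 600 mg cutoff) and fat/sugars AMBER; under `DIG` its serving
provides 40.2 % of the 8700 kJ reference daily energy intake.

Simulate a 100-participant cohort through the 3-arm stratified profile:

```bash
smartrct simulate -n 100 --db-size 200 --seed 11 --out run/
```

```json
{"downloads": 100, "consented": 92, "screened_eligible": 72, "registered": 65,
 "randomized": 47, "excluded_run_in": 8, "withdrawn": 17, "completed": 30,
 "lists": 477, "items": 5310, "receipts": 326, "label_views": 3611,
 "crowdsource": 78, "notifications_sent": 858,
 "per_arm": {"HSR": 16, "NIP": 14, "TLL": 17}}
```

The funnel is monotone (100 → 92 → 72 → 65 → 47 → 30): 8 of 100 installers
refused consent, 20 failed screening, 8 recorded fewer than 15 items
during the run-in week and were excluded, and the 47 randomized
participants are near-balanced across the three arms (the spread is
bounded by the largest randomization block). `run/` contains the full
event log, the allocation audit log and the five outcome exports
(lists, items, receipts, label views, crowdsource), which carry no
identifying fields.

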