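"""Synthetic participant-cohort simulator and funnel reporting.

Drives synthetic participants day-by-day through the full engine —
consent, screening, registration, baseline shopping, the run-in check,
randomization, intervention-phase scanning with label delivery,
follow-up — and aggregates the resulting event log into a recruitment
funnel / usage report.

The behaviour model is deliberately simple: stage-completion
probabilities, a Poisson shopping process (daily trip rate =
trips-per-week / 7, item count per trip Poisson with a floor of one),
a per-list receipt-photo probability, and phase-specific daily dropout
hazards. It exists to exercise the engine at realistic volumes, not to
model human shopping behaviour; defaults are chosen so that roughly
half of installers reach randomization and a transmitted list carries
on the order of ten items, the volumes a national recruitment campaign
of this kind produces.

Also provides the synthetic food-database generator used throughout
the test suite and the CLI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .config import TrialConfig
from .errors import DuplicateRegistrationError, FormatError
from .food_db import FoodDatabase, Product, build_database
from .trial import State, TrialEngine


@dataclass
class BehaviorModel:
    """Stochastic behaviour of one synthetic cohort.

    Probabilities are per stage (consent, screening pass, registration,
    questionnaires) or per event (receipt per list, crowdsource per
    unmatched scan); ``dropout_hazard`` is the daily probability of
    withdrawing, per phase.
    """

    consent_prob: float = 0.90
    screen_pass_prob: float = 0.80
    registration_prob: float = 0.90
    baseline_questionnaire_prob: float = 0.95
    followup_prob: float = 0.80
    trips_per_week: float = 2.0
    items_per_trip_mean: float = 11.0
    receipt_prob: float = 0.70
    unknown_barcode_prob: float = 0.05
    crowdsource_prob: float = 0.30
    dropout_hazard: dict[str, float] = field(
        default_factory=lambda: {"baseline": 0.010, "intervention": 0.005, "followup": 0.005})

    def __post_init__(self) -> None:
        for name in ("consent_prob", "screen_pass_prob", "registration_prob",
                     "baseline_questionnaire_prob", "followup_prob", "receipt_prob",
                     "unknown_barcode_prob", "crowdsource_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.trips_per_week < 0 or self.items_per_trip_mean < 0:
            raise ValueError("rates must be >= 0")


def compliant_behavior() -> BehaviorModel:
    """Zero-attrition limit: every stage completed, ample shopping."""
    return BehaviorModel(consent_prob=1, screen_pass_prob=1, registration_prob=1,
                         baseline_questionnaire_prob=1, followup_prob=1,
                         trips_per_week=7.0, items_per_trip_mean=12.0,
                         unknown_barcode_prob=0.0,
                         dropout_hazard={"baseline": 0.0, "intervention": 0.0, "followup": 0.0})


@dataclass
class CohortReport:
    """Recruitment-funnel and usage counts aggregated from an event log."""

    downloads: int = 0
    consented: int = 0
    screened_eligible: int = 0
    screened_ineligible: int = 0
    registered: int = 0
    randomized: int = 0
    excluded_run_in: int = 0
    completed: int = 0
    withdrawn: int = 0
    lists: int = 0
    items: int = 0
    receipts: int = 0
    label_views: int = 0
    crowdsource: int = 0
    notifications_sent: int = 0
    per_arm: dict[str, int] = field(default_factory=dict)

    def funnel(self) -> list[int]:
        return [self.downloads, self.consented, self.screened_eligible,
                self.registered, self.randomized, self.completed]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def funnel_report(events: list[dict]) -> CohortReport:
    """Deterministic aggregation of an event log into a cohort report.

    Raises
    ------
    FormatError
        On a malformed event, naming its position in the log.
    """
    report = CohortReport()
    counters = {
        "download": "downloads", "consented": "consented",
        "screened_eligible": "screened_eligible", "screened_ineligible": "screened_ineligible",
        "registered": "registered", "excluded_run_in": "excluded_run_in",
        "completed": "completed", "withdrawn": "withdrawn",
        "receipt": "receipts", "label_view": "label_views", "crowdsource": "crowdsource",
        "notification_sent": "notifications_sent",
    }
    for i, event in enumerate(events):
        if not isinstance(event, dict) or "event" not in event or "participant_id" not in event:
            raise FormatError(f"malformed event at line {i}")
        kind = event["event"]
        if kind in counters:
            setattr(report, counters[kind], getattr(report, counters[kind]) + 1)
        elif kind == "randomized":
            report.randomized += 1
            arm = event.get("arm", "?")
            report.per_arm[arm] = report.per_arm.get(arm, 0) + 1
        elif kind == "list_submitted":
            report.lists += 1
            report.items += int(event.get("total_quantity", 0))
    return report


def make_synthetic_db(n_products: int = 300, n_categories: int = 12,
                      seed: int = 0, beverage_frac: float = 0.2) -> FoodDatabase:
    """Generate a synthetic barcode-keyed food composition database.

    Emulates a packaged-food composition backend: EAN-13 barcodes with
    valid check digits, products spread over categories, nutrient
    amounts drawn uniformly from ranges typical of packaged foods
    (energy 100–3000 kJ/100 g, fat up to 30 g, sugars bounded by
    carbohydrate, sodium up to 1200 mg), optional fibre and
    fruit/veg/nut/legume content.
    """
    rng = np.random.default_rng(seed)
    products = []
    for i in range(n_products):
        body = f"93{i:010d}"
        total = sum(int(c) * (3 if j % 2 == 0 else 1) for j, c in enumerate(reversed(body)))
        barcode = body + str((10 - total % 10) % 10)
        is_bev = rng.random() < beverage_frac
        fat = float(rng.uniform(0, 5 if is_bev else 30))
        carb = float(rng.uniform(0, 60))
        products.append(Product(
            barcode=barcode,
            name=f"product-{i:04d}",
            category_id=f"cat-{int(rng.integers(n_categories)):02d}",
            is_beverage=is_bev,
            serving_size=float(rng.uniform(150, 350)) if is_bev else float(rng.uniform(20, 250)),
            energy_kj_100=float(rng.uniform(50, 1500) if is_bev else rng.uniform(100, 3000)),
            protein_g_100=float(rng.uniform(0, 25)),
            fat_g_100=fat,
            satfat_g_100=fat * float(rng.uniform(0, 0.6)),
            carb_g_100=carb,
            sugars_g_100=carb * float(rng.uniform(0, 0.8)),
            sodium_mg_100=float(rng.uniform(0, 1200)),
            fibre_g_100=float(rng.uniform(0, 10)) if rng.random() < 0.7 else None,
            fvnl_pct=float(rng.uniform(0, 100)) if rng.random() < 0.4 else None,
        ))
    return build_database(products)


def write_db_csv(db: FoodDatabase, path) -> None:
    """Serialize a database to the canonical CSV interchange format."""
    import pandas as pd
    from .food_db import CSV_COLUMNS
    rows = [{c: getattr(p, c) for c in CSV_COLUMNS} for p in db.products.values()]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


class _SyntheticParticipant:
    """Per-participant simulation state (not part of the engine)."""

    def __init__(self, pid: str, rng: np.random.Generator, behavior: BehaviorModel,
                 config: TrialConfig):
        self.pid = pid
        self.rng = rng
        self.will_consent = rng.random() < behavior.consent_prob
        self.will_pass_screen = rng.random() < behavior.screen_pass_prob
        self.will_register = rng.random() < behavior.registration_prob
        self.will_baseline_q = rng.random() < behavior.baseline_questionnaire_prob
        self.will_followup = rng.random() < behavior.followup_prob
        self.factors = {f: levels[int(rng.integers(len(levels)))]
                        for f, levels in config.stratification.items()}
        self.active = True


def simulate_cohort(n: int, config: TrialConfig, behavior: BehaviorModel,
                    db: FoodDatabase, seed: int = 0,
                    ) -> tuple[TrialEngine, CohortReport]:
    """Run ``n`` synthetic participants through the full trial engine.

    All participants install on day 0 and are simulated day-by-day for
    the whole trial window plus the follow-up reminder tail. Returns the
    engine (holding the event log, capture store, allocation audit log)
    and the aggregated :class:`CohortReport`. Fully reproducible given
    ``seed``.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    engine = TrialEngine(config, db, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    barcodes = list(db.products.keys())
    daily_trip_rate = behavior.trips_per_week / 7.0
    horizon = config.total_days + config.run_in_grace_days + 35

    sims: list[_SyntheticParticipant] = []
    for i in range(n):
        pid = f"P{i:05d}"
        sim = _SyntheticParticipant(pid, rng, behavior, config)
        sims.append(sim)
        engine.add_participant(pid, day=0)
        engine.consent(pid, sim.will_consent, sim.will_consent, day=0)
        if not sim.will_consent:
            sim.active = False
            continue
        answers = {k: sim.will_pass_screen for k in config.screening.required_true}
        engine.screen(pid, answers, day=0)
        if not sim.will_pass_screen:
            sim.active = False
            continue
        if not sim.will_register:
            continue  # stalls at SCREENED_ELIGIBLE; registration reminders fire
        try:
            engine.register(pid, f"{pid.lower()}@example.org", day=0, factors=sim.factors)
        except DuplicateRegistrationError:  # pragma: no cover - ids are unique
            sim.active = False
            continue
        if sim.will_baseline_q:
            engine.submit_baseline_questionnaire(pid, {"demographics": "synthetic"}, day=0)
        # else: stalls at REGISTERED; the same reminder cascade covers it

    for day in range(1, horizon + 1):
        for sim in sims:
            if not sim.active:
                continue
            p = engine.participants[sim.pid]
            if p.state in (State.SCREENED_INELIGIBLE, State.EXCLUDED_RUN_IN,
                           State.COMPLETED, State.WITHDRAWN):
                sim.active = False
                continue
            engine.advance_to(sim.pid, day)
            p = engine.participants[sim.pid]

            # Daily dropout hazard, by phase.
            phase = ("baseline" if p.state is State.BASELINE
                     else "intervention" if p.state is State.INTERVENTION
                     else "followup" if p.state is State.FOLLOW_UP_DUE else None)
            if phase is not None and rng.random() < behavior.dropout_hazard.get(phase, 0.0):
                engine.withdraw(sim.pid, day=day)
                sim.active = False
                continue

            # Shopping trips (scan + transmit a list, maybe a receipt).
            if p.state in (State.BASELINE, State.INTERVENTION):
                for _ in range(int(rng.poisson(daily_trip_rate))):
                    n_items = max(1, int(rng.poisson(behavior.items_per_trip_mean)))
                    for _ in range(n_items):
                        if barcodes and rng.random() >= behavior.unknown_barcode_prob:
                            code = barcodes[int(rng.integers(len(barcodes)))]
                        else:
                            code = "4" + "".join(str(int(d)) for d in rng.integers(0, 10, 12))
                        outcome = engine.scan(sim.pid, code)
                        if outcome.crowdsource_offered and rng.random() < behavior.crowdsource_prob:
                            engine.submit_crowdsource(sim.pid, code)
                    lst = engine.submit_list(sim.pid)
                    if rng.random() < behavior.receipt_prob:
                        engine.add_receipt(sim.pid, lst.list_id)

            # Follow-up questionnaire on the day it falls due.
            if engine.participants[sim.pid].state is State.FOLLOW_UP_DUE and sim.will_followup:
                engine.complete_followup(sim.pid, {"followup": "synthetic"}, day=day)

            engine.deliver_due_messages(sim.pid)

    return engine, funnel_report(engine.events)
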