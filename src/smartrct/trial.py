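"""Participant lifecycle state machine and trial event dispatch.

The automated trial walks each participant through a fixed sequence:
install -> consent (consent statement and T&C both mandatory) ->
screening questionnaire (first eligibility check) -> registration
(duplicate-e-mail check) -> baseline questionnaire -> 1-week baseline
and run-in -> second eligibility check (>= 15 barcoded items recorded)
-> blocked randomization -> 4-week intervention -> follow-up
questionnaire (end of week 5) -> completion. Withdrawal is allowed from
any state; failing either eligibility check is terminal.

Timekeeping: whole days, 0-based, counted per participant from first
app open; trial-phase days are measured from registration. The
participant clock is monotone, and the engine catches up on every
advance — all timeline events between the previous and the new clock
fire exactly once, in order, so replay and day-skipping are safe.

Privacy: the e-mail address is stored only as a one-way fingerprint,
kept on the participant record and never written to outcome exports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Optional

import numpy as np

from .capture import CaptureStore, ScanOutcome
from .config import Stratum, TrialConfig
from .errors import (
    DuplicateRegistrationError,
    MonotonicClockError,
    ScreeningError,
    StateError,
)
from .food_db import FoodDatabase
from .notifications import NotificationEngine, NotificationRecord
from .randomization import Allocator


class State(IntEnum):
    """Lifecycle states, ordered along the trial sequence."""

    INSTALLED = 0
    CONSENTED = 1
    SCREENED_INELIGIBLE = 2
    SCREENED_ELIGIBLE = 3
    REGISTERED = 4
    BASELINE = 5
    EXCLUDED_RUN_IN = 6
    RANDOMIZED = 7
    INTERVENTION = 8
    FOLLOW_UP_DUE = 9
    COMPLETED = 10
    WITHDRAWN = 11


#: Terminal states: no further timeline events fire.
TERMINAL = {State.SCREENED_INELIGIBLE, State.EXCLUDED_RUN_IN,
            State.COMPLETED, State.WITHDRAWN}


def email_fingerprint(email: str) -> str:
    """One-way, case-insensitive fingerprint of an e-mail address."""
    return hashlib.sha256(email.strip().lower().encode()).hexdigest()


@dataclass
class Questionnaire:
    kind: str                      # screening | baseline | follow-up
    answers: dict
    completed_day: int


@dataclass
class Participant:
    """One user's lifecycle state, anchors, counters and records."""

    id: str
    state: State = State.INSTALLED
    email_fp: Optional[str] = None
    stratum: Stratum = ()
    arm: Optional[str] = None
    factors: dict = field(default_factory=dict)

    install_day: int = 0
    consent_day: Optional[int] = None
    screened_day: Optional[int] = None
    registration_day: Optional[int] = None
    baseline_day: Optional[int] = None
    randomization_day: Optional[int] = None
    intervention_start_day: Optional[int] = None
    intervention_end_day: Optional[int] = None
    followup_day: Optional[int] = None
    withdrawn_day: Optional[int] = None

    items_recorded_week1: int = 0      # lists transmitted during trial days [0, baseline_days)
    run_in_items: int = 0              # items counting toward the second eligibility check
    clock: int = 0                     # last advanced day

    questionnaires: dict[str, Questionnaire] = field(default_factory=dict)

    def trial_day(self, clock: int) -> Optional[int]:
        """Day index from registration, None before registration."""
        if self.registration_day is None:
            return None
        return clock - self.registration_day


class TrialEngine:
    """Wires the food database, allocator, notifications and capture store.

    All randomness (allocation sequences, related-product sampling)
    derives from the single ``seed``.
    """

    def __init__(self, config: TrialConfig, db: FoodDatabase, seed: int = 0):
        self.config = config
        self.db = db
        root = np.random.SeedSequence(seed)
        alloc_seed, capture_seed = root.spawn(2)
        self.allocator = Allocator(config.arms, config.block_sizes,
                                   config.strata(), seed=alloc_seed.entropy % (2 ** 31))
        self.notifications = NotificationEngine(config)
        self.store = CaptureStore(rng=np.random.default_rng(capture_seed))
        self.participants: dict[str, Participant] = {}
        self.registry: set[str] = set()          # e-mail fingerprints
        self.events: list[dict] = []             # append-only event log

    # -- event log ----------------------------------------------------------

    def _log(self, participant_id: str, event: str, day: int, **payload) -> None:
        self.events.append({"day": day, "participant_id": participant_id,
                            "event": event, **payload})

    def write_event_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for event in self.events:
                fh.write(json.dumps(event) + "\n")

    # -- enrolment ----------------------------------------------------------

    def add_participant(self, participant_id: str, day: int = 0) -> Participant:
        """First app open ('download')."""
        if participant_id in self.participants:
            raise StateError(f"participant {participant_id} already exists")
        p = Participant(id=participant_id, install_day=day, clock=day)
        self.participants[participant_id] = p
        self._log(participant_id, "download", day)
        return p

    def consent(self, participant_id: str, accepted_consent: bool,
                accepted_tc: bool, day: int = 0) -> Participant:
        """Consent statement and terms-and-conditions; both mandatory.

        Repeated acceptance is an idempotent no-op; refusal leaves the
        participant INSTALLED with a refusal event logged.
        """
        p = self.participants[participant_id]
        if p.state is not State.INSTALLED:
            return p  # idempotent: a single CONSENTED transition
        if accepted_consent and accepted_tc:
            p.state = State.CONSENTED
            p.consent_day = day
            self._log(participant_id, "consented", day)
        else:
            self._log(participant_id, "consent_refused", day,
                      consent=accepted_consent, tc=accepted_tc)
        return p

    def screen(self, participant_id: str, answers: dict, day: int = 0) -> Participant:
        """First eligibility check from the screening questionnaire."""
        p = self.participants[participant_id]
        if p.state is not State.CONSENTED:
            if "screening" in p.questionnaires:
                self._log(participant_id, "questionnaire_duplicate_rejected", day, kind="screening")
                return p
            raise StateError(f"cannot screen in state {p.state.name}")
        p.questionnaires["screening"] = Questionnaire("screening", answers, day)
        p.screened_day = day
        eligible = self.config.screening.evaluate(answers)
        if eligible:
            p.state = State.SCREENED_ELIGIBLE
            self._log(participant_id, "screened_eligible", day)
        else:
            p.state = State.SCREENED_INELIGIBLE
            self._log(participant_id, "screened_ineligible", day)
            rec = self.notifications.on_screening_failed(p, day)
            if rec is not None:
                self._send(rec, day)
        return p

    def register(self, participant_id: str, email: str, day: int = 0,
                 factors: Optional[dict] = None) -> Participant:
        """Registration with the duplicate-e-mail check.

        A participant whose e-mail collides may retry with another
        address; the rejected attempt is logged.
        """
        p = self.participants[participant_id]
        if p.state is not State.SCREENED_ELIGIBLE:
            raise StateError(f"cannot register in state {p.state.name}")
        fp = email_fingerprint(email)
        if fp in self.registry:
            self._log(participant_id, "registration_rejected", day, reason="duplicate_email")
            raise DuplicateRegistrationError("e-mail address already registered")
        self.registry.add(fp)
        p.email_fp = fp
        p.state = State.REGISTERED
        p.registration_day = day
        p.factors = dict(factors or {})
        p.stratum = self.config.stratum_for(p.factors)
        self._log(participant_id, "registered", day)
        return p

    def submit_baseline_questionnaire(self, participant_id: str, answers: dict,
                                      day: int = 0) -> Participant:
        """Baseline questionnaire; unlocks the baseline (run-in) phase.

        Duplicate submissions collapse to the earliest stored record.
        """
        p = self.participants[participant_id]
        if "baseline" in p.questionnaires:
            self._log(participant_id, "questionnaire_duplicate_rejected", day, kind="baseline")
            return p
        if p.state is not State.REGISTERED:
            raise StateError(f"cannot submit baseline questionnaire in state {p.state.name}")
        p.questionnaires["baseline"] = Questionnaire("baseline", answers, day)
        p.state = State.BASELINE
        p.baseline_day = day
        self._log(participant_id, "baseline_start", day)
        return p

    # -- timeline -----------------------------------------------------------

    def run_in_check(self, participant_id: str) -> bool:
        """Second eligibility check: enough items recorded during run-in."""
        p = self.participants[participant_id]
        return p.run_in_items >= self.config.run_in_min_items

    def advance_to(self, participant_id: str, day: int) -> list[str]:
        """Advance the participant clock, firing due timeline events.

        Catch-up safe: skipping from day 3 to day 40 fires every
        intermediate event exactly once, in order. Returns the names of
        the events fired.
        """
        p = self.participants[participant_id]
        if day < p.clock:
            raise MonotonicClockError(f"clock moved backwards: {p.clock} -> {day}")
        fired: list[str] = []
        for d in range(p.clock + 1, day + 1):
            p.clock = d
            if p.state in TERMINAL:
                continue
            fired.extend(self._tick(p, d))
        p.clock = day
        return fired

    def _tick(self, p: Participant, d: int) -> list[str]:
        cfg = self.config
        fired: list[str] = []
        trial_day = p.trial_day(d)
        if trial_day is None:
            return fired

        # Second eligibility check, randomization, intervention start.
        if p.state is State.BASELINE and trial_day >= cfg.baseline_days:
            if self.run_in_check(p.id):
                arm = self.allocator.assign(p.stratum, participant_id=p.id, day=d)
                p.arm = arm
                p.state = State.RANDOMIZED
                p.randomization_day = d
                self._log(p.id, "run_in_pass", d, items=p.run_in_items)
                self._log(p.id, "randomized", d, arm=arm, stratum=list(p.stratum))
                fired += ["run_in_pass", "randomized"]
                # Intervention delivery begins at randomization.
                p.state = State.INTERVENTION
                p.intervention_start_day = d
                p.intervention_end_day = d + cfg.intervention_days
                self._log(p.id, "intervention_start", d)
                fired.append("intervention_start")
            elif trial_day >= cfg.baseline_days + cfg.run_in_grace_days:
                p.state = State.EXCLUDED_RUN_IN
                self._log(p.id, "excluded_run_in", d, items=p.run_in_items)
                fired.append("excluded_run_in")

        # Follow-up questionnaire falls due when the intervention ends.
        if p.state is State.INTERVENTION and p.intervention_end_day is not None \
                and d >= p.intervention_end_day:
            p.state = State.FOLLOW_UP_DUE
            self._log(p.id, "followup_due", d)
            fired.append("followup_due")
        return fired

    def complete_followup(self, participant_id: str, answers: dict,
                          day: Optional[int] = None) -> Participant:
        """Follow-up questionnaire submission; completes the trial.

        Duplicate submissions collapse to the earliest stored record.
        """
        p = self.participants[participant_id]
        day = p.clock if day is None else day
        if "follow-up" in p.questionnaires:
            self._log(participant_id, "questionnaire_duplicate_rejected", day, kind="follow-up")
            return p
        if p.state is not State.FOLLOW_UP_DUE:
            raise StateError(f"follow-up submitted in state {p.state.name}")
        p.questionnaires["follow-up"] = Questionnaire("follow-up", answers, day)
        p.state = State.COMPLETED
        p.followup_day = day
        self._log(participant_id, "completed", day)
        rec = self.notifications.on_followup_completed(p, day)
        if rec is not None:
            self._send(rec, day)
        return p

    def withdraw(self, participant_id: str, day: Optional[int] = None) -> Participant:
        """Withdrawal, allowed from any non-terminal state."""
        p = self.participants[participant_id]
        day = p.clock if day is None else day
        if p.state in TERMINAL:
            return p
        p.state = State.WITHDRAWN
        p.withdrawn_day = day
        self._log(participant_id, "withdrawn", day)
        return p

    def progress(self, participant_id: str, clock: Optional[int] = None) -> int:
        """Completed-week count shown by the in-app progress tracker."""
        p = self.participants[participant_id]
        if p.state < State.REGISTERED or p.registration_day is None:
            raise StateError("progress is tracked from registration")
        day = p.clock if clock is None else clock
        trial_day = max(0, day - p.registration_day)
        return min(5, trial_day // 7)

    # -- capture passthrough ------------------------------------------------

    def scan(self, participant_id: str, barcode: str, quantity: int = 1) -> ScanOutcome:
        p = self.participants[participant_id]
        outcome = self.store.scan(p, barcode, self.db, self.config, p.clock, quantity=quantity)
        self._log(participant_id, "scan", p.clock, barcode=barcode, matched=outcome.matched,
                  mode=outcome.mode)
        if outcome.label is not None:
            self._log(participant_id, "label_view", p.clock, barcode=barcode, arm=p.arm)
        return outcome

    def submit_list(self, participant_id: str, transmitted: bool = True):
        """Transmit the open list and update the run-in counters."""
        p = self.participants[participant_id]
        lst = self.store.submit_list(p, p.clock, transmitted=transmitted)
        if not transmitted:
            self._log(participant_id, "list_transmission_failed", p.clock, list_id=lst.list_id)
            return lst
        total = lst.total_quantity
        trial_day = p.trial_day(p.clock)
        if trial_day is not None and 0 <= trial_day < self.config.baseline_days:
            p.items_recorded_week1 += total
        # Items recorded before randomization/exclusion count toward the
        # second eligibility check (week 1 plus the grace window).
        if p.state is State.BASELINE:
            p.run_in_items += total
        self._log(participant_id, "list_submitted", p.clock, list_id=lst.list_id,
                  n_items=len(lst.items), total_quantity=total)
        rec = self.notifications.on_list_submitted(p, p.clock, p.items_recorded_week1)
        if rec is not None:
            self._send(rec, p.clock)
        return lst

    def add_receipt(self, participant_id: str, list_id: str):
        p = self.participants[participant_id]
        receipt = self.store.add_receipt(p, p.clock, list_id)
        self._log(participant_id, "receipt", p.clock, receipt_id=receipt.receipt_id,
                  list_id=list_id)
        return receipt

    def submit_crowdsource(self, participant_id: str, barcode: str, photo_count: int = 1):
        p = self.participants[participant_id]
        sub = self.store.submit_crowdsource(p, barcode, p.clock, photo_count=photo_count)
        self._log(participant_id, "crowdsource", p.clock, barcode=barcode)
        return sub

    # -- notifications ------------------------------------------------------

    def _send(self, record: NotificationRecord, day: int) -> None:
        self.notifications.mark_sent(record)
        self._log(record.participant_id, "notification_sent", day,
                  rule=record.rule_id, channel=record.channel)

    def deliver_due_messages(self, participant_id: str) -> list[NotificationRecord]:
        """Evaluate, deliver and log all messages due at the current clock."""
        p = self.participants[participant_id]
        due = self.notifications.due_messages(p, p.clock,
                                              last_list_day=self.store.last_list_day(p.id))
        for rec in due:
            self._send(rec, p.clock)
        return due
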