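"""Notification and reminder rule engine.

Ten message rules drive participant engagement: an ineligibility notice,
a registration/baseline-questionnaire reminder cascade, run-in item-count
feedback on every submitted list, baseline and intervention recording
reminders, end-of-trial and follow-up prompts, and the completion notice.

Rules split into two kinds:

* **time-driven** rules have an anchor event and a list of day offsets;
  :meth:`NotificationEngine.due_messages` materializes the records that
  fall due at the evaluated clock day.
* **event-driven** rules fire when the engine reports the event itself
  (screening failure, list submission, follow-up completion).

Every record is unique on (rule, participant, due day), and a per-rule
repeat cap bounds how often a rule may fire for one participant — the
guard against runaway reminder streams. Offsets, channels and caps are
data (serializable, reloadable); only the trigger predicates are code.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import TYPE_CHECKING, Optional

from .config import TrialConfig
from .errors import ConfigError

if TYPE_CHECKING:  # pragma: no cover
    from .trial import Participant

CHANNEL_IN_APP = "in-app"
CHANNEL_PUSH = "push"

# Rule identifiers.
RULE_INELIGIBLE = "ineligible_notice"
RULE_REGISTRATION = "registration_reminder"
RULE_RUNIN_UNDER = "runin_under_threshold"
RULE_LIST_SENT = "list_sent_success"
RULE_BASELINE_RECORDING = "baseline_recording_reminder"
RULE_INTERVENTION_RECORDING = "intervention_recording_reminder"
RULE_ENDING_SOON = "trial_ending_soon"
RULE_FOLLOWUP_REQUEST = "followup_request"
RULE_FOLLOWUP_REMINDER = "followup_reminder"
RULE_COMPLETED = "trial_completed"

_UNCAPPED = 999


@dataclass
class MessageRule:
    """One rule row: schedule data plus delivery channel and repeat cap.

    ``offsets`` are day offsets from the anchor event (empty for
    event-driven rules). Offsets must be strictly increasing and the
    cap at least 1.
    """

    rule_id: str
    channel: str
    cap: int
    offsets: list[int] = field(default_factory=list)
    anchor: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise ConfigError(f"rule {self.rule_id}: repeat cap must be >= 1")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ConfigError(f"rule {self.rule_id}: offsets must be strictly increasing")

    def to_dict(self) -> dict:
        return asdict(self)


def registration_offsets(recruitment_window_days: int) -> list[int]:
    """Offsets from consent for the registration reminder cascade.

    Two days after consent, then weekly four times, then every 28 days
    until five weeks before the end of the recruitment window.
    """
    offsets = [2, 9, 16, 23, 30]
    cutoff = recruitment_window_days - 35
    day = 30 + 28
    while day <= cutoff:
        offsets.append(day)
        day += 28
    return offsets


def default_rules(config: TrialConfig) -> list[MessageRule]:
    """The shipped rule table for a trial configuration."""
    reg_offsets = registration_offsets(config.recruitment_window_days)
    return [
        MessageRule(RULE_INELIGIBLE, CHANNEL_IN_APP, cap=1, anchor="screening_fail",
                    description="Ineligibility notice with a link to an alternative food-scanner app"),
        MessageRule(RULE_REGISTRATION, CHANNEL_PUSH, cap=len(reg_offsets),
                    offsets=reg_offsets, anchor="consent",
                    description="Reminder to complete registration or the baseline questionnaire"),
        MessageRule(RULE_RUNIN_UNDER, CHANNEL_IN_APP, cap=_UNCAPPED, anchor="list_submitted",
                    description="Reminder to record at least the run-in minimum during week 1"),
        MessageRule(RULE_LIST_SENT, CHANNEL_IN_APP, cap=_UNCAPPED, anchor="list_submitted",
                    description="Confirmation that the product list was transmitted"),
        MessageRule(RULE_BASELINE_RECORDING, CHANNEL_PUSH, cap=2, offsets=[2, 4],
                    anchor="baseline_start",
                    description="Recording reminder on days 3 and 5 of week 1 if no list sent"),
        MessageRule(RULE_INTERVENTION_RECORDING, CHANNEL_PUSH, cap=_UNCAPPED,
                    offsets=[4, 6, 9, 12, 18, 24], anchor="last_list_or_intervention_start",
                    description="Keep-recording reminder during the intervention phase"),
        MessageRule(RULE_ENDING_SOON, CHANNEL_PUSH, cap=1, offsets=[25],
                    anchor="intervention_start",
                    description="Trial ending soon (day 26 of the intervention phase)"),
        MessageRule(RULE_FOLLOWUP_REQUEST, CHANNEL_IN_APP, cap=1, offsets=[27],
                    anchor="intervention_start",
                    description="Follow-up questionnaire request (day 28 of the intervention phase)"),
        MessageRule(RULE_FOLLOWUP_REMINDER, CHANNEL_PUSH, cap=5,
                    offsets=[6, 12, 18, 24, 30], anchor="intervention_end",
                    description="Follow-up reminder while the questionnaire is outstanding"),
        MessageRule(RULE_COMPLETED, CHANNEL_IN_APP, cap=1, anchor="followup_completed",
                    description="Trial completion notice with the alternative-app link"),
    ]


def rules_to_json(rules: list[MessageRule]) -> str:
    return json.dumps([r.to_dict() for r in rules], indent=2)


def rules_from_json(text: str) -> list[MessageRule]:
    return [MessageRule(**d) for d in json.loads(text)]


@dataclass
class NotificationRecord:
    rule_id: str
    participant_id: str
    due_day: int
    channel: str
    sent: bool = False

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.rule_id, self.participant_id, self.due_day)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


class NotificationEngine:
    """Evaluates the rule table against participant state and the clock."""

    def __init__(self, config: TrialConfig, rules: Optional[list[MessageRule]] = None):
        self.config = config
        self.rules = {r.rule_id: r for r in (rules if rules is not None else default_rules(config))}
        self.records: dict[tuple[str, str, int], NotificationRecord] = {}
        self._fired: Counter = Counter()  # (rule_id, participant_id) -> times created

    # -- record bookkeeping -------------------------------------------------

    def _emit(self, rule_id: str, participant_id: str, due_day: int) -> Optional[NotificationRecord]:
        rule = self.rules[rule_id]
        key = (rule_id, participant_id, due_day)
        if key in self.records:
            rec = self.records[key]
            return None if rec.sent else rec
        if self._fired[(rule_id, participant_id)] >= rule.cap:
            return None
        rec = NotificationRecord(rule_id, participant_id, due_day, rule.channel)
        self.records[key] = rec
        self._fired[(rule_id, participant_id)] += 1
        return rec

    def mark_sent(self, record: NotificationRecord) -> None:
        """Mark delivered; idempotent, and the record never falls due again."""
        stored = self.records.get(record.key)
        if stored is not None:
            stored.sent = True
        record.sent = True

    def sent_count(self, rule_id: str, participant_id: str) -> int:
        return sum(1 for r in self.records.values()
                   if r.rule_id == rule_id and r.participant_id == participant_id and r.sent)

    # -- event-driven rules -------------------------------------------------

    def on_screening_failed(self, participant: "Participant", clock: int) -> Optional[NotificationRecord]:
        """Once only: ineligibility notice after a failed first check."""
        return self._emit(RULE_INELIGIBLE, participant.id, clock)

    def on_list_submitted(self, participant: "Participant", clock: int,
                          week1_total: int) -> Optional[NotificationRecord]:
        """Item-count feedback after every transmitted list.

        During week 1 with the running total below the run-in minimum,
        a keep-going reminder; once the total reaches the minimum (any
        phase), the transmission-success notice.
        """
        threshold = self.config.run_in_min_items
        in_week1 = (participant.registration_day is not None
                    and 0 <= clock - participant.registration_day < self.config.baseline_days)
        if in_week1 and week1_total < threshold:
            return self._emit(RULE_RUNIN_UNDER, participant.id, clock)
        return self._emit(RULE_LIST_SENT, participant.id, clock)

    def on_followup_completed(self, participant: "Participant", clock: int) -> Optional[NotificationRecord]:
        """Once only: completion notice after the follow-up questionnaire."""
        return self._emit(RULE_COMPLETED, participant.id, clock)

    # -- time-driven rules --------------------------------------------------

    def due_messages(self, participant: "Participant", clock: int,
                     last_list_day: Optional[int] = None) -> list[NotificationRecord]:
        """Unsent records falling due exactly at ``clock``.

        Re-evaluating at the same clock before marking returns the same
        set; after marking, the set is empty. ``last_list_day`` is the
        day the participant's most recent list was transmitted.
        """
        from .trial import State  # local import to avoid a cycle

        due: list[NotificationRecord] = []

        def _try(rule_id: str) -> None:
            rec = self._emit(rule_id, participant.id, clock)
            if rec is not None:
                due.append(rec)

        # Registration / baseline-questionnaire reminder cascade
        # (REGISTERED means the baseline questionnaire is still pending).
        if (participant.state in (State.CONSENTED, State.SCREENED_ELIGIBLE, State.REGISTERED)
                and participant.consent_day is not None):
            rule = self.rules[RULE_REGISTRATION]
            if clock - participant.consent_day in rule.offsets:
                _try(RULE_REGISTRATION)

        # Baseline recording reminder: no list since the start of week 1.
        if participant.state is State.BASELINE and participant.baseline_day is not None:
            no_lists = last_list_day is None or last_list_day < participant.baseline_day
            if no_lists and clock - participant.baseline_day in self.rules[RULE_BASELINE_RECORDING].offsets:
                _try(RULE_BASELINE_RECORDING)

        if participant.state is State.INTERVENTION and participant.intervention_start_day is not None:
            start = participant.intervention_start_day
            end = participant.intervention_end_day or (start + self.config.intervention_days)
            # Keep-recording reminder, anchored to the later of the last
            # transmitted list and the intervention start.
            anchor = start if last_list_day is None else max(last_list_day, start)
            if clock < end and clock - anchor in self.rules[RULE_INTERVENTION_RECORDING].offsets:
                _try(RULE_INTERVENTION_RECORDING)
            if clock - start in self.rules[RULE_ENDING_SOON].offsets:
                _try(RULE_ENDING_SOON)
            if clock - start in self.rules[RULE_FOLLOWUP_REQUEST].offsets:
                _try(RULE_FOLLOWUP_REQUEST)

        # Follow-up reminders halt permanently once the questionnaire is in.
        if participant.state is State.FOLLOW_UP_DUE and participant.intervention_end_day is not None:
            if clock - participant.intervention_end_day in self.rules[RULE_FOLLOWUP_REMINDER].offsets:
                _try(RULE_FOLLOWUP_REMINDER)

        return due
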