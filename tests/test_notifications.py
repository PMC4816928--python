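"""Notification rule engine checked against hand-coded per-rule oracles.

Each oracle computes, directly from a scripted participant history, the
set of days a rule should fire on a 70-day grid; the engine's emitted
records must match exactly.
"""

import pytest

from smartrct import State, TrialEngine
from smartrct.notifications import (
    RULE_BASELINE_RECORDING,
    RULE_COMPLETED,
    RULE_ENDING_SOON,
    RULE_FOLLOWUP_REMINDER,
    RULE_FOLLOWUP_REQUEST,
    RULE_INELIGIBLE,
    RULE_INTERVENTION_RECORDING,
    RULE_LIST_SENT,
    RULE_REGISTRATION,
    RULE_RUNIN_UNDER,
    default_rules,
    registration_offsets,
    rules_from_json,
    rules_to_json,
)

from conftest import enroll, record_items

GRID_DAYS = 70


def replay(engine, pid="P1", *, enroll_day=None, list_days=None, items_per_list=20,
           followup_day=None, days=GRID_DAYS):
    """Drive one scripted participant and collect sent messages per rule."""
    list_days = dict(list_days or {})
    if enroll_day is not None:
        enroll(engine, pid, day=enroll_day)
    for day in range(days + 1):
        if day > 0:
            engine.advance_to(pid, day)
        if day in list_days:
            record_items(engine, pid, list_days[day])
        if followup_day == day and engine.participants[pid].state is State.FOLLOW_UP_DUE:
            engine.complete_followup(pid, {"a": 1}, day=day)
        engine.deliver_due_messages(pid)
    sent: dict[str, list[int]] = {}
    for e in engine.events:
        if e["event"] == "notification_sent" and e["participant_id"] == pid:
            sent.setdefault(e["rule"], []).append(e["day"])
    return sent


def sent_days(engine, pid, rule_id):
    return [e["day"] for e in engine.events
            if e["event"] == "notification_sent" and e["rule"] == rule_id
            and e["participant_id"] == pid]


@pytest.fixture
def engine(nz_config, db):
    return TrialEngine(nz_config, db, seed=3)


class TestEventDrivenRules:
    def test_ineligibility_message_fires_exactly_once(self, engine):
        engine.add_participant("P1")
        engine.consent("P1", True, True)
        crit = engine.config.screening.required_true
        engine.screen("P1", {k: False for k in crit})
        engine.screen("P1", {k: False for k in crit})  # duplicate submission
        assert sent_days(engine, "P1", RULE_INELIGIBLE) == [0]

    def test_list_feedback_under_then_over_threshold(self, engine):
        enroll(engine, "P1")
        record_items(engine, "P1", 10, day=1)    # week 1, running total 10
        record_items(engine, "P1", 4, day=2)     # still under 15
        record_items(engine, "P1", 5, day=3)     # total 19 -> success notice
        assert sent_days(engine, "P1", RULE_RUNIN_UNDER) == [1, 2]
        assert sent_days(engine, "P1", RULE_LIST_SENT) == [3]

    def test_any_list_after_week_one_gets_success_message(self, engine):
        enroll(engine, "P1")
        record_items(engine, "P1", 20, day=2)
        record_items(engine, "P1", 3, day=20)    # intervention phase, small list
        assert 20 in sent_days(engine, "P1", RULE_LIST_SENT)

    def test_completion_notice_once(self, engine):
        enroll(engine, "P1")
        record_items(engine, "P1", 20, day=2)
        engine.advance_to("P1", 35)
        engine.complete_followup("P1", {"a": 1})
        engine.complete_followup("P1", {"a": 2})
        assert sent_days(engine, "P1", RULE_COMPLETED) == [35]


class TestTimeDrivenRulesAgainstOracles:
    def test_registration_reminder_cascade(self, engine):
        # Consented day 0, never registers: two days after consent, then
        # weekly four times, then every 28 days.
        engine.add_participant("P1")
        engine.consent("P1", True, True, day=0)
        sent = replay(engine, days=GRID_DAYS)
        oracle = [o for o in registration_offsets(engine.config.recruitment_window_days)
                  if o <= GRID_DAYS]
        assert sent.get(RULE_REGISTRATION, []) == oracle
        assert oracle[:5] == [2, 9, 16, 23, 30] and oracle[5] == 58

    def test_baseline_reminder_days_3_and_5_when_no_lists(self, engine):
        sent = replay(engine, enroll_day=0)
        # Day 3 and day 5 of week 1, 1-based within the phase.
        assert sent.get(RULE_BASELINE_RECORDING, [])[:2] == [2, 4]

    def test_baseline_reminder_suppressed_after_a_list(self, engine):
        sent = replay(engine, enroll_day=0, list_days={1: 20})
        assert RULE_BASELINE_RECORDING not in sent

    def test_no_rule_due_on_quiet_day_two_of_week_one(self, engine):
        enroll(engine, "P1", day=0)
        engine.advance_to("P1", 1)   # day 2 of week 1
        assert engine.deliver_due_messages("P1") == []

    def test_intervention_reminders_anchor_on_intervention_start(self, engine):
        # One qualifying list in week 1, silence afterwards. Intervention
        # starts day 7; reminders at 4, 6, 9, 12, 18, 24 days after.
        sent = replay(engine, enroll_day=0, list_days={2: 20})
        assert sent.get(RULE_INTERVENTION_RECORDING, []) == [11, 13, 16, 19, 25, 31]

    def test_intervention_reminders_reset_on_new_list(self, engine):
        # Lists on days 2 (week 1) and 20: the anchor moves to day 20.
        sent = replay(engine, enroll_day=0, list_days={2: 20, 20: 5})
        expected = [11, 13, 16, 19] + [20 + o for o in (4, 6, 9, 12)
                                       if 20 + o < 35]
        assert sent.get(RULE_INTERVENTION_RECORDING, []) == expected

    def test_ending_soon_and_followup_request_days(self, engine):
        sent = replay(engine, enroll_day=0, list_days={2: 20})
        # Days 26 and 28 of the intervention phase that starts on day 7.
        assert sent.get(RULE_ENDING_SOON, []) == [7 + 25]
        assert sent.get(RULE_FOLLOWUP_REQUEST, []) == [7 + 27]

    def test_followup_reminders_until_completion(self, engine):
        # Intervention ends day 35; reminders at +6, +12, ... while the
        # questionnaire is outstanding, halting permanently at completion.
        sent = replay(engine, enroll_day=0, list_days={2: 20}, followup_day=50)
        assert sent.get(RULE_FOLLOWUP_REMINDER, []) == [41, 47]
        assert sent.get(RULE_COMPLETED, []) == [50]

    def test_followup_reminder_capped_at_five(self, engine):
        sent = replay(engine, enroll_day=0, list_days={2: 20})
        assert sent.get(RULE_FOLLOWUP_REMINDER, []) == [41, 47, 53, 59, 65]


class TestEngineMechanics:
    def test_due_set_stable_before_marking_empty_after(self, engine):
        enroll(engine, "P1", day=0)
        engine.advance_to("P1", 2)
        p = engine.participants["P1"]
        first = engine.notifications.due_messages(p, 2)
        again = engine.notifications.due_messages(p, 2)
        assert [r.key for r in first] == [r.key for r in again] and first
        for rec in first:
            engine.notifications.mark_sent(rec)
        assert engine.notifications.due_messages(p, 2) == []

    def test_mark_sent_idempotent(self, engine):
        enroll(engine, "P1", day=0)
        engine.advance_to("P1", 2)
        p = engine.participants["P1"]
        rec = engine.notifications.due_messages(p, 2)[0]
        engine.notifications.mark_sent(rec)
        engine.notifications.mark_sent(rec)
        assert engine.notifications.sent_count(rec.rule_id, "P1") == 1

    def test_caps_never_exceeded_on_full_replay(self, engine):
        replay(engine, enroll_day=0, list_days={2: 20})
        rules = engine.notifications.rules
        for (rule_id, pid), _ in engine.notifications._fired.items():
            assert engine.notifications.sent_count(rule_id, pid) <= rules[rule_id].cap

    def test_rule_table_round_trip_behaviorally_identical(self, nz_config, db):
        rules = default_rules(nz_config)
        reloaded = rules_from_json(rules_to_json(rules))
        assert [r.to_dict() for r in reloaded] == [r.to_dict() for r in rules]
        outs = []
        for rule_set in (rules, reloaded):
            engine = TrialEngine(nz_config, db, seed=3)
            engine.notifications.rules = {r.rule_id: r for r in rule_set}
            sent = replay(engine, enroll_day=0, list_days={2: 20, 20: 5})
            outs.append(sent)
        assert outs[0] == outs[1]
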