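"""Participant lifecycle: consent, eligibility, timeline, completion."""

import pytest

from smartrct import State, TrialEngine
from smartrct.errors import (
    DuplicateRegistrationError,
    MonotonicClockError,
    ScreeningError,
    StateError,
)

from conftest import enroll, record_items


@pytest.fixture
def engine(nz_config, db):
    return TrialEngine(nz_config, db, seed=7)


@pytest.fixture
def au_engine(au_config, db):
    return TrialEngine(au_config, db, seed=7)


class TestConsent:
    def test_both_flags_required(self, engine):
        engine.add_participant("P1")
        engine.consent("P1", True, False)
        assert engine.participants["P1"].state is State.INSTALLED
        engine.consent("P1", True, True)
        assert engine.participants["P1"].state is State.CONSENTED

    def test_repeat_consent_is_idempotent(self, engine):
        engine.add_participant("P1")
        engine.consent("P1", True, True)
        engine.consent("P1", True, True)
        assert sum(e["event"] == "consented" for e in engine.events) == 1


class TestScreening:
    def test_eligible_and_ineligible_paths(self, engine):
        crit = engine.config.screening.required_true
        for pid, passes in [("P1", True), ("P2", False)]:
            engine.add_participant(pid)
            engine.consent(pid, True, True)
            engine.screen(pid, {k: passes for k in crit})
        assert engine.participants["P1"].state is State.SCREENED_ELIGIBLE
        assert engine.participants["P2"].state is State.SCREENED_INELIGIBLE
        # One ineligibility message, delivered immediately.
        sent = [e for e in engine.events if e["event"] == "notification_sent"]
        assert len(sent) == 1 and sent[0]["participant_id"] == "P2"

    def test_incomplete_answers_raise(self, engine):
        engine.add_participant("P1")
        engine.consent("P1", True, True)
        with pytest.raises(ScreeningError):
            engine.screen("P1", {})

    def test_resubmitted_screening_rejected(self, engine):
        enroll(engine, "P1")
        crit = engine.config.screening.required_true
        engine.screen("P1", {k: False for k in crit})
        assert engine.participants["P1"].state is State.BASELINE
        assert any(e["event"] == "questionnaire_duplicate_rejected" for e in engine.events)


class TestRegistration:
    def test_duplicate_email_rejected_case_insensitively(self, engine):
        enroll(engine, "P1", email="Shopper@Example.org")
        engine.add_participant("P2")
        engine.consent("P2", True, True)
        engine.screen("P2", {k: True for k in engine.config.screening.required_true})
        with pytest.raises(DuplicateRegistrationError):
            engine.register("P2", "shopper@example.org")
        assert engine.participants["P2"].state is State.SCREENED_ELIGIBLE

    def test_retry_with_fresh_email_succeeds(self, engine):
        enroll(engine, "P1", email="a@example.org")
        engine.add_participant("P2")
        engine.consent("P2", True, True)
        engine.screen("P2", {k: True for k in engine.config.screening.required_true})
        with pytest.raises(DuplicateRegistrationError):
            engine.register("P2", "a@example.org")
        factors = {f: levels[0] for f, levels in engine.config.stratification.items()}
        engine.register("P2", "b@example.org", factors=factors)
        assert engine.participants["P2"].state is State.REGISTERED
        assert any(e["event"] == "registration_rejected" for e in engine.events)

    def test_no_raw_email_stored(self, engine):
        p = enroll(engine, "P1", email="secret@example.org")
        assert "secret" not in (p.email_fp or "")
        assert "secret" not in str(engine.events)


class TestTimeline:
    def test_compliant_trace_fires_events_in_canonical_order(self, engine):
        enroll(engine, "P1")
        record_items(engine, "P1", 20, day=2)
        for day in range(3, 50):
            engine.advance_to("P1", day)
            if engine.participants["P1"].state is State.FOLLOW_UP_DUE:
                engine.complete_followup("P1", {"a": 1})
                break
        order = [e["event"] for e in engine.events if e["participant_id"] == "P1"]
        keys = [e for e in order if e in (
            "download", "consented", "screened_eligible", "registered",
            "baseline_start", "run_in_pass", "randomized", "intervention_start",
            "followup_due", "completed")]
        assert keys == ["download", "consented", "screened_eligible", "registered",
                        "baseline_start", "run_in_pass", "randomized",
                        "intervention_start", "followup_due", "completed"]

    def test_catch_up_fires_intermediate_events_once(self, engine):
        enroll(engine, "P1")
        record_items(engine, "P1", 20, day=3)
        fired = engine.advance_to("P1", 40)
        assert fired.count("randomized") == 1
        assert fired.count("followup_due") == 1
        assert fired.index("randomized") < fired.index("followup_due")
        days = {e["event"]: e["day"] for e in engine.events}
        assert days["randomized"] == 7 and days["followup_due"] == 35

    def test_clock_cannot_move_backwards(self, engine):
        enroll(engine, "P1")
        engine.advance_to("P1", 10)
        with pytest.raises(MonotonicClockError):
            engine.advance_to("P1", 5)

    def test_followup_due_without_submission_is_not_completed(self, engine):
        enroll(engine, "P1")
        record_items(engine, "P1", 20, day=2)
        engine.advance_to("P1", 40)
        assert engine.participants["P1"].state is State.FOLLOW_UP_DUE


class TestRunIn:
    @pytest.mark.parametrize("items, randomized", [(14, False), (15, True)])
    def test_threshold_boundary_at_day_seven(self, engine, items, randomized):
        enroll(engine, "P1")
        record_items(engine, "P1", items, day=2)
        engine.advance_to("P1", 7)
        p = engine.participants["P1"]
        assert (p.state is State.INTERVENTION) == randomized
        assert (p.arm is not None) == randomized

    def test_failed_run_in_not_excluded_during_grace(self, engine):
        enroll(engine, "P1")
        record_items(engine, "P1", 10, day=2)
        engine.advance_to("P1", 13)
        assert engine.participants["P1"].state is State.BASELINE

    def test_grace_elapsed_without_items_excludes(self, engine):
        enroll(engine, "P1")
        engine.advance_to("P1", 14)
        assert engine.participants["P1"].state is State.EXCLUDED_RUN_IN

    def test_items_during_grace_rescue_randomization(self, engine):
        enroll(engine, "P1")
        record_items(engine, "P1", 10, day=2)
        record_items(engine, "P1", 10, day=9)   # grace window
        engine.advance_to("P1", 10)
        p = engine.participants["P1"]
        assert p.state is State.INTERVENTION
        assert p.items_recorded_week1 == 10     # strictly week-1 lists
        assert p.run_in_items == 20

    def test_never_randomized_below_threshold_or_before_day_seven(self, engine):
        enroll(engine, "P1")
        record_items(engine, "P1", 50, day=2)
        engine.advance_to("P1", 6)
        assert engine.participants["P1"].state is State.BASELINE
        assert engine.participants["P1"].arm is None


class TestFollowUp:
    def _to_followup(self, engine, pid="P1"):
        enroll(engine, pid)
        record_items(engine, pid, 20, day=2)
        engine.advance_to(pid, 35)
        assert engine.participants[pid].state is State.FOLLOW_UP_DUE

    def test_submission_completes(self, engine):
        self._to_followup(engine)
        engine.complete_followup("P1", {"a": 1})
        assert engine.participants["P1"].state is State.COMPLETED

    def test_duplicate_submission_collapses_to_first(self, engine):
        self._to_followup(engine)
        engine.complete_followup("P1", {"a": 1})
        engine.complete_followup("P1", {"a": 2})
        assert engine.participants["P1"].questionnaires["follow-up"].answers == {"a": 1}
        assert sum(e["event"] == "completed" for e in engine.events) == 1

    def test_submission_during_intervention_is_state_error(self, engine):
        enroll(engine, "P1")
        record_items(engine, "P1", 20, day=2)
        engine.advance_to("P1", 10)
        with pytest.raises(StateError):
            engine.complete_followup("P1", {"a": 1})


class TestProgress:
    @pytest.mark.parametrize("day, weeks", [(0, 0), (6, 0), (7, 1), (13, 1), (35, 5), (70, 5)])
    def test_completed_weeks_floor_and_cap(self, engine, day, weeks):
        enroll(engine, "P1")
        assert engine.progress("P1", clock=day) == weeks


def test_withdrawal_allowed_from_any_active_state(engine):
    enroll(engine, "P1")
    record_items(engine, "P1", 20, day=2)
    engine.advance_to("P1", 10)
    engine.withdraw("P1")
    assert engine.participants["P1"].state is State.WITHDRAWN
    # terminal: no further timeline events fire
    assert engine.advance_to("P1", 40) == []


def test_au_profile_uses_single_empty_stratum(au_engine):
    enroll(au_engine, "P1", factors={})
    record_items(au_engine, "P1", 20, day=2)
    au_engine.advance_to("P1", 7)
    p = au_engine.participants["P1"]
    assert p.stratum == ()
    assert p.arm in au_engine.config.arms
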