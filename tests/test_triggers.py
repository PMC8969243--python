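"""Windowed trigger detectors and retrospective support scoring."""

from datetime import date, datetime, time, timedelta, timezone

import numpy as np
import pytest

from headachekit.records import (
    ActivityType,
    ContextEvent,
    DailyRecord,
    EventKind,
    EventSource,
    Interaction,
    MealRecord,
    Trigger,
)
from headachekit.simulate import generate_trigger_support_scenario
from headachekit.timeline import SleepEvent
from headachekit.triggers import (
    PatientTriggerProfile,
    detect_physical_exercise,
    detect_skipped_meals,
    detect_sleep_deprivation,
    detect_stress,
    detect_stress_relief,
    retrospective_support,
    run_known_triggers,
)

UTC = timezone.utc
T = datetime(2021, 1, 10, 18, 0, tzinfo=UTC)


def activity(end_offset_min, duration_min, a_type=ActivityType.RUNNING):
    end = T - timedelta(minutes=end_offset_min)
    return ContextEvent(
        patient_id="p", kind=EventKind.ACTIVITY,
        start=end - timedelta(minutes=duration_min), end=end,
        activity_type=a_type, source=EventSource.AUTOMATIC,
        interaction=Interaction.CONFIRMED,
    )


def stress(end_offset_min, duration_min, level=2, interaction=Interaction.CONFIRMED):
    end = T - timedelta(minutes=end_offset_min)
    return ContextEvent(
        patient_id="p", kind=EventKind.STRESS,
        start=end - timedelta(minutes=duration_min), end=end,
        stress_level=level if interaction is Interaction.CONFIRMED else None,
        source=EventSource.AUTOMATIC, interaction=interaction,
    )


def night(get_up, sleep_hours, wake=()):
    bed = get_up - timedelta(hours=sleep_hours) - sum((e - s for s, e in wake), timedelta(0))
    return SleepEvent(patient_id="p", time_to_bed=bed, get_up=get_up,
                      wake_periods=tuple(wake), quality=1.0)


class TestPhysicalExercise:
    def test_running_in_window_fires(self):
        alarm = detect_physical_exercise([activity(40, 20)], T)
        assert alarm is not None and alarm.trigger is Trigger.PHYSICAL_EXERCISE
        assert len(alarm.evidence) == 1

    def test_commuting_never_counts(self):
        assert detect_physical_exercise([activity(30, 30, ActivityType.COMMUTING)], T) is None

    def test_below_minimum_duration(self):
        assert detect_physical_exercise([activity(40, 4)], T) is None

    def test_outside_window(self):
        assert detect_physical_exercise([activity(200, 20)], T) is None


class TestStress:
    def test_confirmed_event_in_long_window(self):
        alarm = detect_stress([stress(120, 30)], T)
        assert alarm is not None
        assert alarm.short_window_hit is False
        assert alarm.measure == pytest.approx(30.0)

    def test_unconfirmed_only_no_alarm(self):
        assert detect_stress([stress(120, 30, interaction=Interaction.IGNORED)], T) is None
        assert detect_stress([stress(120, 30, interaction=Interaction.REMOVED)], T) is None

    def test_level_zero_correction_no_alarm(self):
        e = stress(120, 30)
        zero = ContextEvent(
            patient_id="p", kind=EventKind.STRESS, start=e.start, end=e.end,
            stress_level=0, source=EventSource.AUTOMATIC,
            interaction=Interaction.CONFIRMED,
        )
        assert detect_stress([zero], T) is None

    def test_total_minutes_across_events(self):
        alarm = detect_stress([stress(120, 60), stress(30, 30)], T)
        assert alarm.measure == pytest.approx(90.0)
        assert alarm.short_window_hit is True


class TestStressRelief:
    def test_long_stress_ended_and_quiet(self):
        alarm = detect_stress_relief([stress(180, 120)], T)
        assert alarm is not None and alarm.measure == pytest.approx(180.0)

    def test_ongoing_stress_no_relief(self):
        ongoing = ContextEvent(
            patient_id="p", kind=EventKind.STRESS, start=T - timedelta(hours=2),
            end=T + timedelta(minutes=30), stress_level=2,
            source=EventSource.AUTOMATIC, interaction=Interaction.CONFIRMED,
        )
        assert detect_stress_relief([ongoing], T) is None

    def test_ended_too_long_ago(self):
        assert detect_stress_relief([stress(8 * 60, 120)], T) is None

    def test_short_stress_not_relief(self):
        assert detect_stress_relief([stress(180, 30)], T) is None


class TestSleepDeprivation:
    def history(self, hours_last_night):
        nights = [
            night(T.replace(hour=7) - timedelta(days=d), 8.0) for d in range(1, 6)
        ]
        if hours_last_night is not None:
            nights.append(night(T.replace(hour=7), hours_last_night))
        return nights

    def test_large_deficit_fires(self):
        alarm = detect_sleep_deprivation(self.history(5.0), T)
        assert alarm is not None
        assert alarm.measure == pytest.approx(180.0)

    def test_median_night_quiet(self):
        assert detect_sleep_deprivation(self.history(8.0), T) is None

    def test_missing_night_with_history_fires(self):
        alarm = detect_sleep_deprivation(self.history(None), T)
        assert alarm is not None and alarm.evidence == ()

    def test_no_history_not_assessable(self):
        assert detect_sleep_deprivation([], T) is None


class TestSkippedMeals:
    def record(self, lunch_taken=True):
        return DailyRecord(
            patient_id="p", day=T.date(), stress_level=3, mood=4,
            breakfast=MealRecord(True, time(8, 0)),
            lunch=MealRecord(lunch_taken, time(13, 0) if lunch_taken else None),
            dinner=MealRecord(False, None),
        )

    def test_skipped_lunch_detected_in_evening(self):
        # dinner due at 19:00 is still in the future at 18:00
        alarm = detect_skipped_meals([self.record(lunch_taken=False)], T)
        assert alarm is not None and alarm.measure == 1.0

    def test_all_due_meals_taken(self):
        assert detect_skipped_meals([self.record()], T) is None

    def test_breakfast_not_yet_due(self):
        early = T.replace(hour=7)
        rec = DailyRecord(
            patient_id="p", day=T.date(),
            breakfast=MealRecord(False, None),
            lunch=MealRecord(False, None), dinner=MealRecord(False, None),
        )
        assert detect_skipped_meals([rec], early) is None

    def test_missing_record_not_assessable(self):
        assert detect_skipped_meals([], T) is None


class TestRunKnownTriggers:
    def test_runs_only_profiled_detectors(self):
        timeline = [activity(40, 20), stress(120, 30)]
        profile = PatientTriggerProfile("p", frozenset({Trigger.PHYSICAL_EXERCISE}))
        alarms = run_known_triggers(profile, T, timeline=timeline)
        assert [a.trigger for a in alarms] == [Trigger.PHYSICAL_EXERCISE]

    def test_empty_profile_and_quiet_timeline(self):
        assert run_known_triggers(PatientTriggerProfile("p", frozenset()), T) == []
        profile = PatientTriggerProfile("p", frozenset({Trigger.STRESS}))
        assert run_known_triggers(profile, T, timeline=[]) == []

    def test_non_detectable_triggers_reported(self):
        profile = PatientTriggerProfile("p", frozenset({Trigger.ALCOHOL, Trigger.STRESS}))
        assert profile.not_detectable() == {Trigger.ALCOHOL}
        assert profile.detectable() == {Trigger.STRESS}

    def test_unknown_code_rejected(self):
        profile = PatientTriggerProfile("p", frozenset({"caffeine"}))  # type: ignore[arg-type]
        with pytest.raises(ValueError):
            run_known_triggers(profile, T)


class TestTimeTranslation:
    def test_shifting_timeline_shifts_alarms(self):
        shift = timedelta(days=13, hours=5)
        timeline = [activity(40, 20), stress(90, 45)]
        shifted = [
            ContextEvent(
                patient_id=e.patient_id, kind=e.kind, start=e.start + shift,
                end=e.end + shift, activity_type=e.activity_type,
                stress_level=e.stress_level, source=e.source,
                interaction=e.interaction,
            )
            for e in timeline
        ]
        before = detect_stress(timeline, T)
        after = detect_stress(shifted, T + shift)
        assert after.reference - before.reference == shift
        assert after.measure == before.measure
        assert after.short_window_hit == before.short_window_hit


class TestRetrospectiveSupport:
    def test_counts_supported_attacks(self):
        rng = np.random.default_rng(1)
        attacks, events = generate_trigger_support_scenario(40, 0.5, rng)
        table = retrospective_support(attacks, events)
        support = table[Trigger.PHYSICAL_EXERCISE]
        assert support.n_tagged == 40
        assert 0 <= support.n_supported <= 40
        assert support.fraction == support.n_supported / 40

    def test_no_tagged_attacks_empty_table(self, make_attack):
        assert retrospective_support([make_attack()], []) == {}
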