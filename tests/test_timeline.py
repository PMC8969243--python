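"""Event-stream algorithms: commute, grouping, stress limits, sleep."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headachekit.records import (
    ActivityType,
    ContextEvent,
    EventKind,
    EventSource,
    Interaction,
    LocationSample,
)
from headachekit.simulate import generate_activity_index_trace, generate_gps_track
from headachekit.timeline import (
    ActivityIndexSeries,
    SleepConfig,
    admit_stress_events,
    correct_commute,
    detect_sleep,
    flag_location_mismatch,
    group_sedentary,
    sleep_anomaly,
    stress_notification_due,
)

UTC = timezone.utc
T0 = datetime(2021, 1, 1, 10, 0, tzinfo=UTC)


def event(kind=EventKind.ACTIVITY, start=T0, minutes=30, **kwargs):
    kwargs.setdefault("patient_id", "p")
    if kind is EventKind.ACTIVITY:
        kwargs.setdefault("activity_type", ActivityType.SITTING)
    return ContextEvent(kind=kind, start=start, end=start + timedelta(minutes=minutes), **kwargs)


class TestCommuteCorrection:
    @pytest.mark.parametrize(
        "speed,expected",
        [(40.0, ActivityType.COMMUTING), (10.0, ActivityType.WALKING), (25.0, ActivityType.WALKING)],
    )
    def test_speed_threshold_is_strict(self, speed, expected):
        act = event(activity_type=ActivityType.WALKING, minutes=3)
        track = generate_gps_track("p", T0, timedelta(minutes=3), speed)
        assert correct_commute(act, track).activity_type is expected

    def test_too_few_samples_leaves_event_unchanged(self):
        act = event(activity_type=ActivityType.WALKING, minutes=3)
        track = generate_gps_track("p", T0, timedelta(minutes=0), 40.0)
        assert correct_commute(act, track) is act

    def test_only_activity_type_changes(self):
        act = event(activity_type=ActivityType.WALKING, minutes=3)
        track = generate_gps_track("p", T0, timedelta(minutes=3), 40.0)
        corrected = correct_commute(act, track)
        assert corrected.start == act.start and corrected.end == act.end
        assert corrected.interaction is act.interaction
        assert corrected.activity_type is ActivityType.COMMUTING


class TestSedentaryGrouping:
    def test_merges_runs_with_small_gaps(self):
        t = datetime(2021, 1, 1, 10, 0, tzinfo=UTC)
        sitting = event(start=t, minutes=20)
        standing = event(start=t + timedelta(minutes=20, seconds=30), minutes=19.5,
                         activity_type=ActivityType.STANDING)
        lying = event(start=t + timedelta(minutes=41), minutes=19,
                      activity_type=ActivityType.LYING_DOWN)
        out = group_sedentary([sitting, standing, lying])
        assert len(out) == 1
        merged = out[0]
        assert merged.activity_type is ActivityType.SEDENTARY
        assert merged.start == sitting.start and merged.end == lying.end

    def test_walking_breaks_the_run(self):
        a = event(start=T0, minutes=10)
        w = event(start=T0 + timedelta(minutes=10), minutes=10, activity_type=ActivityType.WALKING)
        b = event(start=T0 + timedelta(minutes=20), minutes=10)
        out = group_sedentary([a, w, b])
        assert len(out) == 3
        assert out[1].activity_type is ActivityType.WALKING

    def test_mixed_confirmation_not_merged(self):
        a = event(start=T0, minutes=10, interaction=Interaction.CONFIRMED)
        b = event(start=T0 + timedelta(minutes=10, seconds=10), minutes=10,
                  interaction=Interaction.IGNORED)
        assert len(group_sedentary([a, b])) == 2

    def test_idempotent_and_span_preserving(self):
        events = [
            event(start=T0 + timedelta(minutes=11 * i), minutes=10) for i in range(5)
        ] + [event(start=T0 + timedelta(minutes=60), minutes=10,
                   activity_type=ActivityType.WALKING)]
        events.sort(key=lambda e: e.start)
        once = group_sedentary(events)
        assert group_sedentary(once) == once


class TestStressAdmission:
    def stress(self, start, minutes):
        return ContextEvent(
            patient_id="p", kind=EventKind.STRESS, start=start,
            end=start + timedelta(minutes=minutes), source=EventSource.AUTOMATIC,
        )

    def test_longest_first_within_one_hour(self):
        base = T0.replace(minute=0)
        new = [
            self.stress(base + timedelta(minutes=5), 10),
            self.stress(base + timedelta(minutes=20), 8),
            self.stress(base + timedelta(minutes=40), 5),
        ]
        admitted = admit_stress_events(new)
        assert [e.duration for e in admitted] == [timedelta(minutes=10), timedelta(minutes=8)]

    def test_daily_cap_admits_ten_longest(self):
        base = T0.replace(hour=0, minute=0)
        new = [
            self.stress(base + timedelta(hours=2 * i), 30 - i) for i in range(12)
        ]
        admitted = admit_stress_events(new)
        assert len(admitted) == 10
        assert min(e.duration for e in admitted) == timedelta(minutes=30 - 9)

    def test_existing_events_count_toward_limits(self):
        base = T0.replace(minute=0)
        existing = [self.stress(base + timedelta(minutes=1), 5),
                    self.stress(base + timedelta(minutes=10), 5)]
        new = [self.stress(base + timedelta(minutes=30), 20)]
        assert admit_stress_events(new, existing) == []

    def test_empty_input(self):
        assert admit_stress_events([]) == []

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_limits_never_violated(self, data):
        minutes_in_day = 24 * 60
        offsets = data.draw(
            st.lists(st.integers(0, minutes_in_day - 1), min_size=0, max_size=60)
        )
        durations = data.draw(
            st.lists(st.integers(1, 120), min_size=len(offsets), max_size=len(offsets))
        )
        base = T0.replace(hour=0, minute=0)
        new = [
            self.stress(base + timedelta(minutes=o), d)
            for o, d in zip(offsets, durations)
        ]
        admitted = admit_stress_events(new)
        hours, days = {}, {}
        for e in admitted:
            hb = e.start.replace(minute=0, second=0, microsecond=0)
            hours[hb] = hours.get(hb, 0) + 1
            days[e.start.date()] = days.get(e.start.date(), 0) + 1
        assert all(v <= 2 for v in hours.values())
        assert all(v <= 10 for v in days.values())


class TestNotificationsAndFlags:
    def test_notification_window(self):
        e = event(kind=EventKind.STRESS, minutes=30)
        end = e.end
        assert stress_notification_due(e, end + timedelta(minutes=10))
        assert not stress_notification_due(e, end + timedelta(minutes=20))
        assert not stress_notification_due(e, end - timedelta(minutes=1))

    def test_location_mismatch_threshold(self):
        sed = event(minutes=60)
        def sample(t, lat):
            return LocationSample(patient_id="p", time=t, latitude=lat, longitude=3.7)
        # ~1 km apart in latitude
        far = [sample(sed.start, 51.0), sample(sed.end, 51.009)]
        near = [sample(sed.start, 51.0), sample(sed.end, 51.00135)]  # ~150 m
        same = [sample(sed.start, 51.0), sample(sed.end, 51.0)]
        assert flag_location_mismatch(sed, far)
        assert not flag_location_mismatch(sed, near)
        assert not flag_location_mismatch(sed, same)
        assert not flag_location_mismatch(sed, [])


class TestSleepDetection:
    def trace(self, **kwargs):
        rng = np.random.default_rng(kwargs.pop("seed", 0))
        return generate_activity_index_trace("p", T0, rng, **kwargs)

    def test_single_wake_period_quality(self):
        # 8 h in bed: 45 restful epochs, 6 above-threshold (30 min), 45 restful
        series = self.trace(in_bed=[(12, 108)], wake_excursions={0: [(57, 63)]})
        events = detect_sleep(series)
        assert len(events) == 1
        ev = events[0]
        assert ev.time_to_bed == series.time_at(12)
        assert ev.get_up == series.time_at(108)
        assert len(ev.wake_periods) == 1
        assert ev.quality == pytest.approx(1 - 0.5 / 8)

    def test_uninterrupted_night_quality_one(self):
        series = self.trace(in_bed=[(12, 108)])
        (ev,) = detect_sleep(series)
        assert ev.quality == 1.0 and ev.wake_periods == ()

    def test_long_excursion_splits_rest_periods(self):
        # two 4-h rests separated by 3 h of activity
        series = self.trace(in_bed=[(0, 48), (84, 132)])
        events = detect_sleep(series)
        assert len(events) == 2
        assert all(e.quality == 1.0 for e in events)

    def test_all_active_series_yields_nothing(self):
        series = ActivityIndexSeries(patient_id="p", start=T0, values=(50.0,) * 100)
        assert detect_sleep(series) == []

    def test_wake_periods_strictly_shorter_than_cap(self):
        series = self.trace(in_bed=[(0, 120)], wake_excursions={0: [(50, 61)]})  # 55 min
        (ev,) = detect_sleep(series)
        assert len(ev.wake_periods) == 1
        start, end = ev.wake_periods[0]
        assert end - start < timedelta(hours=1)

    def test_exactly_one_hour_excursion_terminates(self):
        series = self.trace(in_bed=[(0, 48), (60, 120)])  # 1 h active between
        assert len(detect_sleep(series)) == 2


class TestSleepAnomaly:
    def test_clear_drop_is_anomalous(self):
        assert sleep_anomaly([0.95, 0.9, 0.92], 0.5)

    def test_mean_quality_is_not(self):
        history = [0.9, 0.9, 0.9]
        assert not sleep_anomaly(history, 0.9)

    def test_zero_variance_floor(self):
        assert sleep_anomaly([0.9, 0.9, 0.9], 0.8)

    def test_insufficient_history(self):
        assert not sleep_anomaly([0.9, 0.9], 0.1)
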