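"""Windowed detection of headache triggers in contextual event streams.

Of the 29 triggers a patient can indicate for an attack, five are observable
in the collected contextual data: physical exercise, stress, relief from
stress, sleep deprivation and skipping of meals.  Each detector is a pure
function of the timeline, a reference time ``t`` and a per-patient window
configuration; it answers whether the trigger demonstrably occurred in the
window preceding ``t`` and, if so, returns a :class:`TriggerAlarm` carrying
the supporting evidence.

Detector rules (windows are defaults, personalizable per patient):

* *physical exercise* — a running or cycling activity of at least 5 min
  (commuting never counts: commuting requires no real physical exercise)
  overlapping the 3 h before ``t``;
* *stress* — at least one confirmed stress event (level >= 1) overlapping
  the 5 h before ``t``; the alarm also reports whether one falls in the last
  hour and the total confirmed-stress minutes in the long window;
* *relief from stress* — a confirmed stress period of at least 60 min ending
  within the 6 h before ``t``, with no confirmed stress since;
* *sleep deprivation* — last night's sleep shorter than the personal median
  by at least 90 min, or no sleep detected for the preceding night at all;
* *skipping of meals* — a main meal already due before ``t`` on the day of
  ``t`` marked as not taken (meal due times default to 09:00/13:00/19:00).

The stress, relief and sleep-deprivation rules are operational choices of
this package: the diary and event schema define what is observable, but no
canonical rule exists for these triggers.

``retrospective_support`` scores patient-indicated triggers against the
timeline: for each detectable trigger it counts the tagged attacks for which
the corresponding detector fires at the attack start.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple, Union

from .records import (
    EXERCISE_TYPES,
    AttackRegistration,
    ContextEvent,
    DailyRecord,
    EventKind,
    EventSource,
    Interaction,
    Trigger,
)
from .timeline import SleepEvent

__all__ = [
    "TriggerAlarm",
    "PatientTriggerProfile",
    "TriggerWindows",
    "DETECTABLE_TRIGGERS",
    "detect_physical_exercise",
    "detect_stress",
    "detect_stress_relief",
    "detect_sleep_deprivation",
    "detect_skipped_meals",
    "run_known_triggers",
    "retrospective_support",
    "TriggerSupport",
]

logger = logging.getLogger(__name__)

DETECTABLE_TRIGGERS: FrozenSet[Trigger] = frozenset(
    {
        Trigger.PHYSICAL_EXERCISE,
        Trigger.STRESS,
        Trigger.RELIEF_FROM_STRESS,
        Trigger.SLEEP_DEPRIVATION,
        Trigger.SKIPPING_OF_MEALS,
    }
)

Evidence = Union[ContextEvent, SleepEvent, DailyRecord]


@dataclass(frozen=True)
class TriggerAlarm:
    """A detected trigger occurrence preceding a reference time."""

    patient_id: str
    trigger: Trigger
    reference: datetime
    window: timedelta
    evidence: Tuple[Evidence, ...] = ()
    measure: Optional[float] = None
    short_window_hit: Optional[bool] = None


@dataclass(frozen=True)
class TriggerWindows:
    """Per-patient trigger-detection windows and thresholds."""

    exercise: timedelta = timedelta(hours=3)
    exercise_min_duration: timedelta = timedelta(minutes=5)
    stress_long: timedelta = timedelta(hours=5)
    stress_short: timedelta = timedelta(hours=1)
    relief: timedelta = timedelta(hours=6)
    relief_min_stress: timedelta = timedelta(minutes=60)
    sleep_deficit: timedelta = timedelta(minutes=90)
    night_lookback: timedelta = timedelta(hours=24)
    meal_due: Tuple[time, time, time] = (time(9, 0), time(13, 0), time(19, 0))


DEFAULT_WINDOWS = TriggerWindows()


@dataclass(frozen=True)
class PatientTriggerProfile:
    """The triggers known to affect one patient."""

    patient_id: str
    known: FrozenSet[Trigger]
    windows: TriggerWindows = DEFAULT_WINDOWS

    def detectable(self) -> FrozenSet[Trigger]:
        return self.known & DETECTABLE_TRIGGERS

    def not_detectable(self) -> FrozenSet[Trigger]:
        return self.known - DETECTABLE_TRIGGERS - {Trigger.NONE}


def _overlap(event: ContextEvent, lo: datetime, hi: datetime) -> timedelta:
    start, end = max(event.start, lo), min(event.end, hi)
    return max(end - start, timedelta(0))


def _confirmed_stress(event: ContextEvent) -> bool:
    """A stress event that counts as evidence: confirmed with level >= 1.

    Manual stress registrations count by construction; automatic ones must
    have been confirmed by the patient and carry a level of at least 1
    (level-0 corrections are semantically removals).
    """
    if event.kind is not EventKind.STRESS:
        return False
    level_ok = event.stress_level is None or event.stress_level >= 1
    if event.source is EventSource.MANUAL:
        return level_ok and event.interaction is not Interaction.REMOVED
    return event.interaction is Interaction.CONFIRMED and level_ok and (
        event.stress_level is None or event.stress_level >= 1
    )


def detect_physical_exercise(
    timeline: Sequence[ContextEvent],
    t: datetime,
    windows: TriggerWindows = DEFAULT_WINDOWS,
) -> Optional[TriggerAlarm]:
    """Alarm iff a >=5-min running or cycling activity overlaps [t - window, t]."""
    lo = t - windows.exercise
    hits = [
        e
        for e in timeline
        if e.kind is EventKind.ACTIVITY
        and e.activity_type in EXERCISE_TYPES
        and e.duration >= windows.exercise_min_duration
        and _overlap(e, lo, t) > timedelta(0)
    ]
    if not hits:
        return None
    total_min = sum(e.duration.total_seconds() for e in hits) / 60.0
    return TriggerAlarm(
        patient_id=hits[0].patient_id,
        trigger=Trigger.PHYSICAL_EXERCISE,
        reference=t,
        window=windows.exercise,
        evidence=tuple(hits),
        measure=total_min,
    )


def detect_stress(
    timeline: Sequence[ContextEvent],
    t: datetime,
    windows: TriggerWindows = DEFAULT_WINDOWS,
) -> Optional[TriggerAlarm]:
    """Alarm iff a confirmed stress event overlaps the long window before ``t``.

    The alarm's measure is the total confirmed-stress overlap with the long
    window in minutes; ``short_window_hit`` reports whether any confirmed
    stress also falls within the short window (default: the last hour).
    """
    lo = t - windows.stress_long
    hits = [
        e for e in timeline if _confirmed_stress(e) and _overlap(e, lo, t) > timedelta(0)
    ]
    if not hits:
        return None
    total = sum(_overlap(e, lo, t).total_seconds() for e in hits) / 60.0
    short_lo = t - windows.stress_short
    short_hit = any(_overlap(e, short_lo, t) > timedelta(0) for e in hits)
    return TriggerAlarm(
        patient_id=hits[0].patient_id,
        trigger=Trigger.STRESS,
        reference=t,
        window=windows.stress_long,
        evidence=tuple(hits),
        measure=total,
        short_window_hit=short_hit,
    )


def detect_stress_relief(
    timeline: Sequence[ContextEvent],
    t: datetime,
    windows: TriggerWindows = DEFAULT_WINDOWS,
) -> Optional[TriggerAlarm]:
    """Alarm iff a long confirmed stress period ended recently and none since.

    The stress period must last at least ``relief_min_stress``, end within
    ``[t - relief, t]``, and no confirmed stress may overlap ``(end, t]``.
    """
    lo = t - windows.relief
    confirmed = [e for e in timeline if _confirmed_stress(e)]
    candidates = [
        e
        for e in confirmed
        if e.duration >= windows.relief_min_stress and lo <= e.end <= t
    ]
    for e in sorted(candidates, key=lambda e: e.end, reverse=True):
        quiet = all(_overlap(other, e.end, t) == timedelta(0) for other in confirmed if other is not e)
        if quiet:
            relief_min = (t - e.end).total_seconds() / 60.0
            return TriggerAlarm(
                patient_id=e.patient_id,
                trigger=Trigger.RELIEF_FROM_STRESS,
                reference=t,
                window=windows.relief,
                evidence=(e,),
                measure=relief_min,
            )
    return None


def detect_sleep_deprivation(
    sleep_events: Sequence[SleepEvent],
    t: datetime,
    windows: TriggerWindows = DEFAULT_WINDOWS,
) -> Optional[TriggerAlarm]:
    """Alarm iff last night's sleep was much shorter than usual, or missing.

    "Last night" is the most recent sleep event ending within 24 h before
    ``t``.  The baseline is the median sleep duration over all other nights;
    a deficit of at least ``sleep_deficit`` (default 90 min) raises the
    alarm.  A present history with no sleep event for the preceding night is
    itself an alarm; with no history at all nothing can be concluded.
    """
    if not sleep_events:
        logger.debug("sleep deprivation not assessable: no sleep history")
        return None
    last_night = [e for e in sleep_events if t - windows.night_lookback <= e.get_up <= t]
    history = [e for e in sleep_events if e.get_up < t - windows.night_lookback]
    if not last_night:
        if not history:
            logger.debug("sleep deprivation not assessable: no prior nights")
            return None
        return TriggerAlarm(
            patient_id=sleep_events[0].patient_id,
            trigger=Trigger.SLEEP_DEPRIVATION,
            reference=t,
            window=windows.night_lookback,
            evidence=(),
            measure=None,
        )
    night = max(last_night, key=lambda e: e.get_up)
    baseline_pool = history if history else [e for e in sleep_events if e is not night]
    if not baseline_pool:
        logger.debug("sleep deprivation not assessable: single night only")
        return None
    baseline = statistics.median(e.sleep_duration.total_seconds() for e in baseline_pool)
    deficit = baseline - night.sleep_duration.total_seconds()
    if deficit >= windows.sleep_deficit.total_seconds():
        return TriggerAlarm(
            patient_id=night.patient_id,
            trigger=Trigger.SLEEP_DEPRIVATION,
            reference=t,
            window=windows.night_lookback,
            evidence=(night,),
            measure=deficit / 60.0,
        )
    return None


def detect_skipped_meals(
    daily_records: Sequence[DailyRecord],
    t: datetime,
    windows: TriggerWindows = DEFAULT_WINDOWS,
) -> Optional[TriggerAlarm]:
    """Alarm iff a main meal due before ``t`` on its day was not taken."""
    record = next((r for r in daily_records if r.day == t.date()), None)
    if record is None:
        logger.debug("skipped meals not assessable: no daily record for %s", t.date())
        return None
    skipped = []
    for name, due in zip(("breakfast", "lunch", "dinner"), windows.meal_due):
        meal = record.meal(name)
        if meal is None:
            continue
        if t.timetz().replace(tzinfo=None) >= due and not meal.taken:
            skipped.append(name)
    if not skipped:
        return None
    return TriggerAlarm(
        patient_id=record.patient_id,
        trigger=Trigger.SKIPPING_OF_MEALS,
        reference=t,
        window=timedelta(days=1),
        evidence=(record,),
        measure=float(len(skipped)),
    )


def run_known_triggers(
    profile: PatientTriggerProfile,
    t: datetime,
    timeline: Sequence[ContextEvent] = (),
    sleep_events: Sequence[SleepEvent] = (),
    daily_records: Sequence[DailyRecord] = (),
) -> List[TriggerAlarm]:
    """Run exactly the detectors for the patient's known, detectable triggers.

    Alarms are returned sorted by trigger kind.  Unknown codes in the profile
    raise; known but non-detectable triggers are silently not run (they are
    listed by ``profile.not_detectable()``).
    """
    for code in profile.known:
        if not isinstance(code, Trigger):
            raise ValueError(f"unknown trigger code: {code!r}")
    alarms: List[TriggerAlarm] = []
    w = profile.windows
    if Trigger.PHYSICAL_EXERCISE in profile.known:
        alarm = detect_physical_exercise(timeline, t, w)
        if alarm:
            alarms.append(alarm)
    if Trigger.STRESS in profile.known:
        alarm = detect_stress(timeline, t, w)
        if alarm:
            alarms.append(alarm)
    if Trigger.RELIEF_FROM_STRESS in profile.known:
        alarm = detect_stress_relief(timeline, t, w)
        if alarm:
            alarms.append(alarm)
    if Trigger.SLEEP_DEPRIVATION in profile.known:
        alarm = detect_sleep_deprivation(sleep_events, t, w)
        if alarm:
            alarms.append(alarm)
    if Trigger.SKIPPING_OF_MEALS in profile.known:
        alarm = detect_skipped_meals(daily_records, t, w)
        if alarm:
            alarms.append(alarm)
    return sorted(alarms, key=lambda a: a.trigger.value)


@dataclass
class TriggerSupport:
    """Per-trigger retrospective evidence counts over tagged attacks."""

    trigger: Trigger
    n_tagged: int
    n_supported: int

    @property
    def fraction(self) -> float:
        return self.n_supported / self.n_tagged if self.n_tagged else 0.0


def retrospective_support(
    attacks: Sequence[AttackRegistration],
    timeline: Sequence[ContextEvent] = (),
    sleep_events: Sequence[SleepEvent] = (),
    daily_records: Sequence[DailyRecord] = (),
    windows: TriggerWindows = DEFAULT_WINDOWS,
) -> Dict[Trigger, TriggerSupport]:
    """Score indicated, detectable triggers against the contextual timeline.

    For every detectable trigger indicated on at least one attack, counts the
    tagged attacks for which the corresponding detector fires at the attack
    start time.
    """
    detectors = {
        Trigger.PHYSICAL_EXERCISE: lambda t: detect_physical_exercise(timeline, t, windows),
        Trigger.STRESS: lambda t: detect_stress(timeline, t, windows),
        Trigger.RELIEF_FROM_STRESS: lambda t: detect_stress_relief(timeline, t, windows),
        Trigger.SLEEP_DEPRIVATION: lambda t: detect_sleep_deprivation(sleep_events, t, windows),
        Trigger.SKIPPING_OF_MEALS: lambda t: detect_skipped_meals(daily_records, t, windows),
    }
    table: Dict[Trigger, TriggerSupport] = {}
    for trigger in sorted(DETECTABLE_TRIGGERS, key=lambda x: x.value):
        tagged = [a for a in attacks if trigger in a.triggers]
        if not tagged:
            continue
        supported = sum(1 for a in tagged if detectors[trigger](a.start) is not None)
        table[trigger] = TriggerSupport(trigger=trigger, n_tagged=len(tagged), n_supported=supported)
    return table
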