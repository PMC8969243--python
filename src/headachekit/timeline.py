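"""Deterministic processing of contextual event streams.

The wearable pipeline produces automatic activity, stress and sleep events;
this module holds the deterministic post-processing rules applied to them:

* **commute correction** — an activity whose start-to-end GPS displacement
  implies a moving speed above 25 km/h is relabelled ``commuting``;
* **sedentary grouping** — consecutive sedentary-form activities (sedentary,
  sitting, standing, lying down) separated by at most 60 s and sharing a
  confirmation state are merged into one ``sedentary`` event;
* **stress-event admission** — newly detected stress periods are admitted to
  the timeline longest-first, subject to at most 2 automatic stress events
  per clock hour and 10 per calendar day;
* **stress notifications** — due while the event ended no more than 15 min ago;
* **location-mismatch flagging** — an automatic sedentary event whose start
  and end positions differ by more than a threshold (default 200 m) is
  flagged as a potential misprediction;
* **sleep detection** — from a 5-min-epoch activity-index series, candidate
  rest periods are maximal runs of below-threshold epochs in which embedded
  above-threshold runs shorter than one hour count as wake-up periods, while
  longer ones delimit time-to-bed and get-up time; a preliminary sleep
  quality (1 - wake time / in-bed time) and an anomaly flag (quality below
  the personal mean minus k standard deviations) are derived.

All functions are pure: they never mutate their inputs and return new event
objects where a field changes.
"""

from __future__ import annotations

import dataclasses
import logging
import statistics
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._geo import haversine_m
from .records import (
    SEDENTARY_TYPES,
    ActivityType,
    ContextEvent,
    EventKind,
    EventSource,
    LocationSample,
)

__all__ = [
    "correct_commute",
    "group_sedentary",
    "admit_stress_events",
    "stress_notification_due",
    "flag_location_mismatch",
    "ActivityIndexSeries",
    "SleepEvent",
    "SleepConfig",
    "detect_sleep",
    "sleep_anomaly",
    "activity_index_surrogate",
    "COMMUTE_SPEED_KMH",
]

logger = logging.getLogger(__name__)

COMMUTE_SPEED_KMH = 25.0
STRESS_NOTIFICATION_WINDOW = timedelta(minutes=15)
MAX_STRESS_PER_HOUR = 2
MAX_STRESS_PER_DAY = 10
SEDENTARY_GROUP_GAP = timedelta(seconds=60)
LOCATION_MISMATCH_THRESHOLD_M = 200.0


def correct_commute(
    activity: ContextEvent,
    locations: Sequence[LocationSample],
    speed_threshold_kmh: float = COMMUTE_SPEED_KMH,
) -> ContextEvent:
    """Relabel an activity as commuting if the implied speed exceeds 25 km/h.

    The moving speed is the great-circle distance between the first and last
    GPS sample inside ``[start, end]`` divided by the time between those
    samples.  The threshold is strict ("higher than"); with fewer than two
    samples in the interval the event is returned unchanged.
    """
    if activity.kind is not EventKind.ACTIVITY:
        raise ValueError("correct_commute expects an activity event")
    inside = sorted(
        (s for s in locations if activity.start <= s.time <= activity.end),
        key=lambda s: s.time,
    )
    if len(inside) < 2:
        logger.debug("commute correction skipped: <2 location samples in interval")
        return activity
    first, last = inside[0], inside[-1]
    elapsed_h = (last.time - first.time).total_seconds() / 3600.0
    if elapsed_h <= 0:
        return activity
    dist_km = haversine_m(first.latitude, first.longitude, last.latitude, last.longitude) / 1000.0
    if dist_km / elapsed_h > speed_threshold_kmh:
        return dataclasses.replace(activity, activity_type=ActivityType.COMMUTING)
    return activity


def _is_sedentary(event: ContextEvent) -> bool:
    return event.kind is EventKind.ACTIVITY and event.activity_type in SEDENTARY_TYPES


def group_sedentary(
    events: Sequence[ContextEvent],
    max_gap: timedelta = SEDENTARY_GROUP_GAP,
) -> List[ContextEvent]:
    """Merge runs of sedentary-form activities into single ``sedentary`` events.

    Events must be time-sorted.  A run extends while the next event is also
    sedentary-form, starts at most ``max_gap`` after the previous one ends,
    and has the same confirmation state.  Non-sedentary events pass through
    unchanged and always break a run.  Idempotent.
    """
    out: List[ContextEvent] = []
    run: List[ContextEvent] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1 and run[0].activity_type is ActivityType.SEDENTARY:
            out.append(run[0])
        else:
            out.append(
                dataclasses.replace(
                    run[0],
                    activity_type=ActivityType.SEDENTARY,
                    end=run[-1].end,
                    flagged=any(e.flagged for e in run),
                )
            )
        run.clear()

    for event in events:
        if not _is_sedentary(event):
            flush()
            out.append(event)
            continue
        if run and (
            event.start - run[-1].end > max_gap
            or event.is_confirmed != run[0].is_confirmed
            or event.patient_id != run[0].patient_id
        ):
            flush()
        run.append(event)
    flush()
    return out


def _hour_bucket(t: datetime) -> datetime:
    return t.replace(minute=0, second=0, microsecond=0)


def admit_stress_events(
    new_periods: Sequence[ContextEvent],
    existing: Sequence[ContextEvent] = (),
    max_per_hour: int = MAX_STRESS_PER_HOUR,
    max_per_day: int = MAX_STRESS_PER_DAY,
) -> List[ContextEvent]:
    """Select which newly detected stress periods enter the timeline.

    Periods from one detection run are processed longest-first (ties broken
    by earlier start, then end).  A period is admitted iff, counting existing
    automatic stress events and previously admitted ones, its start's clock
    hour holds fewer than ``max_per_hour`` and its start's calendar day fewer
    than ``max_per_day`` events.
    """
    for e in new_periods:
        if e.kind is not EventKind.STRESS:
            raise ValueError("admit_stress_events expects stress events")
    hour_counts: dict = {}
    day_counts: dict = {}
    for e in existing:
        if e.kind is EventKind.STRESS and e.source is EventSource.AUTOMATIC:
            hb, db = _hour_bucket(e.start), e.start.date()
            hour_counts[hb] = hour_counts.get(hb, 0) + 1
            day_counts[db] = day_counts.get(db, 0) + 1
    admitted: List[ContextEvent] = []
    ordered = sorted(new_periods, key=lambda e: (-e.duration.total_seconds(), e.start, e.end))
    for e in ordered:
        hb, db = _hour_bucket(e.start), e.start.date()
        if hour_counts.get(hb, 0) < max_per_hour and day_counts.get(db, 0) < max_per_day:
            admitted.append(e)
            hour_counts[hb] = hour_counts.get(hb, 0) + 1
            day_counts[db] = day_counts.get(db, 0) + 1
    return admitted


def stress_notification_due(
    event: ContextEvent,
    now: datetime,
    window: timedelta = STRESS_NOTIFICATION_WINDOW,
) -> bool:
    """True iff the stress event ended no longer than ``window`` ago (and not in the future)."""
    if event.kind is not EventKind.STRESS:
        raise ValueError("stress_notification_due expects a stress event")
    elapsed = now - event.end
    return timedelta(0) <= elapsed <= window


def flag_location_mismatch(
    event: ContextEvent,
    locations: Sequence[LocationSample],
    threshold_m: float = LOCATION_MISMATCH_THRESHOLD_M,
) -> bool:
    """Whether start and end positions of a sedentary event differ significantly.

    Compares the GPS sample nearest the event start with the one nearest the
    event end; returns True iff their great-circle distance exceeds the
    threshold.  Without any samples the event cannot be assessed (False).
    """
    if not _is_sedentary(event):
        raise ValueError("flag_location_mismatch expects a sedentary-form activity event")
    if not locations:
        logger.debug("location-mismatch check skipped: no samples")
        return False
    near_start = min(locations, key=lambda s: abs((s.time - event.start).total_seconds()))
    near_end = min(locations, key=lambda s: abs((s.time - event.end).total_seconds()))
    dist = haversine_m(
        near_start.latitude, near_start.longitude, near_end.latitude, near_end.longitude
    )
    return dist > threshold_m


# ---------------------------------------------------------------------------
# Sleep detection from an activity-index series


@dataclass(frozen=True)
class ActivityIndexSeries:
    """Equally spaced, non-negative activity-index values (5-min epochs by default)."""

    patient_id: str
    start: datetime
    values: Tuple[float, ...]
    epoch: timedelta = timedelta(minutes=5)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if any(v < 0 for v in self.values):
            raise ValueError("activity-index values must be non-negative")
        if self.epoch <= timedelta(0):
            raise ValueError("epoch length must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def time_at(self, i: int) -> datetime:
        """Start timestamp of epoch ``i``."""
        return self.start + i * self.epoch

    @classmethod
    def from_samples(
        cls, patient_id: str, timestamps: Sequence[datetime], values: Sequence[float]
    ) -> "ActivityIndexSeries":
        if len(timestamps) != len(values) or len(timestamps) < 2:
            raise ValueError("need >= 2 matching timestamps and values")
        gaps = {timestamps[i + 1] - timestamps[i] for i in range(len(timestamps) - 1)}
        if len(gaps) != 1 or min(gaps) <= timedelta(0):
            raise ValueError("timestamps must be strictly increasing and equally spaced")
        return cls(patient_id=patient_id, start=timestamps[0], values=tuple(values), epoch=gaps.pop())


@dataclass(frozen=True)
class SleepEvent:
    """One detected rest period with embedded wake-up periods."""

    patient_id: str
    time_to_bed: datetime
    get_up: datetime
    wake_periods: Tuple[Tuple[datetime, datetime], ...]
    quality: float
    anomaly: bool = False

    @property
    def in_bed(self) -> timedelta:
        return self.get_up - self.time_to_bed

    @property
    def sleep_duration(self) -> timedelta:
        wake = sum((e - s for s, e in self.wake_periods), timedelta(0))
        return self.in_bed - wake


@dataclass(frozen=True)
class SleepConfig:
    """Thresholds for activity-index sleep detection.

    ``threshold`` separates restful from active epochs; ``max_wake`` is the
    strict upper bound on an embedded above-threshold run still counted as a
    wake-up period; ``min_rest`` is the minimum span of a candidate rest
    period; ``anomaly_k`` and ``anomaly_sd_floor`` parameterize the
    low-quality anomaly rule.
    """

    threshold: float = 10.0
    max_wake: timedelta = timedelta(hours=1)
    min_rest: timedelta = timedelta(hours=3)
    anomaly_k: float = 2.0
    anomaly_sd_floor: float = 0.01


def detect_sleep(series: ActivityIndexSeries, config: SleepConfig = SleepConfig()) -> List[SleepEvent]:
    """Detect rest periods and wake-up periods in an activity-index series.

    A candidate rest period is a maximal run of below-threshold epochs that
    may embed above-threshold runs strictly shorter than ``config.max_wake``
    (reported as wake-up periods); a longer above-threshold run terminates
    the period.  Periods spanning less than ``config.min_rest`` are dropped.
    """
    below = [v <= config.threshold for v in series.values]
    n = len(below)
    max_wake_epochs = int(config.max_wake / series.epoch)
    events: List[SleepEvent] = []
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        # start of candidate rest period
        start_idx = i
        last_below = i
        wake_runs: List[Tuple[int, int]] = []
        j = i + 1
        while j < n:
            if below[j]:
                last_below = j
                j += 1
                continue
            # above-threshold run starting at j
            k = j
            while k < n and not below[k]:
                k += 1
            run_len = k - j
            if k < n and run_len < max_wake_epochs:
                wake_runs.append((j, k))  # embedded: strictly < 1 h and more rest follows
                j = k
            else:
                break
        events_span = series.time_at(last_below + 1) - series.time_at(start_idx)
        if events_span >= config.min_rest:
            time_to_bed = series.time_at(start_idx)
            get_up = series.time_at(last_below + 1)
            wake_periods = tuple(
                (series.time_at(s), series.time_at(e)) for s, e in wake_runs
            )
            wake_time = sum((e - s for s, e in wake_periods), timedelta(0))
            in_bed = get_up - time_to_bed
            quality = 1.0 - wake_time / in_bed if in_bed > timedelta(0) else 0.0
            events.append(
                SleepEvent(
                    patient_id=series.patient_id,
                    time_to_bed=time_to_bed,
                    get_up=get_up,
                    wake_periods=wake_periods,
                    quality=quality,
                )
            )
        i = last_below + 1
        while i < n and not below[i]:
            i += 1
    return events


def sleep_anomaly(
    history: Sequence[float],
    current: float,
    k: float = 2.0,
    sd_floor: float = 0.01,
) -> bool:
    """Whether the current sleep quality is significantly lower than normal.

    True iff ``current < mean(history) - k * sd(history)`` with the standard
    deviation floored at ``sd_floor``.  Needs at least three historical
    qualities; with fewer the night is not assessable (False).
    """
    if len(history) < 3:
        logger.debug("sleep anomaly not assessable: %d historical nights", len(history))
        return False
    mean = statistics.fmean(history)
    sd = max(statistics.pstdev(history), sd_floor)
    return current < mean - k * sd


def activity_index_surrogate(
    acceleration_magnitude: Sequence[float],
    samples_per_epoch: int,
) -> List[float]:
    """Epoch-wise surrogate activity index from an acceleration-magnitude trace.

    Computes the mean absolute deviation of the magnitude within each epoch —
    a simple movement-intensity summary with the same shape as an actigraphy
    activity index, sufficient to exercise the sleep-detection rules on
    synthetic data.
    """
    x = np.asarray(acceleration_magnitude, dtype=float)
    n_epochs = len(x) // samples_per_epoch
    out = []
    for i in range(n_epochs):
        seg = x[i * samples_per_epoch : (i + 1) * samples_per_epoch]
        out.append(float(np.mean(np.abs(seg - seg.mean()))))
    return out
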