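"""Domain types for electronic headache-diary data.

The record types mirror the registration schema of a mobile headache diary
coupled to a wrist-worn wearable: self-reported headache attacks (times, pain
intensity on a 0-4 Likert scale, pain zones on a 20-zone head manikin, a
unilaterality flag, associated symptoms, suspected triggers, acute-treatment
outcome), contextual timeline events (activities, stress periods, sleep,
medicine intakes, menstrual periods) that are either entered manually or
produced automatically by detection algorithms, GPS location samples, and
once-a-day self reports (general stress, mood, meals).

Two diary versions exist.  Under ``AppVersion.V1`` the symptom and trigger
lists may simply be left empty, and every unselected option is interpreted as
absent.  Under ``AppVersion.V2`` the user must select at least one option or
the explicit "none of those" sentinel, so absence is always explicit; the
sentinel and the empty set evaluate identically in every criterion predicate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import FrozenSet, Optional, Sequence, Tuple

__all__ = [
    "AppVersion",
    "Intensity",
    "HeadRegion",
    "Side",
    "Location",
    "Symptom",
    "Trigger",
    "Treatment",
    "EventKind",
    "ActivityType",
    "EventSource",
    "Interaction",
    "AttackRegistration",
    "ContextEvent",
    "LocationSample",
    "DailyRecord",
    "MealRecord",
    "attack_duration",
    "symptom_present",
    "CAS_SYMPTOMS",
    "SEDENTARY_TYPES",
    "EXERCISE_TYPES",
]


class AppVersion(enum.Enum):
    V1 = "v1"
    V2 = "v2"


class Intensity(enum.IntEnum):
    """Five-point pain intensity scale."""

    NO_PAIN = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    VERY_SEVERE = 4


class HeadRegion(enum.Enum):
    CERVICAL = "cervical"
    FRONTAL = "frontal"
    MANDIBULAR = "mandibular"
    MAXILLAR = "maxillar"
    OCCIPITAL = "occipital"
    ORBITAL = "orbital"
    PARIETAL = "parietal"
    TEMPORAL = "temporal"


class Side(enum.Enum):
    LEFT = "left"
    MID = "mid"
    RIGHT = "right"


# The 20 selectable pain zones of the head manikin (region x side).
_ZONE_SIDES = {
    HeadRegion.CERVICAL: (Side.LEFT, Side.MID, Side.RIGHT),
    HeadRegion.FRONTAL: (Side.LEFT, Side.MID, Side.RIGHT),
    HeadRegion.MANDIBULAR: (Side.LEFT, Side.RIGHT),
    HeadRegion.MAXILLAR: (Side.LEFT, Side.RIGHT),
    HeadRegion.OCCIPITAL: (Side.LEFT, Side.MID, Side.RIGHT),
    HeadRegion.ORBITAL: (Side.LEFT, Side.RIGHT),
    HeadRegion.PARIETAL: (Side.LEFT, Side.MID, Side.RIGHT),
    HeadRegion.TEMPORAL: (Side.LEFT, Side.RIGHT),
}


@dataclass(frozen=True)
class Location:
    """One pain zone: an anatomical region plus a side."""

    region: HeadRegion
    side: Side

    def __post_init__(self) -> None:
        if self.side not in _ZONE_SIDES[self.region]:
            raise ValueError(f"no such zone: {self.region.value}-{self.side.value}")

    @property
    def code(self) -> str:
        return f"{self.region.value}-{self.side.value}"

    @classmethod
    def from_code(cls, code: str) -> "Location":
        try:
            region, side = code.rsplit("-", 1)
            return cls(HeadRegion(region), Side(side))
        except ValueError as exc:
            raise ValueError(f"unknown location code: {code!r}") from exc


ALL_LOCATIONS: Tuple[Location, ...] = tuple(
    Location(region, side) for region, sides in _ZONE_SIDES.items() for side in sides
)
assert len(ALL_LOCATIONS) == 20


class Symptom(enum.Enum):
    """Selectable headache-associated symptoms.

    Movement sensitivity and pain increment during routine physical activity
    are separate selectable codes; both proxy the "aggravation by or causing
    avoidance of routine physical activity" characteristic.  ``NONE`` is the
    explicit "none of those" sentinel and must be the sole member of a
    symptom set.
    """

    CONJUNCTIVAL_INJECTION = "conjunctival injection"
    LACRIMATION = "lacrimation"
    PTOSIS = "ptosis"
    MIOSIS = "miosis"
    EYELID_OEDEMA = "eyelid oedema"
    NASAL_CONGESTION = "nasal congestion"
    RHINORRHOEA = "rhinorrhoea"
    SWEATY_FOREHEAD_FACE = "sweaty forehead and face"
    PULSATING_PAIN = "pulsating pain"
    MOVEMENT_SENSITIVITY = "movement sensitivity"
    PAIN_INCREMENT_PHYSICAL_ACTIVITY = "pain increment during routine physical activity"
    RESTLESSNESS_AGITATION = "restlessness or agitation"
    PHOTOPHOBIA = "photophobia"
    PHONOPHOBIA = "phonophobia"
    OSMOPHOBIA = "osmophobia"
    NAUSEA = "nausea"
    VOMITING = "vomiting"
    NONE = "none of those"


#: Cranial autonomic symptoms (for the cluster-headache symptom criterion).
CAS_SYMPTOMS: FrozenSet[Symptom] = frozenset(
    {
        Symptom.CONJUNCTIVAL_INJECTION,
        Symptom.LACRIMATION,
        Symptom.NASAL_CONGESTION,
        Symptom.RHINORRHOEA,
        Symptom.EYELID_OEDEMA,
        Symptom.SWEATY_FOREHEAD_FACE,
        Symptom.MIOSIS,
        Symptom.PTOSIS,
    }
)


class Trigger(enum.Enum):
    """The 29 selectable suspected triggers, plus the explicit sentinel."""

    ALCOHOL = "alcohol"
    ATMOSPHERIC_PRESSURE = "atmospheric pressure difference"
    BRIGHT_LIGHT = "bright light"
    CAFFEINE = "caffeine"
    CHANGE_IN_WEATHER = "change in weather"
    COLD = "cold"
    COUGHING = "coughing"
    DECREASED_WATER_INTAKE = "decreased water intake"
    FLICKERING_LIGHT = "flickering light"
    HEAT = "heat"
    HEIGHT = "height"
    HOLIDAY = "holiday"
    ILLNESSES = "illnesses"
    LOUD_SOUNDS = "loud sounds"
    MEDICATION = "medication"
    MENSTRUAL_CYCLE = "menstrual cycle"
    PHYSICAL_EXERCISE = "physical exercise"
    PRESSING = "pressing"
    RELIEF_FROM_STRESS = "relieve from stress"
    RESOLVENTS = "resolvents"
    SEXUAL_INTERCOURSE = "sexual intercourse"
    SKIPPING_OF_MEALS = "skipping of meals"
    SLEEP_DEPRIVATION = "sleep deprivation"
    SLEEPING_AWAY = "sleeping away"
    SMELLS_ODORS = "smells/odors"
    SNEEZING = "sneezing"
    SPECIFIC_HEAD_MOVEMENTS = "specific head movements"
    STRESS = "stress"
    TOUCH = "touch"
    NONE = "none of those"


class Treatment(enum.Enum):
    """Acute-medication outcome for one attack."""

    TREATED_SUCCESS = "treated_success"
    TREATED_FAILURE = "treated_failure"
    UNTREATED = "untreated"


class EventKind(enum.Enum):
    ACTIVITY = "activity"
    STRESS = "stress"
    SLEEP = "sleep"
    MEDICINE = "medicine"
    PERIOD = "period"


class ActivityType(enum.Enum):
    SEDENTARY = "sedentary"
    SITTING = "sitting"
    STANDING = "standing"
    LYING_DOWN = "lying_down"
    WALKING = "walking"
    RUNNING = "running"
    CYCLING = "cycling"
    COMMUTING = "commuting"
    OTHER = "other"


SEDENTARY_TYPES: FrozenSet[ActivityType] = frozenset(
    {ActivityType.SEDENTARY, ActivityType.SITTING, ActivityType.STANDING, ActivityType.LYING_DOWN}
)

#: Activity types that represent real physical exercise (commuting excluded,
#: since commuting requires no real physical exercise by definition).
EXERCISE_TYPES: FrozenSet[ActivityType] = frozenset({ActivityType.RUNNING, ActivityType.CYCLING})


class EventSource(enum.Enum):
    MANUAL = "manual"
    AUTOMATIC = "automatic"


class Interaction(enum.Enum):
    """What the user did with an automatically added timeline event."""

    IGNORED = "ignored"
    CONFIRMED = "confirmed"
    CONFIRMED_SEDENTARY_ONLY = "confirmed_sedentary_only"
    TIME_CORRECTED = "time_corrected"
    TYPE_CORRECTED = "type_corrected"
    REMOVED = "removed"


def _check_times(start: datetime, end: datetime) -> None:
    if start.tzinfo is None or end.tzinfo is None:
        raise ValueError("timestamps must be timezone-aware")
    if end < start:
        raise ValueError(f"end {end} before start {start}")


def _check_sentinel(values: frozenset, sentinel) -> None:
    if sentinel in values and len(values) > 1:
        raise ValueError("'none of those' sentinel must be the sole member of its set")


@dataclass(frozen=True)
class AttackRegistration:
    """One self-reported headache attack."""

    patient_id: str
    start: datetime
    end: datetime
    intensity: Intensity
    locations: FrozenSet[Location] = frozenset()
    unilateral: bool = False
    symptoms: FrozenSet[Symptom] = frozenset()
    triggers: FrozenSet[Trigger] = frozenset()
    treatment: Treatment = Treatment.UNTREATED
    app_version: AppVersion = AppVersion.V2

    def __post_init__(self) -> None:
        _check_times(self.start, self.end)
        object.__setattr__(self, "intensity", Intensity(self.intensity))
        object.__setattr__(self, "locations", frozenset(self.locations))
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))
        object.__setattr__(self, "triggers", frozenset(self.triggers))
        _check_sentinel(self.symptoms, Symptom.NONE)
        _check_sentinel(self.triggers, Trigger.NONE)
        if self.app_version is AppVersion.V2:
            if not self.symptoms:
                raise ValueError("v2 registrations require at least one symptom or the sentinel")
            if not self.triggers:
                raise ValueError("v2 registrations require at least one trigger or the sentinel")

    @property
    def duration(self) -> timedelta:
        return self.end - self.start


def attack_duration(a: AttackRegistration) -> float:
    """Duration of an attack in minutes (end minus start, >= 0)."""
    return a.duration.total_seconds() / 60.0


def symptom_present(a: AttackRegistration, code: Symptom) -> bool:
    """Whether a symptom was selected for the attack.

    Unselected symptoms are implicitly absent; the explicit "none of those"
    sentinel means every symptom is absent.
    """
    code = Symptom(code)
    if code is Symptom.NONE:
        raise ValueError("the sentinel is not a queryable symptom")
    return code in a.symptoms


@dataclass(frozen=True)
class ContextEvent:
    """One contextual timeline event (activity, stress, sleep, medicine, period)."""

    patient_id: str
    kind: EventKind
    start: datetime
    end: datetime
    activity_type: Optional[ActivityType] = None
    stress_level: Optional[int] = None
    source: EventSource = EventSource.AUTOMATIC
    interaction: Interaction = Interaction.IGNORED
    flagged: bool = False

    def __post_init__(self) -> None:
        _check_times(self.start, self.end)
        if self.kind is EventKind.ACTIVITY:
            if self.activity_type is None:
                raise ValueError("activity events require an activity_type")
        elif self.activity_type is not None:
            raise ValueError("activity_type is only valid for activity events")
        if self.kind is EventKind.STRESS:
            if self.stress_level is not None and self.stress_level not in (0, 1, 2):
                raise ValueError("stress_level must be 0, 1 or 2")
        elif self.stress_level is not None:
            raise ValueError("stress_level is only valid for stress events")

    @property
    def duration(self) -> timedelta:
        return self.end - self.start

    @property
    def is_confirmed(self) -> bool:
        """True if the user affirmed the event (fully or as sedentary only)."""
        if self.source is EventSource.MANUAL:
            return True
        return self.interaction in (Interaction.CONFIRMED, Interaction.CONFIRMED_SEDENTARY_ONLY)


@dataclass(frozen=True)
class LocationSample:
    """One GPS sample: position plus estimated accuracy."""

    patient_id: str
    time: datetime
    latitude: float
    longitude: float
    accuracy: float = 0.0

    def __post_init__(self) -> None:
        if self.time.tzinfo is None:
            raise ValueError("timestamps must be timezone-aware")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass(frozen=True)
class MealRecord:
    taken: bool
    at: Optional[time] = None


@dataclass(frozen=True)
class DailyRecord:
    """Once-a-day self report: stress level (1-10), mood (1-5), main meals."""

    patient_id: str
    day: date
    stress_level: Optional[int] = None
    mood: Optional[int] = None
    breakfast: Optional[MealRecord] = None
    lunch: Optional[MealRecord] = None
    dinner: Optional[MealRecord] = None

    def __post_init__(self) -> None:
        if self.stress_level is not None and not 1 <= self.stress_level <= 10:
            raise ValueError("daily stress level must be in 1..10")
        if self.mood is not None and not 1 <= self.mood <= 5:
            raise ValueError("mood must be in 1..5")

    def meal(self, name: str) -> Optional[MealRecord]:
        if name not in ("breakfast", "lunch", "dinner"):
            raise ValueError(f"unknown meal: {name}")
        return getattr(self, name)
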