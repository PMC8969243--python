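"""Seeded synthetic cohort generation.

The study's diary dataset is not public, so this module generates cohorts
with the same registration schema and phenotype-level statistical structure:
migraine-phenotype patients register relatively long attacks (hours,
log-normal) that are unilateral in roughly three quarters of cases and carry
photo-/phonophobia, nausea and pulsating pain at migraine-typical rates,
while cluster-headache-phenotype patients register short (tens of minutes),
always-unilateral orbital/temporal attacks weighted towards cranial autonomic
symptoms and restlessness.  Default parameters are centred on the second
data-collection wave of the emulated study (e.g. mean migraine duration about
6 h, mean CH duration under an hour, CH unilaterality 1.0, 21-day trials);
they are configuration, not constants, and the generator never claims to
reproduce the study's exact counts.

Besides the realistic mode, the generator can emit *criterion-complete*
attacks — constructed to provably satisfy every required classification
criterion of a chosen disorder under a chosen criteria version — and
*criterion-violating* attacks that fail exactly one named criterion.  These
are the closed-loop oracles for the classifier.

Determinism: one root seed; per-patient generators are spawned from
``numpy`` seed sequences keyed by the patient index, so extending a cohort
does not reshuffle earlier patients.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta, timezone
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .criteria import CriteriaVersion, Disorder
from .records import (
    ALL_LOCATIONS,
    ActivityType,
    AppVersion,
    AttackRegistration,
    ContextEvent,
    DailyRecord,
    EventKind,
    EventSource,
    HeadRegion,
    Intensity,
    Interaction,
    Location,
    LocationSample,
    MealRecord,
    Side,
    Symptom,
    Treatment,
    Trigger,
)
from .timeline import ActivityIndexSeries

__all__ = [
    "PhenotypeParams",
    "MIGRAINE_PARAMS",
    "CLUSTER_PARAMS",
    "CompletenessMode",
    "CohortConfig",
    "Patient",
    "Cohort",
    "generate_cohort",
    "generate_criterion_complete_attack",
    "sample_phenotype_attacks",
    "sample_random_attacks",
    "generate_gps_track",
    "generate_activity_index_trace",
    "generate_trigger_support_scenario",
]

UTC = timezone.utc
_TRIAL_START = datetime(2021, 3, 1, 0, 0, tzinfo=UTC)


@dataclass(frozen=True)
class PhenotypeParams:
    """Attack-level distribution parameters for one diagnosis group."""

    attacks_per_trial_mean: float
    attacks_per_trial_sd: float
    duration_mean_min: float
    duration_sd_min: float
    unilateral_p: float
    intensity_probs: Tuple[float, float, float, float, float]  # intensities 0..4
    symptom_probs: Mapping[Symptom, float]
    trigger_probs: Mapping[Trigger, float]
    treatment_probs: Tuple[float, float, float]  # success, failure, untreated
    cluster_zones: bool = False  # restrict zones to orbital/temporal, one side


MIGRAINE_PARAMS = PhenotypeParams(
    attacks_per_trial_mean=8.7,
    attacks_per_trial_sd=3.5,
    duration_mean_min=359.0,
    duration_sd_min=342.0,
    unilateral_p=0.73,
    intensity_probs=(0.0, 0.46, 0.33, 0.195, 0.015),
    symptom_probs={
        Symptom.CONJUNCTIVAL_INJECTION: 0.01,
        Symptom.LACRIMATION: 0.05,
        Symptom.PTOSIS: 0.09,
        Symptom.MIOSIS: 0.06,
        Symptom.EYELID_OEDEMA: 0.06,
        Symptom.NASAL_CONGESTION: 0.08,
        Symptom.RHINORRHOEA: 0.04,
        Symptom.SWEATY_FOREHEAD_FACE: 0.01,
        Symptom.PULSATING_PAIN: 0.35,
        Symptom.MOVEMENT_SENSITIVITY: 0.28,
        Symptom.PAIN_INCREMENT_PHYSICAL_ACTIVITY: 0.26,
        Symptom.RESTLESSNESS_AGITATION: 0.22,
        Symptom.PHOTOPHOBIA: 0.24,
        Symptom.PHONOPHOBIA: 0.29,
        Symptom.OSMOPHOBIA: 0.03,
        Symptom.NAUSEA: 0.23,
        Symptom.VOMITING: 0.0,
    },
    trigger_probs={
        Trigger.STRESS: 0.15,
        Trigger.SLEEP_DEPRIVATION: 0.10,
        Trigger.PHYSICAL_EXERCISE: 0.05,
        Trigger.SKIPPING_OF_MEALS: 0.05,
        Trigger.MENSTRUAL_CYCLE: 0.08,
        Trigger.RELIEF_FROM_STRESS: 0.04,
        Trigger.CHANGE_IN_WEATHER: 0.05,
        Trigger.ALCOHOL: 0.03,
    },
    treatment_probs=(0.37, 0.14, 0.49),
)

CLUSTER_PARAMS = PhenotypeParams(
    attacks_per_trial_mean=7.5,
    attacks_per_trial_sd=2.0,
    duration_mean_min=50.0,
    duration_sd_min=20.0,
    unilateral_p=1.0,
    intensity_probs=(0.0, 0.13, 0.47, 0.40, 0.0),
    symptom_probs={
        Symptom.CONJUNCTIVAL_INJECTION: 0.27,
        Symptom.LACRIMATION: 0.27,
        Symptom.NASAL_CONGESTION: 0.60,
        Symptom.RHINORRHOEA: 0.07,
        Symptom.EYELID_OEDEMA: 0.03,
        Symptom.SWEATY_FOREHEAD_FACE: 0.02,
        Symptom.PULSATING_PAIN: 0.53,
        Symptom.MOVEMENT_SENSITIVITY: 0.07,
        Symptom.PAIN_INCREMENT_PHYSICAL_ACTIVITY: 0.07,
        Symptom.RESTLESSNESS_AGITATION: 0.60,
        Symptom.PHOTOPHOBIA: 0.07,
    },
    trigger_probs={
        Trigger.ALCOHOL: 0.10,
        Trigger.STRESS: 0.08,
        Trigger.SLEEP_DEPRIVATION: 0.06,
        Trigger.PHYSICAL_EXERCISE: 0.04,
    },
    treatment_probs=(0.93, 0.07, 0.0),
    cluster_zones=True,
)


class CompletenessMode(enum.Enum):
    REALISTIC = "realistic"
    CRITERION_COMPLETE = "criterion_complete"
    CRITERION_VIOLATING = "criterion_violating"


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic cohort."""

    seed: int = 0
    n_migraine: int = 9
    n_ch: int = 2
    trial_days: int = 21
    app_version: AppVersion = AppVersion.V2
    migraine: PhenotypeParams = MIGRAINE_PARAMS
    cluster: PhenotypeParams = CLUSTER_PARAMS
    activities_per_day: float = 40.0
    stress_events_per_day: float = 6.7
    stress_confirm_p: float = 0.45
    sleep_bed_time: time = time(23, 0)
    sleep_bed_sd_min: float = 40.0
    sleep_duration_mean_min: float = 480.0
    sleep_duration_sd_min: float = 60.0
    trigger_plant_p: float = 0.5
    mode: CompletenessMode = CompletenessMode.REALISTIC
    target_version: CriteriaVersion = CriteriaVersion.V3
    violate_criterion: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_migraine < 0 or self.n_ch < 0 or self.trial_days <= 0:
            raise ValueError("counts must be non-negative and trial length positive")
        for params in (self.migraine, self.cluster):
            for p in list(params.symptom_probs.values()) + list(params.trigger_probs.values()):
                if not 0.0 <= p <= 1.0:
                    raise ValueError("probabilities must lie in [0, 1]")
            if not 0.0 <= params.unilateral_p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
            if abs(sum(params.treatment_probs) - 1.0) > 1e-9:
                raise ValueError("treatment probabilities must sum to 1")
        if self.mode is CompletenessMode.CRITERION_VIOLATING and not self.violate_criterion:
            raise ValueError("criterion-violating mode needs violate_criterion")


@dataclass(frozen=True)
class Patient:
    patient_id: str
    diagnosis: Disorder
    app_version: AppVersion
    home: Tuple[float, float] = (51.05, 3.72)


@dataclass
class Cohort:
    config: CohortConfig
    patients: List[Patient]
    attacks: List[AttackRegistration]
    events: List[ContextEvent]
    location_samples: List[LocationSample]
    daily_records: List[DailyRecord]

    @property
    def diagnoses(self) -> Dict[str, Disorder]:
        return {p.patient_id: p.diagnosis for p in self.patients}


def _lognormal_minutes(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from a log-normal with the given arithmetic mean/sd, >= 5 min."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return max(5.0, float(rng.lognormal(mu, math.sqrt(sigma2))))


def _minute(dt: datetime) -> datetime:
    return dt.replace(second=0, microsecond=0)


def _draw_set(rng: np.random.Generator, probs: Mapping, sentinel) -> FrozenSet:
    selected = {code for code, p in probs.items() if rng.random() < p}
    if not selected:
        return frozenset({sentinel})
    return frozenset(selected)


def _draw_locations(
    rng: np.random.Generator, params: PhenotypeParams, unilateral: bool
) -> FrozenSet[Location]:
    if params.cluster_zones:
        side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        region = HeadRegion.ORBITAL if rng.random() < 0.7 else HeadRegion.TEMPORAL
        zones = {Location(region, side)}
        if rng.random() < 0.3:
            zones.add(Location(HeadRegion.TEMPORAL if region is HeadRegion.ORBITAL else HeadRegion.ORBITAL, side))
        return frozenset(zones)
    n_zones = 1 + int(rng.integers(0, 3))
    pool = list(ALL_LOCATIONS)
    if unilateral:
        side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        pool = [z for z in pool if z.side is side]
    idx = rng.choice(len(pool), size=min(n_zones, len(pool)), replace=False)
    return frozenset(pool[i] for i in idx)


def _realistic_attack(
    rng: np.random.Generator,
    patient: Patient,
    params: PhenotypeParams,
    start: datetime,
) -> AttackRegistration:
    duration = _lognormal_minutes(rng, params.duration_mean_min, params.duration_sd_min)
    unilateral = bool(rng.random() < params.unilateral_p)
    intensity = Intensity(int(rng.choice(5, p=params.intensity_probs)))
    symptoms = _draw_set(rng, params.symptom_probs, Symptom.NONE)
    triggers = _draw_set(rng, params.trigger_probs, Trigger.NONE)
    if patient.app_version is AppVersion.V1:
        # implicit absence: strip sentinels back to empty sets
        symptoms = symptoms - {Symptom.NONE}
        triggers = triggers - {Trigger.NONE}
    treatment = (Treatment.TREATED_SUCCESS, Treatment.TREATED_FAILURE, Treatment.UNTREATED)[
        int(rng.choice(3, p=params.treatment_probs))
    ]
    return AttackRegistration(
        patient_id=patient.patient_id,
        start=_minute(start),
        end=_minute(start + timedelta(minutes=duration)),
        intensity=intensity,
        locations=_draw_locations(rng, params, unilateral),
        unilateral=unilateral,
        symptoms=symptoms,
        triggers=triggers,
        treatment=treatment,
        app_version=patient.app_version,
    )


# ---------------------------------------------------------------------------
# Criterion-complete construction

_CRITERIA_OF = {
    Disorder.MIGRAINE_WO_AURA: ("C", "D", "duration", "treatment"),
    Disorder.CLUSTER_HEADACHE: ("location", "symptoms", "duration", "treatment", "severity"),
    Disorder.EPISODIC_TTH: ("C", "D", "duration"),
}


def generate_criterion_complete_attack(
    disorder: Disorder,
    version: CriteriaVersion,
    rng: np.random.Generator,
    violate: Optional[str] = None,
    patient_id: str = "sim",
    start: Optional[datetime] = None,
) -> AttackRegistration:
    """Construct an attack that satisfies a disorder's required criteria.

    The attack provably fulfils every criterion required under ``version``;
    non-required criteria are sampled freely.  With ``violate`` set, exactly
    that criterion is made false and *every other* attack-level criterion of
    the disorder is made true, so the attack is labelled under precisely the
    versions that do not require the violated criterion.  Violating a
    criterion the disorder does not define raises.
    """
    version = CriteriaVersion(version)
    if violate is not None and violate not in _CRITERIA_OF[disorder]:
        raise ValueError(f"{disorder.value} has no criterion {violate!r}")
    strict = violate is not None  # hold every non-violated criterion true
    if start is None:
        start = _TRIAL_START + timedelta(minutes=float(rng.integers(0, 21 * 24 * 60)))
    start = _minute(start)

    def dur_minutes(lo: float, hi: float, required: bool, out_lo: float, out_hi: float) -> float:
        if violate == "duration":
            return out_lo if rng.random() < 0.5 else out_hi
        if required or strict or rng.random() < 0.5:
            return float(rng.uniform(lo, hi))
        return float(rng.uniform(max(1.0, lo / 3), hi * 1.3))

    if disorder is Disorder.MIGRAINE_WO_AURA:
        required_dur = version < CriteriaVersion.V3 or strict
        required_treat = version < CriteriaVersion.V2 or strict
        unilateral, symptoms = True, {Symptom.PULSATING_PAIN, Symptom.NAUSEA}
        intensity = Intensity(int(rng.integers(2, 5)))
        if violate == "C":
            unilateral, intensity = False, Intensity.MILD
            symptoms = {Symptom.NAUSEA}
        elif violate == "D":
            symptoms = {Symptom.PULSATING_PAIN, Symptom.PHOTOPHOBIA}
        minutes = dur_minutes(4 * 60, 72 * 60, required_dur, 60.0, 90 * 60.0)
        if violate == "treatment":
            treatment = Treatment.TREATED_SUCCESS
        elif required_treat or rng.random() < 0.5:
            treatment = Treatment.UNTREATED if rng.random() < 0.5 else Treatment.TREATED_FAILURE
        else:
            treatment = Treatment.TREATED_SUCCESS
        locations = frozenset({Location(HeadRegion.PARIETAL, Side.LEFT)})
    elif disorder is Disorder.CLUSTER_HEADACHE:
        required_dur = version < CriteriaVersion.V3 or strict
        required_sev = version < CriteriaVersion.V3 or strict
        required_treat = version < CriteriaVersion.V2 or strict
        unilateral = True
        locations = frozenset({Location(HeadRegion.ORBITAL, Side.LEFT)})
        symptoms = {Symptom.LACRIMATION} if rng.random() < 0.5 else {Symptom.RESTLESSNESS_AGITATION}
        if violate == "location":
            unilateral = False
        elif violate == "symptoms":
            symptoms = set()
        intensity = Intensity(int(rng.integers(3, 5)))
        if violate == "severity":
            intensity = Intensity(int(rng.integers(1, 3)))
        elif not required_sev and rng.random() < 0.3:
            intensity = Intensity(int(rng.integers(1, 5)))
        minutes = dur_minutes(15, 180, required_dur, 5.0, 300.0)
        if violate == "treatment":
            treatment = Treatment.TREATED_SUCCESS
        elif required_treat or rng.random() < 0.5:
            treatment = Treatment.UNTREATED
        else:
            treatment = Treatment.TREATED_SUCCESS
    else:  # episodic TTH
        required_dur = version < CriteriaVersion.V3 or strict
        unilateral, symptoms = False, set()
        intensity = Intensity(int(rng.integers(1, 3)))
        if violate == "C":
            unilateral = True
            symptoms = {Symptom.PULSATING_PAIN}
            intensity = Intensity.SEVERE
        elif violate == "D":
            symptoms = {Symptom.NAUSEA}
        minutes = dur_minutes(30, 7 * 24 * 60, required_dur, 10.0, 8 * 24 * 60.0)
        treatment = (Treatment.UNTREATED, Treatment.TREATED_SUCCESS)[int(rng.integers(0, 2))]
        locations = frozenset({Location(HeadRegion.FRONTAL, Side.MID)})

    return AttackRegistration(
        patient_id=patient_id,
        start=start,
        end=start + timedelta(minutes=round(minutes)),
        intensity=intensity,
        locations=locations,
        unilateral=unilateral,
        symptoms=frozenset(symptoms),
        triggers=frozenset(),
        treatment=treatment,
        app_version=AppVersion.V1,
    )


def sample_phenotype_attacks(
    params: PhenotypeParams,
    n: int,
    rng: np.random.Generator,
    app_version: AppVersion = AppVersion.V2,
) -> List[AttackRegistration]:
    """Draw ``n`` attacks from one phenotype's configured distributions."""
    patient = Patient(patient_id="sample", diagnosis=Disorder.MIGRAINE_WO_AURA, app_version=app_version)
    out = []
    for _ in range(n):
        start = _TRIAL_START + timedelta(minutes=float(rng.integers(0, 21 * 24 * 60)))
        out.append(_realistic_attack(rng, patient, params, start))
    return out


def sample_random_attacks(n: int, rng: np.random.Generator) -> List[AttackRegistration]:
    """Draw attacks uniformly-ish over the whole registration feature space.

    Intended for property tests (e.g. version nesting), not realism: every
    symptom is an independent coin flip, durations span minutes to days, all
    treatment outcomes and intensities occur.
    """
    symptoms_pool = [s for s in Symptom if s is not Symptom.NONE]
    out = []
    for _ in range(n):
        start = _TRIAL_START + timedelta(minutes=float(rng.integers(0, 30 * 24 * 60)))
        start = _minute(start)
        symptoms = frozenset(s for s in symptoms_pool if rng.random() < 0.3)
        if not symptoms and rng.random() < 0.5:
            symptoms = frozenset({Symptom.NONE})
        n_zones = int(rng.integers(0, 4))
        idx = rng.choice(len(ALL_LOCATIONS), size=n_zones, replace=False)
        minutes = float(rng.choice([10, 30, 45, 120, 300, 1000, 4320, 12000]))
        out.append(
            AttackRegistration(
                patient_id=f"rand{int(rng.integers(0, 50)):02d}",
                start=start,
                end=start + timedelta(minutes=minutes),
                intensity=Intensity(int(rng.integers(0, 5))),
                locations=frozenset(ALL_LOCATIONS[i] for i in idx),
                unilateral=bool(rng.random() < 0.5),
                symptoms=symptoms,
                triggers=frozenset(),
                treatment=(Treatment.TREATED_SUCCESS, Treatment.TREATED_FAILURE, Treatment.UNTREATED)[
                    int(rng.integers(0, 3))
                ],
                app_version=AppVersion.V1,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Contextual streams


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _daily_events(
    rng: np.random.Generator,
    patient: Patient,
    day_start: datetime,
    config: CohortConfig,
) -> Tuple[List[ContextEvent], List[DailyRecord]]:
    events: List[ContextEvent] = []
    pid = patient.patient_id
    # nightly sleep
    bed_offset = float(rng.normal(0.0, config.sleep_bed_sd_min))
    bed = day_start + timedelta(hours=config.sleep_bed_time.hour, minutes=config.sleep_bed_time.minute + bed_offset)
    sleep_min = max(240.0, float(rng.normal(config.sleep_duration_mean_min, config.sleep_duration_sd_min)))
    events.append(
        ContextEvent(
            patient_id=pid,
            kind=EventKind.SLEEP,
            start=_minute(bed),
            end=_minute(bed + timedelta(minutes=sleep_min)),
            source=EventSource.AUTOMATIC,
            interaction=Interaction.CONFIRMED if rng.random() < 0.15 else Interaction.IGNORED,
        )
    )
    # daytime activities: mostly sedentary blocks, occasional walking/exercise
    t = day_start + timedelta(hours=8)
    day_end = day_start + timedelta(hours=22)
    n_target = rng.poisson(config.activities_per_day)
    n_made = 0
    while t < day_end and n_made < n_target:
        r = rng.random()
        if r < 0.85:
            a_type = ActivityType(
                ["sedentary", "sitting", "standing", "lying_down"][int(rng.integers(0, 4))]
            )
            minutes = float(rng.uniform(10, 40))
        elif r < 0.95:
            a_type = ActivityType.WALKING
            minutes = float(rng.uniform(5, 25))
        else:
            a_type = ActivityType.RUNNING if rng.random() < 0.7 else ActivityType.CYCLING
            minutes = float(rng.uniform(15, 60))
        end = min(t + timedelta(minutes=minutes), day_end)
        events.append(
            ContextEvent(
                patient_id=pid,
                kind=EventKind.ACTIVITY,
                start=_minute(t),
                end=_minute(end),
                activity_type=a_type,
                source=EventSource.AUTOMATIC,
                interaction=Interaction.CONFIRMED if rng.random() < 0.45 else Interaction.IGNORED,
            )
        )
        t = end + timedelta(seconds=float(rng.uniform(0, 120)))
        n_made += 1
    # stress periods
    n_stress = rng.poisson(config.stress_events_per_day)
    for _ in range(int(n_stress)):
        s = day_start + timedelta(hours=8) + timedelta(minutes=float(rng.uniform(0, 13 * 60)))
        minutes = float(rng.uniform(10, 60))
        confirmed = rng.random() < config.stress_confirm_p
        events.append(
            ContextEvent(
                patient_id=pid,
                kind=EventKind.STRESS,
                start=_minute(s),
                end=_minute(s + timedelta(minutes=minutes)),
                stress_level=int(rng.integers(1, 3)) if confirmed else None,
                source=EventSource.AUTOMATIC,
                interaction=Interaction.CONFIRMED if confirmed else Interaction.IGNORED,
            )
        )
    # daily record
    skip_meal = rng.random() < 0.1
    meals = {}
    for name, at in (("breakfast", time(8, 0)), ("lunch", time(12, 30)), ("dinner", time(19, 0))):
        taken = not (skip_meal and name == "lunch")
        meals[name] = MealRecord(taken=taken, at=at if taken else None)
    record = DailyRecord(
        patient_id=pid,
        day=day_start.date(),
        stress_level=int(rng.integers(1, 11)),
        mood=int(rng.integers(1, 6)),
        breakfast=meals["breakfast"],
        lunch=meals["lunch"],
        dinner=meals["dinner"],
    )
    return events, [record]


def _plant_trigger_evidence(
    rng: np.random.Generator,
    attack: AttackRegistration,
    config: CohortConfig,
) -> List[ContextEvent]:
    """Plant contextual events backing an attack's indicated triggers."""
    events: List[ContextEvent] = []
    if Trigger.PHYSICAL_EXERCISE in attack.triggers and rng.random() < config.trigger_plant_p:
        lead = timedelta(minutes=float(rng.uniform(30, 150)))
        start = attack.start - lead
        events.append(
            ContextEvent(
                patient_id=attack.patient_id,
                kind=EventKind.ACTIVITY,
                start=_minute(start),
                end=_minute(start + timedelta(minutes=float(rng.uniform(10, 45)))),
                activity_type=ActivityType.RUNNING if rng.random() < 0.6 else ActivityType.CYCLING,
                source=EventSource.AUTOMATIC,
                interaction=Interaction.CONFIRMED,
            )
        )
    if Trigger.STRESS in attack.triggers and rng.random() < config.trigger_plant_p:
        lead = timedelta(minutes=float(rng.uniform(30, 270)))
        start = attack.start - lead
        events.append(
            ContextEvent(
                patient_id=attack.patient_id,
                kind=EventKind.STRESS,
                start=_minute(start),
                end=_minute(start + timedelta(minutes=float(rng.uniform(15, 60)))),
                stress_level=int(rng.integers(1, 3)),
                source=EventSource.AUTOMATIC,
                interaction=Interaction.CONFIRMED,
            )
        )
    return events


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort: patients, attacks, contextual streams.

    Reproducible: the same config (including seed) yields identical output.
    """
    patients: List[Patient] = []
    attacks: List[AttackRegistration] = []
    events: List[ContextEvent] = []
    samples: List[LocationSample] = []
    records: List[DailyRecord] = []
    specs = [(Disorder.MIGRAINE_WO_AURA, config.migraine)] * config.n_migraine + [
        (Disorder.CLUSTER_HEADACHE, config.cluster)
    ] * config.n_ch
    for index, (diagnosis, params) in enumerate(specs):
        rng = _patient_rng(config.seed, index)
        home = (51.0 + float(rng.uniform(-0.5, 0.5)), 3.7 + float(rng.uniform(-0.5, 0.5)))
        patient = Patient(
            patient_id=f"p{index:03d}",
            diagnosis=diagnosis,
            app_version=config.app_version,
            home=home,
        )
        patients.append(patient)
        # contextual streams, one day at a time
        for day in range(config.trial_days):
            day_start = _TRIAL_START + timedelta(days=day)
            ev, rec = _daily_events(rng, patient, day_start, config)
            events.extend(ev)
            records.extend(rec)
            for k in range(0, 24 * 60, 30):  # sparse background GPS at home
                jitter = rng.normal(0.0, 2e-5, size=2)
                samples.append(
                    LocationSample(
                        patient_id=patient.patient_id,
                        time=day_start + timedelta(minutes=k),
                        latitude=home[0] + float(jitter[0]),
                        longitude=home[1] + float(jitter[1]),
                        accuracy=float(rng.uniform(5, 30)),
                    )
                )
        # attacks
        n_attacks = max(0, int(round(rng.normal(params.attacks_per_trial_mean, params.attacks_per_trial_sd))))
        day_offsets = sorted(rng.uniform(0, config.trial_days * 24 * 60, size=n_attacks))
        for minutes in day_offsets:
            start = _TRIAL_START + timedelta(minutes=float(minutes))
            if config.mode is CompletenessMode.REALISTIC:
                attack = _realistic_attack(rng, patient, params, start)
            else:
                attack = generate_criterion_complete_attack(
                    diagnosis,
                    config.target_version,
                    rng,
                    violate=(
                        config.violate_criterion
                        if config.mode is CompletenessMode.CRITERION_VIOLATING
                        else None
                    ),
                    patient_id=patient.patient_id,
                    start=start,
                )
            attacks.append(attack)
            events.extend(_plant_trigger_evidence(rng, attack, config))
    events.sort(key=lambda e: (e.patient_id, e.start, e.end))
    samples.sort(key=lambda s: (s.patient_id, s.time))
    return Cohort(
        config=config,
        patients=patients,
        attacks=attacks,
        events=events,
        location_samples=samples,
        daily_records=records,
    )


# ---------------------------------------------------------------------------
# Focused scenario generators


def generate_gps_track(
    patient_id: str,
    start: datetime,
    duration: timedelta,
    speed_kmh: float,
    sample_interval: timedelta = timedelta(minutes=0.5),
    origin: Tuple[float, float] = (51.05, 3.72),
    bearing_deg: float = 90.0,
) -> List[LocationSample]:
    """Straight-line GPS track at a constant speed (spherical geometry)."""
    samples = []
    n = int(duration / sample_interval) + 1
    meters_per_sample = speed_kmh / 3.6 * sample_interval.total_seconds()
    lat, lon = origin
    brg = math.radians(bearing_deg)
    for i in range(n):
        d = meters_per_sample * i / 6_371_000.0
        phi1 = math.radians(lat)
        lam1 = math.radians(lon)
        phi2 = math.asin(
            math.sin(phi1) * math.cos(d) + math.cos(phi1) * math.sin(d) * math.cos(brg)
        )
        lam2 = lam1 + math.atan2(
            math.sin(brg) * math.sin(d) * math.cos(phi1),
            math.cos(d) - math.sin(phi1) * math.sin(phi2),
        )
        samples.append(
            LocationSample(
                patient_id=patient_id,
                time=start + i * sample_interval,
                latitude=math.degrees(phi2),
                longitude=math.degrees(lam2),
                accuracy=10.0,
            )
        )
    return samples


def generate_activity_index_trace(
    patient_id: str,
    start: datetime,
    rng: np.random.Generator,
    in_bed: Sequence[Tuple[int, int]],
    wake_excursions: Mapping[int, Sequence[Tuple[int, int]]] = {},
    n_epochs: Optional[int] = None,
    threshold: float = 10.0,
    epoch: timedelta = timedelta(minutes=5),
) -> ActivityIndexSeries:
    """Synthetic activity-index series with planted rest periods.

    ``in_bed`` lists epoch-index intervals ``[lo, hi)`` of rest; for rest
    interval ``i``, ``wake_excursions[i]`` lists embedded above-threshold
    intervals (each must be shorter than 1 h to register as a wake period).
    Outside rest the index is noisy and above threshold; inside it is low.
    """
    if n_epochs is None:
        n_epochs = max(hi for _, hi in in_bed) + 12
    values = threshold + 5.0 + 10.0 * rng.random(n_epochs)  # active baseline
    for i, (lo, hi) in enumerate(in_bed):
        values[lo:hi] = threshold * 0.2 * rng.random(hi - lo)
        for wlo, whi in wake_excursions.get(i, ()):  # planted wake-ups
            values[wlo:whi] = threshold + 2.0 + 5.0 * rng.random(whi - wlo)
    return ActivityIndexSeries(
        patient_id=patient_id, start=start, values=tuple(values), epoch=epoch
    )


def generate_trigger_support_scenario(
    n_attacks: int,
    p: float,
    rng: np.random.Generator,
    trigger: Trigger = Trigger.PHYSICAL_EXERCISE,
    window: timedelta = timedelta(hours=3),
) -> Tuple[List[AttackRegistration], List[ContextEvent]]:
    """Trigger-tagged attacks of which a fraction ``p`` has planted evidence.

    Each attack is tagged with ``trigger``; with probability ``p`` a backing
    event (a running activity, or a confirmed stress period) is planted
    inside the detection window before the attack, otherwise no evidence
    exists anywhere near the attack.  Attacks are spaced far apart so
    evidence never leaks across attacks.
    """
    if trigger not in (Trigger.PHYSICAL_EXERCISE, Trigger.STRESS):
        raise ValueError("scenario supports the exercise and stress triggers")
    attacks: List[AttackRegistration] = []
    events: List[ContextEvent] = []
    for i in range(n_attacks):
        start = _TRIAL_START + timedelta(days=i)  # >> any window: no leakage
        attacks.append(
            AttackRegistration(
                patient_id="scenario",
                start=start,
                end=start + timedelta(hours=2),
                intensity=Intensity.MODERATE,
                unilateral=True,
                symptoms=frozenset({Symptom.PHOTOPHOBIA}),
                triggers=frozenset({trigger}),
                treatment=Treatment.UNTREATED,
                app_version=AppVersion.V2,
            )
        )
        if rng.random() < p:
            lead = timedelta(minutes=float(rng.uniform(20, window.total_seconds() / 60 - 30)))
            ev_start = start - lead
            if trigger is Trigger.PHYSICAL_EXERCISE:
                events.append(
                    ContextEvent(
                        patient_id="scenario",
                        kind=EventKind.ACTIVITY,
                        start=ev_start,
                        end=ev_start + timedelta(minutes=20),
                        activity_type=ActivityType.RUNNING,
                        source=EventSource.AUTOMATIC,
                        interaction=Interaction.CONFIRMED,
                    )
                )
            else:
                events.append(
                    ContextEvent(
                        patient_id="scenario",
                        kind=EventKind.STRESS,
                        start=ev_start,
                        end=ev_start + timedelta(minutes=30),
                        stress_level=2,
                        source=EventSource.AUTOMATIC,
                        interaction=Interaction.CONFIRMED,
                    )
                )
    return attacks, events
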