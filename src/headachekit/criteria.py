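"""Rule-based classification of individual headache attacks.

The classifier evaluates, per attack and per disorder, the diagnostic-criteria
predicates of ICHD-3 that are targeted at characteristics of an *individual*
attack, for three primary headache phenotypes: migraine without aura, cluster
headache (CH) and episodic tension-type headache (TTH).  Criteria targeted at
series of attacks (attack counts, frequencies, the "not better accounted for"
caution) are deliberately out of scope here and handled at the disorder level
(see :mod:`headachekit.diagnosis`).

Three criteria versions progressively relax the attack-level criteria:

* **V1** requires every attack-level criterion (the strict reading).
* **V2** drops the treatment requirement ("untreated or unsuccessfully
  treated" for migraine, "untreated" for CH), because treated attacks are the
  practical norm; the treatment criterion is still *evaluated* and reported.
* **V3** additionally drops the duration requirement for all three disorders
  and the severity requirement for CH; all dropped criteria are evaluated and
  reported alongside each assigned label.

Because the criteria only relax across versions, the label sets nest:
``labels(V1) <= labels(V2) <= labels(V3)`` for every attack.  The migraine
associated-symptom criterion (nausea/vomiting, or photophobia plus
phonophobia) is the logical complement of the TTH one, so an attack can never
carry the migraine and TTH labels simultaneously.

App-list predicates that have no verbatim ICHD-3 wording are mapped through
fixed proxies: "pressing or tightening (non-pulsating)" is the absence of
"pulsating pain"; "aggravation by routine physical activity" is "movement
sensitivity" or "pain increment during routine physical activity"; the CH
location criterion matches any selected orbital, frontal (supra-orbital
proxy) or temporal zone together with the explicit unilateral flag.
Ipsilaterality of cranial autonomic symptoms is implicitly assumed fulfilled,
since the diary does not record symptom side.
"""

from __future__ import annotations

import enum
import itertools
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

from .records import (
    CAS_SYMPTOMS,
    AppVersion,
    AttackRegistration,
    HeadRegion,
    Intensity,
    Location,
    Side,
    Symptom,
    Treatment,
    attack_duration,
)

__all__ = [
    "Disorder",
    "CriteriaVersion",
    "ClassifierConfig",
    "MigraineProfile",
    "ClusterProfile",
    "TTHProfile",
    "CriterionProfile",
    "ClassificationResult",
    "evaluate_profile",
    "classify_attack",
    "classify_cohort",
    "CohortSummary",
    "PatientSummary",
    "mostly_diagnosis",
    "exhaustive_attack_space",
    "ENUMERATION_SYMPTOMS",
]


class Disorder(enum.Enum):
    MIGRAINE_WO_AURA = "migraine_without_aura"
    CLUSTER_HEADACHE = "cluster_headache"
    EPISODIC_TTH = "episodic_tth"


class CriteriaVersion(enum.IntEnum):
    V1 = 1
    V2 = 2
    V3 = 3


#: Attack-level criteria per disorder: the required "core" set (needed by every
#: version) and the relaxable set with the version in which each criterion
#: stops being required.
_CORE: Dict[Disorder, Tuple[str, ...]] = {
    Disorder.MIGRAINE_WO_AURA: ("C", "D"),
    Disorder.CLUSTER_HEADACHE: ("location", "symptoms"),
    Disorder.EPISODIC_TTH: ("C", "D"),
}
# criterion -> first version in which it is no longer required
_RELAXED_AT: Dict[Disorder, Dict[str, CriteriaVersion]] = {
    Disorder.MIGRAINE_WO_AURA: {"treatment": CriteriaVersion.V2, "duration": CriteriaVersion.V3},
    Disorder.CLUSTER_HEADACHE: {
        "treatment": CriteriaVersion.V2,
        "duration": CriteriaVersion.V3,
        "severity": CriteriaVersion.V3,
    },
    Disorder.EPISODIC_TTH: {"duration": CriteriaVersion.V3},
}


def required_criteria(disorder: Disorder, version: CriteriaVersion) -> Tuple[str, ...]:
    """Names of the criteria an attack must fulfil to receive this label."""
    relaxed = _RELAXED_AT[disorder]
    return _CORE[disorder] + tuple(c for c, v in relaxed.items() if version < v)


def additionally_evaluated(disorder: Disorder, version: CriteriaVersion) -> Tuple[str, ...]:
    """Criteria evaluated and reported, but not required, under this version."""
    relaxed = _RELAXED_AT[disorder]
    return tuple(c for c, v in relaxed.items() if version >= v)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable predicate mappings.

    ``very_severe_counts_as_severe`` controls whether intensity 4 (very
    severe) satisfies "moderate or severe" (migraine) — on by default, reading
    the scale as ordered so that any intensity above the named band's floor
    that is not below its ceiling counts.
    """

    very_severe_counts_as_severe: bool = True


DEFAULT_CONFIG = ClassifierConfig()

# Inclusive duration bounds, in minutes.
_MIGRAINE_DURATION = (4 * 60.0, 72 * 60.0)
_CLUSTER_DURATION = (15.0, 180.0)
_TTH_DURATION = (30.0, 7 * 24 * 60.0)

#: CH location criterion: matching manikin regions for "orbital, supra-orbital
#: and/or temporal" (frontal is the manikin's supra-orbital proxy).
_CLUSTER_REGIONS = frozenset({HeadRegion.ORBITAL, HeadRegion.FRONTAL, HeadRegion.TEMPORAL})

_AGGRAVATION = (Symptom.MOVEMENT_SENSITIVITY, Symptom.PAIN_INCREMENT_PHYSICAL_ACTIVITY)


@dataclass(frozen=True)
class MigraineProfile:
    """Attack-level migraine-without-aura criterion truth assignment."""

    c1_unilateral: bool
    c2_pulsating: bool
    c3_moderate_or_severe: bool
    c4_aggravation: bool
    c_met: bool
    d1_nausea_vomiting: bool
    d2_photo_phonophobia: bool
    d_met: bool
    duration_ok: bool
    treatment_ok: bool

    disorder = Disorder.MIGRAINE_WO_AURA

    @property
    def criteria(self) -> Dict[str, bool]:
        return {
            "C": self.c_met,
            "D": self.d_met,
            "duration": self.duration_ok,
            "treatment": self.treatment_ok,
        }


@dataclass(frozen=True)
class ClusterProfile:
    """Attack-level cluster-headache criterion truth assignment."""

    loc_ok: bool
    cas_ok: bool
    restlessness_ok: bool
    c_met: bool
    duration_ok: bool
    severity_ok: bool
    treatment_ok: bool

    disorder = Disorder.CLUSTER_HEADACHE

    @property
    def criteria(self) -> Dict[str, bool]:
        return {
            "location": self.loc_ok,
            "symptoms": self.c_met,
            "duration": self.duration_ok,
            "treatment": self.treatment_ok,
            "severity": self.severity_ok,
        }


@dataclass(frozen=True)
class TTHProfile:
    """Attack-level episodic tension-type-headache criterion truth assignment."""

    c1_bilateral: bool
    c2_non_pulsating: bool
    c3_mild_or_moderate: bool
    c4_not_aggravated: bool
    c_met: bool
    d_met: bool
    duration_ok: bool

    disorder = Disorder.EPISODIC_TTH

    @property
    def criteria(self) -> Dict[str, bool]:
        return {"C": self.c_met, "D": self.d_met, "duration": self.duration_ok}


CriterionProfile = MigraineProfile | ClusterProfile | TTHProfile


def _migraine_profile(a: AttackRegistration, config: ClassifierConfig) -> MigraineProfile:
    s = a.symptoms
    c1 = a.unilateral
    c2 = Symptom.PULSATING_PAIN in s
    top = Intensity.VERY_SEVERE if config.very_severe_counts_as_severe else Intensity.SEVERE
    c3 = Intensity.MODERATE <= a.intensity <= top
    c4 = _AGGRAVATION[0] in s or _AGGRAVATION[1] in s
    d1 = Symptom.NAUSEA in s or Symptom.VOMITING in s
    d2 = Symptom.PHOTOPHOBIA in s and Symptom.PHONOPHOBIA in s
    dur = attack_duration(a)
    return MigraineProfile(
        c1_unilateral=c1,
        c2_pulsating=c2,
        c3_moderate_or_severe=c3,
        c4_aggravation=c4,
        c_met=(c1 + c2 + c3 + c4) >= 2,
        d1_nausea_vomiting=d1,
        d2_photo_phonophobia=d2,
        d_met=d1 or d2,
        duration_ok=_MIGRAINE_DURATION[0] <= dur <= _MIGRAINE_DURATION[1],
        treatment_ok=a.treatment is not Treatment.TREATED_SUCCESS,
    )


def _cluster_profile(a: AttackRegistration, config: ClassifierConfig) -> ClusterProfile:
    s = a.symptoms
    loc = a.unilateral and any(loc.region in _CLUSTER_REGIONS for loc in a.locations)
    cas = not CAS_SYMPTOMS.isdisjoint(s)
    restless = Symptom.RESTLESSNESS_AGITATION in s
    dur = attack_duration(a)
    return ClusterProfile(
        loc_ok=loc,
        cas_ok=cas,
        restlessness_ok=restless,
        c_met=cas or restless,
        duration_ok=_CLUSTER_DURATION[0] <= dur <= _CLUSTER_DURATION[1],
        severity_ok=a.intensity >= Intensity.SEVERE,
        treatment_ok=a.treatment is Treatment.UNTREATED,
    )


def _tth_profile(a: AttackRegistration, config: ClassifierConfig) -> TTHProfile:
    s = a.symptoms
    c1 = not a.unilateral
    c2 = Symptom.PULSATING_PAIN not in s
    c3 = Intensity.MILD <= a.intensity <= Intensity.MODERATE
    c4 = _AGGRAVATION[0] not in s and _AGGRAVATION[1] not in s
    d = (
        Symptom.NAUSEA not in s
        and Symptom.VOMITING not in s
        and not (Symptom.PHOTOPHOBIA in s and Symptom.PHONOPHOBIA in s)
    )
    dur = attack_duration(a)
    return TTHProfile(
        c1_bilateral=c1,
        c2_non_pulsating=c2,
        c3_mild_or_moderate=c3,
        c4_not_aggravated=c4,
        c_met=(c1 + c2 + c3 + c4) >= 2,
        d_met=d,
        duration_ok=_TTH_DURATION[0] <= dur <= _TTH_DURATION[1],
    )


_PROFILE_FN = {
    Disorder.MIGRAINE_WO_AURA: _migraine_profile,
    Disorder.CLUSTER_HEADACHE: _cluster_profile,
    Disorder.EPISODIC_TTH: _tth_profile,
}


def evaluate_profile(
    a: AttackRegistration,
    disorder: Disorder,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> CriterionProfile:
    """Evaluate every attack-level criterion of one disorder for one attack."""
    return _PROFILE_FN[disorder](a, config)


@dataclass(frozen=True)
class ClassificationResult:
    """Zero-to-three disorder labels for one attack.

    ``labels`` maps each assigned disorder to the fulfilment flags of the
    criteria that the active version evaluates but does not require.
    """

    attack: AttackRegistration
    version: CriteriaVersion
    labels: Dict[Disorder, Dict[str, bool]]
    profiles: Dict[Disorder, CriterionProfile]

    @property
    def label_set(self) -> FrozenSet[Disorder]:
        return frozenset(self.labels)

    def all_additional_fulfilled(self, disorder: Disorder) -> bool:
        return all(self.labels[disorder].values())


def classify_attack(
    a: AttackRegistration,
    version: CriteriaVersion = CriteriaVersion.V3,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> ClassificationResult:
    """Classify one attack under one criteria version.

    Each disorder is evaluated independently: its label is assigned iff every
    criterion required by the version holds, and for each assigned label the
    additionally-evaluated (non-required) criteria are reported.
    """
    version = CriteriaVersion(version)
    profiles: Dict[Disorder, CriterionProfile] = {}
    labels: Dict[Disorder, Dict[str, bool]] = {}
    for disorder in Disorder:
        profile = _PROFILE_FN[disorder](a, config)
        profiles[disorder] = profile
        crit = profile.criteria
        if all(crit[name] for name in required_criteria(disorder, version)):
            labels[disorder] = {name: crit[name] for name in additionally_evaluated(disorder, version)}
    return ClassificationResult(attack=a, version=version, labels=labels, profiles=profiles)


# ---------------------------------------------------------------------------
# Cohort-level summaries


@dataclass
class PatientSummary:
    patient_id: str
    diagnosis: Optional[Disorder]
    n_attacks: int
    label_counts: Counter
    mostly_diagnosis: Optional[bool]
    mostly_diagnosis_excl_tth: Optional[bool]


@dataclass
class CohortSummary:
    """Aggregated classification counts for a cohort of attacks.

    Counts are reported overall and per diagnosis group; the histogram counts
    attacks by how many labels (0-3) they received.
    """

    version: CriteriaVersion
    n_attacks: int
    label_counts: Counter
    label_pct: Dict[Disorder, float]
    additional_fulfilled: Dict[Disorder, Counter]
    all_additional_fulfilled: Counter
    n_labels_histogram: Counter
    patients: List[PatientSummary]
    groups: Dict[Optional[Disorder], "CohortSummary"] = field(default_factory=dict)


def mostly_diagnosis(
    label_counts: Mapping[Disorder, int],
    diagnosis: Disorder,
    include_tth: bool = True,
) -> Optional[bool]:
    """Whether the strictly most frequent label matches the patient diagnosis.

    With ``include_tth=False`` episodic-TTH labels are ignored before taking
    the argmax.  A tie for the top count yields ``False`` (a strict majority
    is required); no labels at all yields ``False``; the caller should pass
    ``None``-diagnosis / zero-attack patients through as not assessable.
    """
    counts = {d: int(c) for d, c in label_counts.items() if c > 0}
    if not include_tth:
        counts.pop(Disorder.EPISODIC_TTH, None)
    if not counts:
        return False
    best = max(counts.values())
    winners = [d for d, c in counts.items() if c == best]
    return winners == [diagnosis]


def classify_cohort(
    attacks: Sequence[AttackRegistration],
    version: CriteriaVersion = CriteriaVersion.V3,
    diagnoses: Optional[Mapping[str, Disorder]] = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> CohortSummary:
    """Classify a cohort and aggregate counts overall and per diagnosis group."""
    results = [classify_attack(a, version, config) for a in attacks]
    summary = _summarize(results, version, diagnoses)
    if diagnoses:
        by_group: Dict[Optional[Disorder], List[ClassificationResult]] = {}
        for r in results:
            by_group.setdefault(diagnoses.get(r.attack.patient_id), []).append(r)
        summary.groups = {
            g: _summarize(rs, version, diagnoses) for g, rs in sorted(
                by_group.items(), key=lambda kv: (kv[0] is None, kv[0].value if kv[0] else "")
            )
        }
    return summary


def _summarize(
    results: Sequence[ClassificationResult],
    version: CriteriaVersion,
    diagnoses: Optional[Mapping[str, Disorder]],
) -> CohortSummary:
    label_counts: Counter = Counter()
    additional: Dict[Disorder, Counter] = {d: Counter() for d in Disorder}
    all_additional: Counter = Counter()
    histogram: Counter = Counter({k: 0 for k in range(4)})
    per_patient: Dict[str, Counter] = {}
    patient_n: Counter = Counter()
    for r in results:
        histogram[len(r.labels)] += 1
        patient_n[r.attack.patient_id] += 1
        counts = per_patient.setdefault(r.attack.patient_id, Counter())
        for disorder, flags in r.labels.items():
            label_counts[disorder] += 1
            counts[disorder] += 1
            for name, ok in flags.items():
                if ok:
                    additional[disorder][name] += 1
            if flags and all(flags.values()):
                all_additional[disorder] += 1
    n = len(results)
    patients = []
    for pid in sorted(per_patient):
        diag = diagnoses.get(pid) if diagnoses else None
        counts = per_patient[pid]
        patients.append(
            PatientSummary(
                patient_id=pid,
                diagnosis=diag,
                n_attacks=patient_n[pid],
                label_counts=counts,
                mostly_diagnosis=mostly_diagnosis(counts, diag, True) if diag else None,
                mostly_diagnosis_excl_tth=mostly_diagnosis(counts, diag, False) if diag else None,
            )
        )
    return CohortSummary(
        version=version,
        n_attacks=n,
        label_counts=label_counts,
        label_pct={d: (100.0 * label_counts[d] / n if n else 0.0) for d in Disorder},
        additional_fulfilled=additional,
        all_additional_fulfilled=all_additional,
        n_labels_histogram=histogram,
        patients=patients,
    )


# ---------------------------------------------------------------------------
# Exhaustive enumeration of the discretized attack feature space

#: The 16 criterion-distinct symptom codes used by the exhaustive enumeration:
#: all selectable symptoms except the pain-increment code, which is
#: predicate-equivalent to movement sensitivity in every criterion.
ENUMERATION_SYMPTOMS: Tuple[Symptom, ...] = tuple(
    s
    for s in Symptom
    if s not in (Symptom.NONE, Symptom.PAIN_INCREMENT_PHYSICAL_ACTIVITY)
)
assert len(ENUMERATION_SYMPTOMS) == 16


def exhaustive_attack_space(
    symptom_codes: Sequence[Symptom] = ENUMERATION_SYMPTOMS,
    intensities: Sequence[int] = (1, 2, 3),
    duration_minutes: float = 45.0,
    location: Optional[Location] = None,
    treatment: Treatment = Treatment.UNTREATED,
) -> Iterator[AttackRegistration]:
    """Enumerate every attack over all symptom subsets x unilaterality x intensity.

    The remaining fields are held fixed (orbital-left zone, 45 min, untreated
    by default), giving ``2**len(symptom_codes) * 2 * len(intensities)``
    attacks.  Registrations are emitted under the v1 schema so the empty
    symptom set is representable.
    """
    if location is None:
        location = Location(HeadRegion.ORBITAL, Side.LEFT)
    start = datetime(2021, 1, 1, 12, 0, tzinfo=timezone.utc)
    end = start + timedelta(minutes=duration_minutes)
    locations = frozenset({location})
    codes = tuple(symptom_codes)
    for bits in range(2 ** len(codes)):
        symptoms = frozenset(c for i, c in enumerate(codes) if bits >> i & 1)
        for unilateral in (True, False):
            for intensity in intensities:
                yield AttackRegistration(
                    patient_id="enum",
                    start=start,
                    end=end,
                    intensity=Intensity(intensity),
                    locations=locations,
                    unilateral=unilateral,
                    symptoms=symptoms,
                    triggers=frozenset(),
                    treatment=treatment,
                    app_version=AppVersion.V1,
                )
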