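"""Lifting per-attack classifications to disorder-level diagnosis candidates.

Attack-level classification deliberately ignores the criteria that concern a
*series* of attacks: the minimum attack counts, the cluster-headache attack
frequency ("between one every other day and eight per day"), the episodic-TTH
episode count, and the "not better accounted for by another diagnosis"
caution.  This module applies exactly those criteria to the labelled attacks
of one patient.

Candidate rules:

* migraine without aura — at least five attacks labelled migraine;
* cluster headache — at least five CH-labelled attacks *and* a CH attack
  frequency within [0.5, 8] per day over the active window (first to last
  CH-labelled attack, floored at one day; the data does not delimit cluster
  periods, so the whole observed CH span is used);
* episodic TTH — at least ten TTH-labelled episodes; the infrequent/frequent
  subtypes share identical episode-level criteria, so the episode-day
  frequency is reported but never used to split the candidate.

The "not better accounted for" criterion cannot be machine-evaluated and is
always surfaced as NOT EVALUATED — it is a reminder to consider alternative
diagnoses, never an automatic check.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Dict, List, Optional, Sequence, Tuple

from .criteria import ClassificationResult, CriteriaVersion, Disorder

__all__ = ["CriterionStatus", "DiagnosisCandidate", "DiagnosisResult", "diagnose"]

MIN_ATTACKS = {
    Disorder.MIGRAINE_WO_AURA: 5,
    Disorder.CLUSTER_HEADACHE: 5,
    Disorder.EPISODIC_TTH: 10,
}

#: CH frequency band, attacks per day, inclusive ("one every other day" .. 8/day).
CLUSTER_FREQUENCY_BAND = (0.5, 8.0)


class CriterionStatus(enum.Enum):
    MET = "met"
    NOT_MET = "not_met"
    NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class DiagnosisCandidate:
    disorder: Disorder
    qualifying_attacks: int
    frequency_per_day: float
    count_ok: bool
    frequency_status: CriterionStatus
    not_better_accounted_for: CriterionStatus = CriterionStatus.NOT_EVALUATED

    @property
    def is_candidate(self) -> bool:
        return self.count_ok and self.frequency_status is not CriterionStatus.NOT_MET


@dataclass
class DiagnosisResult:
    patient_id: str
    candidates: List[DiagnosisCandidate]
    window: Optional[Tuple[datetime, datetime]]

    @property
    def candidate_disorders(self) -> List[Disorder]:
        return [c.disorder for c in self.candidates if c.is_candidate]


def _active_window_days(starts: Sequence[datetime]) -> float:
    """Span from first to last attack start in days, floored at one day."""
    span = (max(starts) - min(starts)).total_seconds() / 86400.0
    return max(span, 1.0)


def diagnose(
    results: Sequence[ClassificationResult],
    version: Optional[CriteriaVersion] = None,
) -> DiagnosisResult:
    """Evaluate disorder-level criteria over one patient's classified attacks.

    ``results`` must all belong to one patient and one criteria version; an
    empty input yields an empty candidate set.
    """
    if not results:
        return DiagnosisResult(patient_id="", candidates=[], window=None)
    pids = {r.attack.patient_id for r in results}
    if len(pids) > 1:
        raise ValueError(f"results span multiple patients: {sorted(pids)}")
    versions = {r.version for r in results}
    if len(versions) > 1:
        raise ValueError("results mix criteria versions")
    if version is not None and versions != {CriteriaVersion(version)}:
        raise ValueError("results were classified under a different version")

    starts = [r.attack.start for r in results]
    window = (min(starts), max(starts))
    candidates: List[DiagnosisCandidate] = []
    for disorder in Disorder:
        labelled = [r for r in results if disorder in r.labels]
        n = len(labelled)
        count_ok = n >= MIN_ATTACKS[disorder]
        if labelled:
            days = _active_window_days([r.attack.start for r in labelled])
            freq = n / days
        else:
            freq = 0.0
        if disorder is Disorder.CLUSTER_HEADACHE:
            lo, hi = CLUSTER_FREQUENCY_BAND
            status = CriterionStatus.MET if (n and lo <= freq <= hi) else CriterionStatus.NOT_MET
        else:
            # reported, not required (migraine has no frequency criterion at
            # this level; the TTH infrequent/frequent split is collapsed)
            status = CriterionStatus.NOT_EVALUATED
        candidates.append(
            DiagnosisCandidate(
                disorder=disorder,
                qualifying_attacks=n,
                frequency_per_day=freq,
                count_ok=count_ok,
                frequency_status=status,
            )
        )
    return DiagnosisResult(patient_id=pids.pop(), candidates=candidates, window=window)
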