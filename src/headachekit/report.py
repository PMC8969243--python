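"""Tabular reports over cohort classification results.

The report mirrors the structure of the result tables a headache study would
print: per diagnosis group, the number and percentage of attacks classified
as each disorder, how often each additionally-evaluated criterion was
fulfilled per label, the distribution of labels-per-attack (0-3), and the
per-patient "mostly diagnosis classifications" flags.
"""

from __future__ import annotations

from typing import Dict, Optional

import pandas as pd

from .criteria import CohortSummary, Disorder

__all__ = ["report_classification_summary"]

_LABEL_NAMES = {
    Disorder.MIGRAINE_WO_AURA: "migraine_without_aura",
    Disorder.CLUSTER_HEADACHE: "cluster_headache",
    Disorder.EPISODIC_TTH: "episodic_tth",
}


def _group_name(group: Optional[Disorder]) -> str:
    return _LABEL_NAMES.get(group, "all") if group else "all"


def report_classification_summary(summary: CohortSummary) -> Dict[str, pd.DataFrame]:
    """Build the summary tables for one classified cohort.

    Returns four frames: ``labels`` (counts and percentages per group and
    label), ``additional`` (fulfilled additionally-evaluated criteria per
    label), ``histogram`` (attacks by number of labels received) and
    ``patients`` (per-patient label counts and mostly-diagnosis flags).
    """
    groups = {None: summary, **summary.groups} if summary.groups else {None: summary}

    label_rows, additional_rows, histogram_rows = [], [], []
    for group, s in groups.items():
        name = _group_name(group)
        for disorder in Disorder:
            label_rows.append(
                {
                    "group": name,
                    "label": _LABEL_NAMES[disorder],
                    "n_attacks": s.n_attacks,
                    "n_classified": s.label_counts[disorder],
                    "pct": round(s.label_pct[disorder], 2),
                }
            )
            for criterion, count in sorted(s.additional_fulfilled[disorder].items()):
                additional_rows.append(
                    {
                        "group": name,
                        "label": _LABEL_NAMES[disorder],
                        "criterion": criterion,
                        "n_fulfilled": count,
                    }
                )
            additional_rows.append(
                {
                    "group": name,
                    "label": _LABEL_NAMES[disorder],
                    "criterion": "all",
                    "n_fulfilled": s.all_additional_fulfilled[disorder],
                }
            )
        for k in range(4):
            histogram_rows.append(
                {
                    "group": name,
                    "n_labels": k,
                    "n_attacks": s.n_labels_histogram[k],
                    "pct": round(100.0 * s.n_labels_histogram[k] / s.n_attacks, 2)
                    if s.n_attacks
                    else 0.0,
                }
            )

    patient_rows = []
    for p in summary.patients:
        row = {
            "patient_id": p.patient_id,
            "diagnosis": _LABEL_NAMES.get(p.diagnosis, "") if p.diagnosis else "",
            "n_attacks": p.n_attacks,
            "mostly_diagnosis": p.mostly_diagnosis,
            "mostly_diagnosis_excl_tth": p.mostly_diagnosis_excl_tth,
        }
        for disorder in Disorder:
            row[f"n_{_LABEL_NAMES[disorder]}"] = p.label_counts[disorder]
        patient_rows.append(row)

    return {
        "labels": pd.DataFrame(label_rows),
        "additional": pd.DataFrame(additional_rows),
        "histogram": pd.DataFrame(histogram_rows),
        "patients": pd.DataFrame(patient_rows),
    }
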