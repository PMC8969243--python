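"""Independent truth-table evaluation of the attack-level criteria.

This is a deliberately separate, direct transcription of the diagnostic
criteria text into boolean expressions — no code shared with the package's
rule engine — used as the oracle in equivalence tests.
"""

from headachekit.records import AttackRegistration, HeadRegion, Symptom, Treatment

HOURS = 60.0
DAYS = 24 * 60.0


def oracle_labels(a: AttackRegistration, version: int) -> set:
    """Labels for one attack under criteria version 1, 2 or 3."""
    s = a.symptoms
    minutes = (a.end - a.start).total_seconds() / 60.0
    labels = set()

    # --- migraine without aura ---
    # C: at least two of unilateral / pulsating / moderate-or-severe /
    #    aggravated by routine physical activity
    chars = [
        a.unilateral,
        Symptom.PULSATING_PAIN in s,
        int(a.intensity) in (2, 3, 4),
        (Symptom.MOVEMENT_SENSITIVITY in s)
        or (Symptom.PAIN_INCREMENT_PHYSICAL_ACTIVITY in s),
    ]
    mig_c = sum(chars) >= 2
    # D: nausea and/or vomiting, or photophobia and phonophobia
    mig_d = (
        (Symptom.NAUSEA in s)
        or (Symptom.VOMITING in s)
        or (Symptom.PHOTOPHOBIA in s and Symptom.PHONOPHOBIA in s)
    )
    mig_duration = 4 * HOURS <= minutes <= 72 * HOURS
    mig_treatment = a.treatment in (Treatment.UNTREATED, Treatment.TREATED_FAILURE)
    mig = mig_c and mig_d
    if version <= 2:
        mig = mig and mig_duration
    if version <= 1:
        mig = mig and mig_treatment
    if mig:
        labels.add("migraine_without_aura")

    # --- cluster headache ---
    ch_loc = a.unilateral and any(
        z.region in (HeadRegion.ORBITAL, HeadRegion.FRONTAL, HeadRegion.TEMPORAL)
        for z in a.locations
    )
    cas = {
        Symptom.CONJUNCTIVAL_INJECTION,
        Symptom.LACRIMATION,
        Symptom.NASAL_CONGESTION,
        Symptom.RHINORRHOEA,
        Symptom.EYELID_OEDEMA,
        Symptom.SWEATY_FOREHEAD_FACE,
        Symptom.MIOSIS,
        Symptom.PTOSIS,
    }
    ch_sym = bool(s & cas) or (Symptom.RESTLESSNESS_AGITATION in s)
    ch_duration = 15 <= minutes <= 180
    ch_severity = int(a.intensity) in (3, 4)
    ch_treatment = a.treatment is Treatment.UNTREATED
    ch = ch_loc and ch_sym
    if version <= 2:
        ch = ch and ch_duration and ch_severity
    if version <= 1:
        ch = ch and ch_treatment
    if ch:
        labels.add("cluster_headache")

    # --- episodic tension-type headache ---
    tth_chars = [
        not a.unilateral,
        Symptom.PULSATING_PAIN not in s,
        int(a.intensity) in (1, 2),
        not (
            (Symptom.MOVEMENT_SENSITIVITY in s)
            or (Symptom.PAIN_INCREMENT_PHYSICAL_ACTIVITY in s)
        ),
    ]
    tth_c = sum(tth_chars) >= 2
    tth_d = (
        Symptom.NAUSEA not in s
        and Symptom.VOMITING not in s
        and not (Symptom.PHOTOPHOBIA in s and Symptom.PHONOPHOBIA in s)
    )
    tth_duration = 30 <= minutes <= 7 * DAYS
    tth = tth_c and tth_d
    if version <= 2:
        tth = tth and tth_duration
    if tth:
        labels.add("episodic_tth")

    return labels
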