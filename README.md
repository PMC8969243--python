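# headachekit

Rule-based classification of **individual headache attacks** from electronic
diary data, together with the deterministic event-stream algorithms that
surround such a diary in a wearable-supported follow-up setting.

## The problem

Primary headache disorders — migraine, cluster headache (CH) and
tension-type headache (TTH) — are diagnosed with the ICHD-3 criteria, which
describe a *series* of attacks as reported to a physician. For continuous,
prospective follow-up one instead needs to label each *single* attack as it
is registered in a diary. `headachekit` implements a knowledge-based
classifier for this task, for three phenotypes:

* **migraine without aura** — attacks of 4–72 h with ≥ 2 of {unilateral,
  pulsating, moderate-or-severe, aggravated by routine physical activity}
  (criterion C) and nausea/vomiting or photophobia + phonophobia
  (criterion D);
* **cluster headache** — severe unilateral orbital/supra-orbital/temporal
  attacks of 15–180 min with cranial autonomic symptoms or restlessness;
* **episodic TTH** — bilateral, non-pulsating, mild-to-moderate attacks
  without the migraine-defining associated symptoms (its criterion D is the
  logical complement of the migraine one, so the two labels are mutually
  exclusive by construction).

Because the strict attack-level reading of the diagnostic criteria labels
very few real attacks (treated attacks fail the treatment clause, aborted
attacks the duration clause), three **criteria versions** are provided:

| version | required | additionally evaluated (reported, not required) |
|---|---|---|
| v1 | every attack-level criterion | — |
| v2 | v1 minus the treatment criterion | treatment |
| v3 | core criteria only | duration, treatment, severity (CH) |

Labels therefore nest: `labels(v1) ⊆ labels(v2) ⊆ labels(v3)` for every
attack.

Around the classifier the package provides: disorder-level diagnosis
criteria (attack counts and the CH frequency band of 0.5–8 attacks/day),
timeline algorithms (GPS-based commute correction at 25 km/h, sedentary-event
grouping at ≤ 60 s gaps, stress-event admission limits of 2/hour and 10/day,
location-mismatch flagging, actigraphy-style sleep detection with wake-up
periods), windowed detection of the five observable triggers (physical
exercise, stress, relief from stress, sleep deprivation, skipped meals), a
seeded synthetic cohort generator, JSONL/CSV I/O, an RDF export, and a CLI.

## Worked example

```python
from datetime import datetime, timedelta, timezone
from headachekit import (AttackRegistration, Intensity, Location, Symptom,
                         Treatment, Trigger, AppVersion,
                         classify_attack, CriteriaVersion)

start = datetime(2021, 3, 5, 14, 0, tzinfo=timezone.utc)
attack = AttackRegistration(
    patient_id="p001",
    start=start, end=start + timedelta(minutes=30),
    intensity=Intensity.SEVERE,
    locations={Location.from_code("orbital-left")},
    unilateral=True,
    symptoms={Symptom.LACRIMATION, Symptom.RESTLESSNESS_AGITATION},
    triggers={Trigger.NONE},
    treatment=Treatment.TREATED_SUCCESS,
    app_version=AppVersion.V2,
)
for version in CriteriaVersion:
    result = classify_attack(attack, version)
    print(f"v{int(version)}: {sorted(d.value for d in result.label_set)}")
```

prints

```
v1: ['episodic_tth']
v2: ['cluster_headache', 'episodic_tth']
v3: ['cluster_headache', 'episodic_tth']
```

A textbook 30-minute severe unilateral orbital attack with lacrimation and
restlessness is *not* a cluster-headache attack under the strict v1 rules —
it was successfully treated — but becomes one as soon as v2 drops the
treatment requirement. The episodic-TTH label co-occurs because its
absence-based criteria are also satisfied (the attack is non-pulsating and
carries none of the migraine-defining symptoms; only two of its four
C-characteristics are needed). The v3 result additionally reports the
relaxed criteria per label; for cluster headache here:
`{'duration': True, 'treatment': False, 'severity': True}`.

A full pipeline from the shell:

```bash
headachekit simulate --seed 7 --out cohort/
headachekit classify --version 3 --attacks cohort/attacks.jsonl \
    --patients cohort/patients.json --out labels.jsonl --summary-dir summary/
headachekit diagnose --version 3 --attacks cohort/attacks.jsonl --out dx.jsonl
headachekit triggers --attacks cohort/attacks.jsonl \
    --events cohort/events.jsonl --out support.csv
```

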