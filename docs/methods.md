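# Methods

This note documents the models and procedures implemented in `headachekit`,
the predicate mappings and numerical choices behind them, what the synthetic
cohort generator does and does not emulate, and the known limitations.

## 1. Data model

An **attack registration** carries: start and end timestamps (timezone-aware,
minute resolution — the diary collects minute-level data, so durations are
computed in minutes and converted as needed), pain intensity on a five-point
Likert scale (0 no pain … 4 very severe), a set of pain zones on a 20-zone
head manikin (region × side, e.g. `orbital-left`), an explicit unilaterality
flag, a symptom set, a trigger set, and the acute-treatment outcome
(successful / unsuccessful / untreated).

Two diary schema versions exist. Under **v1** the symptom and trigger lists
may be left empty and every unselected option is *implicitly* absent. Under
**v2** at least one option or the explicit sentinel "none of those" must be
selected, making absence explicit. The sentinel is preserved in the data
model (it is ground truth about explicitness) but evaluates identically to
the empty set in every criterion predicate.

The symptom list holds 17 selectable codes. "Movement sensitivity" and
"pain increment during routine physical activity" are stored as two separate
codes because they are separately selectable and separately reported; they
are predicate-equivalent — both feed the single "aggravated by routine
physical activity" characteristic — so exhaustive enumerations over the
criterion-relevant symptom space use the 16 criterion-distinct codes (all
codes minus one of the pair).

**Contextual events** (activity, stress, sleep, medicine, menstrual period)
carry provenance (manual vs automatic) and the user's interaction state
(ignored, confirmed, confirmed-as-sedentary-only, time-corrected,
type-corrected, removed). GPS samples and once-a-day records (stress 1–10,
mood 1–5, per-meal taken flags) complete the inputs.

## 2. Attack-level classification

Each of the three disorders is evaluated independently; an attack receives
between zero and three labels. The criterion predicates are mapped onto the
diary's option lists as follows:

* *pulsating quality* ⇔ "pulsating pain" selected; *pressing/tightening
  (non-pulsating)* ⇔ not selected;
* *aggravation by routine physical activity* ⇔ "movement sensitivity" or
  "pain increment during routine physical activity" selected; the TTH
  "not aggravated" predicate is the negation;
* intensity bands: *moderate or severe* ⇔ {2, 3, 4}, *mild or moderate* ⇔
  {1, 2}, *severe or very severe* ⇔ {3, 4}. Counting very-severe (4) pain as
  satisfying "moderate or severe" reads the scale as ordered; the choice is
  exposed as a configuration switch (`very_severe_counts_as_severe`);
* CH location: any selected zone with region ∈ {orbital, frontal, temporal}
  AND the explicit unilateral flag. The manikin has no "supra-orbital" zone;
  frontal is its proxy. Unilaterality is always taken from the explicit
  flag, never inferred from zone sides, and no side-consistency between flag
  and zones is enforced (the diary does not enforce one either);
* cranial autonomic symptoms (CAS): conjunctival injection, lacrimation,
  nasal congestion, rhinorrhoea, eyelid oedema, sweaty forehead and face,
  miosis, ptosis. Ipsilaterality of CAS is implicitly assumed fulfilled —
  the diary records no symptom side;
* duration bounds are inclusive at both ends: migraine 4–72 h, CH
  15–180 min, TTH 30 min–7 days;
* treatment: *untreated or unsuccessfully treated* ⇔ outcome ∈ {untreated,
  unsuccessful}; *untreated* ⇔ untreated only.

The three criteria versions relax requirements monotonically (v2 drops
treatment; v3 additionally drops duration for all disorders and severity for
CH), and dropped criteria are still evaluated and reported per assigned
label. Two structural invariants follow: version nesting
(`labels(v1) ⊆ labels(v2) ⊆ labels(v3)`) and migraine/TTH mutual exclusion
(their D criteria are logical complements), which makes a triple label
impossible — the quantity `scripts/acceptance.py` verifies exhaustively.

**Mostly-diagnosis agreement.** A patient "has mostly diagnosis
classifications" when the disorder with the *strictly* highest label count
over their attacks equals their clinical diagnosis; ties yield `False`
(strict argmax — the natural reading of "the most classifications"), and
patients without attacks are not assessable. The flag is computed both with
and without episodic-TTH labels.

## 3. Disorder-level diagnosis

The criteria ignored at attack level are applied per patient: ≥ 5
migraine-labelled attacks; ≥ 5 CH-labelled attacks with a frequency within
0.5–8 attacks/day; ≥ 10 TTH-labelled episodes. The CH frequency window is
the span from first to last CH-labelled attack, floored at one day — the
data does not delimit cluster periods, so the whole observed CH span is
used. The TTH infrequent/frequent split depends only on episode frequency,
not on episode characteristics, so it is collapsed: the frequency is
reported, never used to split the candidate. "Not better accounted for by
another diagnosis" is always surfaced as NOT EVALUATED; it is a caution for
the clinician, never auto-resolved.

## 4. Timeline algorithms

* **Commute correction** — speed = great-circle (haversine) distance between
  the first and last GPS sample inside the activity interval ÷ the time
  between those samples; strictly above 25 km/h relabels the activity as
  commuting, changing only the activity-type field. Fewer than two samples:
  unchanged, logged. GPS accuracy estimates are ignored in this version.
* **Sedentary grouping** — maximal runs of sedentary-form activities
  (sedentary, sitting, standing, lying down) with inter-event gaps ≤ 60 s
  and a homogeneous confirmation state merge into one `sedentary` event
  spanning first start to last end. Idempotent; never merges across a
  non-sedentary event.
* **Stress-event admission** — newly detected periods are processed longest
  first (ties: earlier start) and admitted while the clock hour of their
  start holds < 2 and their calendar day < 10 automatic stress events,
  counting pre-existing ones. Bucketing by start time is the simplest
  deterministic reading of "per hour"/"per day"; the 2/hour and 10/day
  bounds then hold for any input by construction.
* **Stress notification** — due while `0 ≤ now − end ≤ 15 min`.
* **Location-mismatch flag** — the samples nearest the start and end of an
  automatic sedentary event more than 200 m apart (configurable) flag the
  event as a potential misprediction.
* **Sleep detection** — input is an activity-index series averaged over
  5-min epochs (the index itself is an input; for testing, a surrogate —
  epoch-wise mean absolute deviation of acceleration magnitude — and a
  direct trace generator are provided). A candidate rest period is a
  maximal run of below-threshold epochs that may embed above-threshold runs
  *strictly shorter than 1 h*; embedded runs are wake-up periods, a run of
  ≥ 1 h terminates the period. Periods spanning < 3 h (default; "a large
  period of rather low activity" is otherwise unquantified) are dropped.
  Sleep quality = 1 − (wake time ÷ in-bed time); a night is anomalous when
  its quality falls below the personal mean minus k·SD (k = 2 default, SD
  floored at 0.01 so a constant history still flags a drop, ≥ 3 nights of
  history required). The quality formula and anomaly rule are this
  package's own operational definitions, exposed in configuration.

## 5. Trigger detection

Detectors are pure functions of (timeline, reference time, configuration)
and are time-translation invariant. Defaults: exercise window 3 h, stress
windows 5 h/1 h (both taken from the documented example cases), relief 6 h,
sleep deprivation previous night, meals same day; all personalizable.

Only *confirmed* stress events with level ≥ 1 count as stress evidence
(level-0 corrections are semantically removals); manual stress
registrations count by construction. Commuting never counts as physical
exercise. The stress alarm reports both the event evidence and the total
overlapped stress minutes in the window — whether count or duration should
drive the alarm is an open question, so both are surfaced. The relief and
sleep-deprivation rules (a ≥ 60-min confirmed stress period ending within
6 h with quiet since; last night ≥ 90 min below the personal median, or a
missing night with history present) are operational definitions of this
package: no canonical rule exists for these triggers. Meal due times
default to 09:00/13:00/19:00 because the daily record stores only
taken/not-taken plus optional times. Indicated triggers outside the
detectable five are accepted in profiles and reported as not detectable.

`retrospective_support` runs each detector at the start time of every
attack tagged with that trigger and reports the supported fraction.

## 6. Synthetic cohort generator

The generator emulates the *structure* of a two-phenotype observational
cohort — it never claims to reproduce any study's exact counts. Defaults
(all configuration): 21-day trials; migraine patients with ≈ 8.7 attacks
per trial, log-normal durations with mean ≈ 6 h (SD ≈ 5.7 h), 73%
unilateral, migraine-typical symptom rates (photophobia 0.24, phonophobia
0.29, nausea 0.23, pulsating 0.35, …), 37%/14%/49%
successful/unsuccessful/untreated outcomes; CH patients with ≈ 7.5 attacks
per trial, log-normal durations with mean 50 min (SD 20 min), 100%
unilateral orbital/temporal zones, CAS- and restlessness-weighted symptoms,
93% successfully treated. Trigger indication rates are plausible values
(stress 0.15, sleep deprivation 0.10, …); the emulated tables report only
per-attack trigger *counts*, so per-trigger rates were chosen once to match
the overall ≈ 0.8 triggers/attack. Contextual streams: ≈ 40 automatic
activities/day (mostly sedentary), ≈ 6.7 stress periods/day with 45%
confirmed, nightly sleep of 8 ± 1 h going to bed around 23:00, sparse
background GPS at a per-patient home location, and daily records with an
occasional skipped lunch. When configured, evidence events (a running
activity, a confirmed stress period) are planted inside the detection
window before trigger-tagged attacks with probability `trigger_plant_p`.

Determinism: per-patient substreams are spawned from the root seed keyed by
patient index, so the same seed yields byte-identical output and extending
a cohort never reshuffles existing patients.

**Criterion-complete mode** constructs attacks that provably satisfy every
criterion a disorder requires under a chosen version (non-required criteria
sampled freely); **criterion-violating mode** makes exactly one named
criterion false while holding *every other* attack-level criterion of the
disorder true, so the attack is labelled under precisely the versions that
do not require the violated criterion. Violating a criterion the disorder
does not define raises.

What the generator does **not** emulate: raw physiological signals,
intra-individual attack heterogeneity beyond independent draws, symptom
co-occurrence structure (symptoms are independent Bernoullis), recall bias,
or interaction behaviour dynamics. Passing closed-loop tests on this data
therefore demonstrates the correctness of the rules, not clinical accuracy
on real diaries.

## 7. Numerical and interface choices

* Thresholds and comparisons: the commute rule is strictly greater-than;
  duration bounds and the sedentary 60-s gap are inclusive; wake-period
  length is strictly less than 1 h.
* Degenerate inputs: zero-length attacks are valid (0 min fails every
  duration band); empty cohorts produce zeroed reports; detectors return
  "no alarm" with a log entry when their inputs are insufficient, never an
  exception.
* The classifier is an in-process rule engine. The RDF export (one
  package-namespace resource per attack, event and classification, one
  property per field, lossless re-import for attacks and events) serves
  interoperability with graph-based tooling; it is not the execution path.
* Problem sizes in the test suite — the full 393 216-attack enumeration for
  the exhaustive checks, 10⁵ random attacks for version nesting, 10³
  closed-loop attacks per (disorder, version), 10³ adversarial admission
  runs, 10⁴ attacks for distribution-recovery checks — were chosen to make
  the structural claims exhaustive where the space is enumerable and
  statistically comfortable elsewhere.

## 8. Limitations

* The classifier sees only registration fields; contextual events do not
  yet inform classification.
* "Probable" disorder categories are not implemented; attacks failing one
  criterion receive simply fewer labels.
* The CH frequency criterion is evaluated over the whole observation span,
  not per cluster period.
* Sleep detection assumes a contiguous, equally spaced activity-index
  series per night; data gaps must be handled upstream.
* The activity-index thresholds are configuration with documented defaults;
  no canonical values are claimed.
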