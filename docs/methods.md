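# Methods

## The problem

Nearly all patients on maintenance hemodialysis develop some manifestation of
chronic kidney disease–mineral and bone disorder (CKD–MBD): dysregulated
parathyroid hormone (PTH), serum phosphate, and calcium, entangled with bone
disease and vascular calcification. Clinicians steer these three analytes into
guideline target ranges with a small formulary — a calcimimetic (cinacalcet),
active vitamin D sterols (calcitriol, paricalcitol, alfacalcidol), calcium-based
and non-calcium-based phosphate binders, and the dialysate calcium
concentration — where a drug that fixes one analyte routinely pushes another
out of range. This package implements a hybrid recommender for that dosing
problem: an expert domain model supplies the class-level action, and past
cases with good outcomes supply the dose numbers.

## The model

**Patient typing.** A yearly imaging work-up grades vascular calcification 0–24
on the abdominal aorta and notes valvular calcification as present/absent.
Patients with valvular involvement or a vascular score > 5 are *type-I* and get
a strict PTH target (150–300 pg/mL); all others are *type-II* with a lenient
target (130–600 pg/mL). Phosphate (3.5–5.5 mg/dL) and albumin-corrected
calcium (7.5–10.2 mg/dL) targets are shared. Calcium is corrected with the
Payne formula, `total + 0.8 × (4.0 − albumin)`; the coefficients live in the
knowledge pack.

**State space and partitions.** At each monthly encounter every analyte is
classified into one of six states: a level (*below / within / above* the
type-scoped range, bounds inclusive — the rule base is deliberately crisp at
the edges) and a trend (*increased / not increased* versus the previous
measurement). The full state space is therefore 2 patient types × 6³ analyte
states = 432 combinations, and compiling the model to grounded IF–THEN
production rules yields exactly 432 rules. A partition table tiles those 432
combinations into 33 mutually exclusive, jointly exhaustive patient groups,
each carrying one generic directive per management class (start/increase,
as-it-is, decrease/stop, consider, and ±0.25 mmol/L moves for dialysate
calcium).

The bundled 33-group table is a *reconstruction*: the original expert table is
not publicly available, so the pack authors one from KDIGO-style management
logic (high PTH → calcimimetic up, vitamin D off when calcium or phosphate is
high; high phosphate → binder up, with calcium-based binders stopped under
hypercalcemia; dialysate calcium follows serum calcium). Type-I uses 18 groups
(PTH level × calcium level × phosphate above-vs-not), type-II uses 15 (the
phosphate split is dropped where calcium is high), totalling 33. The
reconstructed predicates do not discriminate on trend — trends remain part of
the state space and of every compiled rule antecedent, which is the only
factorization consistent with both the 432-rule count and the
current-plus-previous input requirement. The pack is plain YAML; editing the
partitions, ranges, or formulary requires no code changes, and the validator
re-checks distinctness, exclusivity/exhaustiveness over the full grid,
directive vocabulary, and formulary sanity.

**Outcome scoring (PII).** Each encounter becomes a case: problem = the typed
lab state, solution = the 10-factor prescription written that day. The case's
outcome is the Patient Improvement Indicator,

    PII = (1/m) Σᵢ Cᵢ ,  m = 3,

where `Cᵢ` indicates that analyte *i* is inside its type-scoped target range at
the *subsequent* encounter — the efficacy of a prescription is visible only in
the next panel. The codomain is {0, ⅓, ⅔, 1}. Last or single encounters, and
encounters whose subsequent panel is incomplete, are *corner cases* with no
PII (never partially scored: m is fixed at 3).

**Retrieval and adaptation.** A new encounter is typed, classified, and
assigned its partition; similar cases are exactly the non-corner cases of that
partition and patient type, and *reference cases* are those with PII > 0. Per
class, the most frequently used medication among the references is selected
(ties by formulary order) and the interquartile range (Q1–Q3, linear
interpolation by default; Tukey hinges available) of its reference doses
becomes the recommended bounds. The class directive then constrains the range
relative to the patient's standing regimen (the previous encounter's
prescription): *stop* forces 0–0; *start/increase* uses positive reference
doses only and floors the range at one dose step and at the standing dose;
*decrease(-or-stop)* caps it below the standing dose (lower bound 0 when
stopping is allowed); *as-it-is* and *consider* widen the range to bracket the
standing dose — "as it is" must admit the dose the patient is already on, and
"consider" never initiates. Bounds are snapped outward to each medication's
dose step and clamped to its formulary reference range. Dialysate calcium maps
the standing concentration ±0.25 mmol/L (or unchanged), clamped to
{1.25, 1.5, 1.75} mmol/L. Two degenerate paths mirror the clinical workflow:
exactly one reference case is echoed unmodified, and an empty partition yields
a directive-only recommendation with an explicit fallback flag rather than
synthetic dosing.

**Evaluation.** Dosage concordance is the mean, over the factors carried by a
recommendation (10 when complete), of the indicator that the clinician's
prescribed dose lies inside the recommended range. Report-level tallies follow
the total / present / in-range / out-of-range layout; a medication counts as
*present* when the clinician prescribed it at a positive dose or the system
recommended a positive range (configurable to clinician-only), and medications
with zero present cases are excluded from the overall average. Directive
compliance compares the system's class directive with the clinician's observed
action between consecutive encounters — dose deltas are snapped to the dose
step and summed per class normalized by the reference maximum, then labelled
start/increase, maintain, or stop/decrease — and is reported as per-class 3×3
confusion matrices.

## The synthetic cohort

Real encounter data are not redistributable, so the `cohort` module generates
cohorts with the statistical shape the pipeline assumes: 66 patients, up to 13
monthly encounters (~850 cases), a 44 % type-I patient fraction, and quarterly
PTH draws carried forward between measurements (the chart value, not the
latent value, drives partitioning — so monitoring lag is emulated too).

Lab dynamics are linear-Gaussian: monthly,
`next = current + Σ_class effect × normalized dose + N(0, σ)`, clipped to
physiologic bounds, with signed effects fixed by standard pharmacology
(calcimimetics ↓PTH ↓Ca; vitamin D sterols ↓PTH ↑Ca ↑P; calcium-based binders
↓P ↑Ca; non-calcium binders ↓P; dialysate calcium ↑Ca per step above
1.25 mmol/L). Default noise levels (PTH 25 pg/mL, phosphate 0.4 mg/dL, calcium
0.25 mg/dL, albumin 0.05 g/dL per month) are order-of-magnitude choices; real
per-analyte variability is not publicly documented, and all of this is exposed
in `CohortConfig`.

The simulated clinician follows the knowledge base's directive for the current
partition with probability `adherence_prob` (default 0.9), otherwise
substituting *maintain* — mirroring the real-world reluctance to escalate
binders. The policy titrates to a fixed per-medication standard dose:
start/increase saturates at that dose, decrease/stop discontinues, and
first-line medications are used per class by default (`second_line_prob`
raises alternates). This deliberate simplification gives the generator an
analytically recoverable planted truth: with `adherence_prob = 1` and zero
noise, every positive dose of a medication equals its standard dose, so
held-out directives match the generator's exactly and every adapted
recommendation range contains the clinician's dose (overall concordance 1.0).
With default noise and partial adherence the concordance degrades smoothly.

What passing these tests does **not** show: the generator has no
pharmacokinetics, no inter-drug interactions, no dose–response saturation, no
missing-visit structure, and clinician variability far simpler than real
prescribing. Recovery results demonstrate internal consistency of the
pipeline, not clinical performance; published concordance on real hospital
data (overall ≈ 78 % there) is not reproducible without that dataset.

## Evaluation protocol and problem sizes

`run_evaluation` holds out the chronologically latest encounters (by encounter
index; a 600/250-style split is the default exercise), builds the case base
from the rest, recommends for each held-out encounter, and scores it against
the clinician's actual prescription. Per-medication concordance tallies cover
*adapted* recommendations (≥ 2 reference cases); single-reference passthroughs
and empty-partition fallbacks are counted and reported separately — an echoed
foreign prescription is by construction another patient's regimen, and a
fallback has no ranges to score. Nothing is dropped silently: the summary
reports `n_adapted`, `n_passthrough`, and `n_fallback` alongside the score.

Test and acceptance runs use cohorts of ~850 encounters and oracle sweeps of
10⁴ random draws; the full suite runs in a few seconds on one CPU.

## Numerical choices and edge cases

* Quartiles: NumPy linear interpolation by default, pinned in tests against an
  independent sorted-position oracle; Tukey hinges as the alternative.
* Dose snapping: bounds round *outward* to the dose step (floor/ceil), so
  snapping never loses containment; ranges are then clamped to the formulary
  reference range.
* First encounter: no previous panel → trend `not_increased`; no standing
  regimen → all-zero prescription with dialysate at 1.25 mmol/L.
* Missing PTH rows (quarterly draws) are carried forward at ingest; a missing
  first value is an ingestion error.
* Range bounds and in-range membership are inclusive at both ends; dose
  comparisons use a 1e-9 tolerance to absorb float noise.
* The directive vocabulary is per-class; "stop" for the vitamin-D-analog class
  is admitted alongside "decrease or stop" so the classic severe-case
  directive set is expressible.

## Known limitations

* The 33-group table is a documented reconstruction, not the original expert
  content; conclusions about specific group directives transfer only to packs
  with the same logic.
* The "consider" directive has no established semantics; maintain-if-present /
  never-initiate is this package's choice and is flagged in provenance.
* Concordance on synthetic data bounds nothing about real prescribing.
* No drug–drug interaction checking, renal dose scaling beyond the formulary
  ranges, or free-text prescription parsing.
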