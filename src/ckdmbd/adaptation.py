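"""Case adaptation: from generic directives + reference cases to dosage ranges.

The partition's directive set fixes the class-level action (start/increase,
maintain, decrease/stop, ...).  Reference cases supply the evidence for the
numbers: within each class the most frequently used medication is selected and
the interquartile range (Q1-Q3) of its reference doses becomes the recommended
lower/upper bound.  The directive then acts as a constraint on that range
relative to the patient's standing dose:

* ``stop``             -> 0-0 for every medication of the class
* ``maintain``         -> IQR widened to bracket the standing dose ("as it is")
* ``start_or_increase``-> IQR over positive reference doses, floored at one
                          dose step and at the standing dose
* ``decrease(_or_stop)``-> IQR capped below the standing dose (lower bound 0
                          when stopping is allowed)
* ``consider``         -> no initiation; treated as maintain when the patient
                          is already on a medication of the class
* dialysate            -> standing concentration +/- 0.25 mmol/L or unchanged,
                          clamped to the deliverable concentrations

All bounds are snapped outward to the medication's dose step and clamped to
its formulary reference range.  Two degenerate paths mirror the clinical
workflow: a single reference case is passed through unmodified, and an empty
partition yields a directive-only recommendation flagged as a fallback.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .cases import (
    CaseBase,
    ClinicalCase,
    DIALYSATE_LEVELS,
    Encounter,
    LabPanel,
    Prescription,
    retrieve_partition_cases,
    select_reference_cases,
)
from .knowledge import (
    Analyte,
    Directive,
    GenericDirectiveSet,
    InputValidationError,
    KnowledgeBase,
    ManagementClass,
    MedicationSpec,
    assign_partition,
    classify_patient_type,
    lab_states,
)

_MED_CLASSES = (
    ManagementClass.CALCIMIMETICS,
    ManagementClass.CALCITRIOL,
    ManagementClass.VITAMIN_D_ANALOGS,
    ManagementClass.CPB,
    ManagementClass.NCPB,
)


class DosageRange(BaseModel):
    medication: str
    lower: float = Field(ge=0)
    upper: float
    unit: str

    def contains(self, dose: float) -> bool:
        return self.lower - 1e-9 <= dose <= self.upper + 1e-9


class Provenance(BaseModel):
    reference_case_count: int = 0
    single_reference_passthrough: bool = False
    fallback_empty_partition: bool = False
    fallback_classes: list[str] = Field(default_factory=list)
    considered_no_initiation: list[str] = Field(default_factory=list)


class Recommendation(BaseModel):
    """Directives plus per-medication dosage ranges for one encounter."""

    partition_id: str
    patient_type: str
    directive_set: GenericDirectiveSet
    dosage_ranges: dict[str, DosageRange] = Field(default_factory=dict)
    provenance: Provenance = Field(default_factory=Provenance)

    def range_for(self, medication: str) -> Optional[DosageRange]:
        return self.dosage_ranges.get(medication)


def estimate_dosage_range(
    doses: Sequence[float], method: str = "linear"
) -> tuple[float, float]:
    """(Q1, Q3) of a dose list.

    ``method`` selects the quartile estimator: ``linear`` interpolation (the
    default) or ``tukey`` hinges (``median_unbiased`` is accepted too).  A
    single-element list returns the degenerate range (d, d).
    """
    if len(doses) == 0:
        raise InputValidationError("cannot estimate a dosage range from an empty dose list")
    arr = np.asarray(doses, dtype=float)
    if arr.min() < 0:
        raise InputValidationError("doses must be non-negative")
    if method == "tukey":
        lower, upper = _tukey_hinges(arr)
    elif method in {"linear", "median_unbiased"}:
        lower, upper = np.percentile(arr, [25, 75], method=method)
    else:
        raise InputValidationError(f"unknown quartile method {method!r}")
    return float(lower), float(upper)


def _tukey_hinges(arr: np.ndarray) -> tuple[float, float]:
    s = np.sort(arr)
    n = len(s)
    half = (n + 1) // 2
    return float(np.median(s[:half])), float(np.median(s[n - half:]))


def select_medication_within_class(
    reference_cases: Sequence[ClinicalCase],
    mclass: ManagementClass,
    kb: KnowledgeBase,
) -> tuple[MedicationSpec, int]:
    """Most frequently (positively) prescribed medication of a class among
    the reference cases.

    Returns ``(spec, usage_count)``.  Ties break by formulary declaration
    order; a count of 0 means no reference case used the class at all and the
    first formulary entry is returned as a fallback.
    """
    meds = kb.medications_in_class(mclass)
    if not meds:
        raise InputValidationError(f"no formulary medications in class {mclass.value}")
    counts = [sum(1 for c in reference_cases if c.solution.dose(m.name) > 0) for m in meds]
    best = max(range(len(meds)), key=lambda i: (counts[i], -i))
    return meds[best], counts[best]


def _snap(lower: float, upper: float, med: MedicationSpec) -> tuple[float, float]:
    """Round bounds outward to the dose step, then clamp to the reference range."""
    step = med.dose_step
    lo = math.floor(lower / step + 1e-9) * step
    hi = math.ceil(upper / step - 1e-9) * step
    lo = min(max(lo, med.low), med.high)
    hi = min(max(hi, med.low), med.high)
    if lo > hi:
        lo = hi
    return round(lo, 10), round(hi, 10)


def _class_ranges(
    directive: Directive,
    meds: Sequence[MedicationSpec],
    selected: MedicationSpec,
    selected_used: int,
    reference_cases: Sequence[ClinicalCase],
    current: Prescription,
    method: str,
    provenance: Provenance,
) -> dict[str, DosageRange]:
    out: dict[str, DosageRange] = {}
    for med in meds:
        cur = current.dose(med.name)
        if directive is Directive.STOP:
            lo, hi = 0.0, 0.0
        elif directive in (Directive.MAINTAIN, Directive.CONSIDER):
            if med.name == selected.name and selected_used > 0:
                q1, q3 = estimate_dosage_range(
                    [c.solution.dose(med.name) for c in reference_cases], method
                )
            else:
                q1 = q3 = 0.0
            if directive is Directive.CONSIDER and cur == 0:
                # "Consider" never initiates; record that the option was open.
                if med.name == selected.name:
                    provenance.considered_no_initiation.append(med.name)
                lo, hi = 0.0, 0.0
            else:
                lo, hi = min(q1, cur), max(q3, cur)
        elif directive is Directive.START_OR_INCREASE:
            if med.name == selected.name:
                positive = [
                    c.solution.dose(med.name)
                    for c in reference_cases
                    if c.solution.dose(med.name) > 0
                ]
                if positive:
                    q1, q3 = estimate_dosage_range(positive, method)
                else:
                    q1 = q3 = med.dose_step
                    provenance.fallback_classes.append(med.management_class.value)
                lo = max(q1, med.dose_step, cur)
                hi = max(q3, lo)
            else:
                lo, hi = 0.0, cur
        elif directive in (Directive.DECREASE, Directive.DECREASE_OR_STOP):
            if cur == 0:
                lo, hi = 0.0, 0.0
            else:
                if med.name == selected.name and selected_used > 0:
                    q1, q3 = estimate_dosage_range(
                        [c.solution.dose(med.name) for c in reference_cases], method
                    )
                else:
                    q1 = q3 = 0.0
                hi = max(min(q3, cur - med.dose_step), 0.0)
                lo = 0.0 if directive is Directive.DECREASE_OR_STOP else min(q1, hi)
        else:  # pragma: no cover - vocabulary enforced upstream
            raise InputValidationError(
                f"directive {directive.value!r} is not valid for medication class"
            )
        lo, hi = _snap(lo, hi, med)
        out[med.name] = DosageRange(medication=med.name, lower=lo, upper=hi, unit=med.unit)
    return out


def _dialysate_range(
    directive: Directive, current_concentration: float, med: MedicationSpec
) -> DosageRange:
    if directive is Directive.INCREASE_0_25:
        value = current_concentration + 0.25
    elif directive is Directive.REDUCE_0_25:
        value = current_concentration - 0.25
    elif directive is Directive.MAINTAIN:
        value = current_concentration
    else:  # pragma: no cover
        raise InputValidationError(f"directive {directive.value!r} invalid for dialysate")
    value = min(max(value, DIALYSATE_LEVELS[0]), DIALYSATE_LEVELS[-1])
    return DosageRange(medication=med.name, lower=value, upper=value, unit=med.unit)


def adapt(
    directives: GenericDirectiveSet,
    reference_cases: Sequence[ClinicalCase],
    kb: KnowledgeBase,
    current_regimen: Prescription,
    partition_id: str,
    patient_type: str,
    quartile_method: str = "linear",
) -> Recommendation:
    """Combine a partition's directives with reference-case dosing evidence.

    ``current_regimen`` is the prescription the patient arrives on (the
    previous encounter's solution), which the directive constraints are
    anchored to.
    """
    provenance = Provenance(reference_case_count=len(reference_cases))

    if not reference_cases:
        provenance.fallback_empty_partition = True
        return Recommendation(
            partition_id=partition_id,
            patient_type=patient_type,
            directive_set=directives,
            dosage_ranges={},
            provenance=provenance,
        )

    if len(reference_cases) == 1:
        # A single available case is handed to the physician unmodified.
        provenance.single_reference_passthrough = True
        echo = reference_cases[0].solution
        ranges = {
            med.name: DosageRange(
                medication=med.name,
                lower=echo.dose(med.name),
                upper=echo.dose(med.name),
                unit=med.unit,
            )
            for med in kb.formulary
        }
        return Recommendation(
            partition_id=partition_id,
            patient_type=patient_type,
            directive_set=directives,
            dosage_ranges=ranges,
            provenance=provenance,
        )

    ranges: dict[str, DosageRange] = {}
    for mclass in _MED_CLASSES:
        directive = directives.for_class(mclass)
        meds = kb.medications_in_class(mclass)
        selected, used = select_medication_within_class(reference_cases, mclass, kb)
        if used == 0 and directive is Directive.START_OR_INCREASE:
            provenance.fallback_classes.append(mclass.value)
        ranges.update(
            _class_ranges(
                directive,
                meds,
                selected,
                used,
                reference_cases,
                current_regimen,
                quartile_method,
                provenance,
            )
        )

    dialysate_med = kb.medications_in_class(ManagementClass.DIALYSATE)[0]
    ranges[dialysate_med.name] = _dialysate_range(
        directives.for_class(ManagementClass.DIALYSATE),
        current_regimen.dialysate_calcium,
        dialysate_med,
    )
    # keep provenance lists deterministic and duplicate-free
    provenance.fallback_classes = sorted(set(provenance.fallback_classes))
    provenance.considered_no_initiation = sorted(set(provenance.considered_no_initiation))
    ordered = {
        med.name: ranges[med.name] for med in kb.formulary if med.name in ranges
    }
    return Recommendation(
        partition_id=partition_id,
        patient_type=patient_type,
        directive_set=directives,
        dosage_ranges=ordered,
        provenance=provenance,
    )


def recommend(
    case_base: CaseBase,
    kb: KnowledgeBase,
    encounter: Encounter,
    previous: Optional[Encounter] = None,
    quartile_method: str = "linear",
) -> Recommendation:
    """End-to-end recommendation for one encounter.

    Pipeline: patient typing -> lab-state classification (trends against the
    previous encounter when available) -> partition assignment -> directive
    lookup -> similar-case retrieval -> PII > 0 reference selection ->
    adaptation.  Pure function of its inputs.
    """
    ptype = classify_patient_type(encounter.calcification, kb.type_threshold)
    panel = encounter.labs.with_corrected_calcium(kb)
    if not panel.is_complete():
        raise InputValidationError(
            f"encounter {encounter.mrn}/{encounter.sequence_index} has an incomplete panel"
        )
    prev_values = None
    if previous is not None:
        prev_values = previous.labs.with_corrected_calcium(kb).analyte_values()
    states = lab_states(kb, ptype, panel.analyte_values(), prev_values)
    partition_id = assign_partition(kb, ptype, states)
    directives = kb.directives_for_partition(partition_id)

    probe = ClinicalCase(
        mrn=encounter.mrn,
        sequence_index=encounter.sequence_index,
        patient_type=ptype,
        states=states,
        labs=panel,
        solution=encounter.prescription,
        partition_id=partition_id,
        pii=None,
    )
    similar = retrieve_partition_cases(case_base, probe)
    references = select_reference_cases(similar)
    current_regimen = previous.prescription if previous is not None else Prescription()
    return adapt(
        directives,
        references,
        kb,
        current_regimen,
        partition_id,
        ptype.value,
        quartile_method,
    )
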