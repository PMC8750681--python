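"""Longitudinal case base: encounters, outcome scoring, reference selection.

Each clinical case pairs a problem component (the patient's typed lab state at
one encounter) with a solution component (the prescription written at that
encounter).  The outcome of a case is the Patient Improvement Indicator (PII):
the fraction of the three controlled analytes (PTH, corrected calcium,
phosphate) that sit inside their type-scoped target ranges at the *subsequent*
encounter.  Cases without a subsequent encounter (or with an incomplete
subsequent panel) are corner cases and carry no PII.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from typing import ClassVar, Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, Field, field_validator

from .knowledge import (
    Analyte,
    CalcificationAssessment,
    InputValidationError,
    KnowledgeBase,
    LabState,
    PatientType,
    TargetRange,
    assign_partition,
    classify_patient_type,
    corrected_calcium,
    lab_states,
)

#: Dialysate fluid calcium concentrations the dialysis unit can deliver, mmol/L.
DIALYSATE_LEVELS = (1.25, 1.5, 1.75)


class LabPanel(BaseModel):
    """One encounter's laboratory panel.

    ``pth`` may be absent on non-measurement months (it is drawn quarterly);
    the ingest layer carries the last value forward.  ``corrected_calcium_mg_dl``
    is derived from total calcium and albumin with the knowledge base's
    correction coefficients.
    """

    encounter_date: dt.date
    pth: Optional[float] = Field(default=None, gt=0)
    phosphate: Optional[float] = Field(default=None, gt=0)
    total_calcium: Optional[float] = Field(default=None, gt=0)
    albumin: Optional[float] = Field(default=None, gt=0)
    corrected_calcium_mg_dl: Optional[float] = None

    def with_corrected_calcium(self, kb: KnowledgeBase) -> "LabPanel":
        if self.total_calcium is None or self.albumin is None:
            return self
        value = corrected_calcium(
            self.total_calcium,
            self.albumin,
            kb.corrected_calcium_reference_albumin,
            kb.corrected_calcium_coefficient,
        )
        return self.model_copy(update={"corrected_calcium_mg_dl": value})

    def analyte_values(self) -> dict[Analyte, Optional[float]]:
        return {
            Analyte.PTH: self.pth,
            Analyte.PHOSPHATE: self.phosphate,
            Analyte.CORRECTED_CALCIUM: self.corrected_calcium_mg_dl,
        }

    def is_complete(self) -> bool:
        return all(v is not None for v in self.analyte_values().values())


class Prescription(BaseModel):
    """The 10-factor solution component: nine medications plus the dialysate
    calcium concentration."""

    cinacalcet: float = Field(default=0.0, ge=0)          # mg/day
    calcitriol_po: float = Field(default=0.0, ge=0)       # ug/day
    calcitriol_iv: float = Field(default=0.0, ge=0)       # ug/week
    paricalcitol_iv: float = Field(default=0.0, ge=0)     # ug/week
    alfacalcidol: float = Field(default=0.0, ge=0)        # ug/day
    calcium_carbonate: float = Field(default=0.0, ge=0)   # mg/day
    calcium_acetate: float = Field(default=0.0, ge=0)     # mg/day
    sevelamer: float = Field(default=0.0, ge=0)           # mg/day
    lanthanum: float = Field(default=0.0, ge=0)           # mg/day
    dialysate_calcium: float = 1.25                       # mmol/L

    FACTORS: ClassVar[tuple[str, ...]] = (
        "cinacalcet",
        "calcitriol_po",
        "calcitriol_iv",
        "paricalcitol_iv",
        "alfacalcidol",
        "calcium_carbonate",
        "calcium_acetate",
        "sevelamer",
        "lanthanum",
        "dialysate_calcium",
    )

    @field_validator("dialysate_calcium")
    @classmethod
    def _admissible_concentration(cls, v: float) -> float:
        if not any(abs(v - lvl) < 1e-9 for lvl in DIALYSATE_LEVELS):
            raise ValueError(f"dialysate calcium must be one of {DIALYSATE_LEVELS}, got {v}")
        return v

    def dose(self, factor: str) -> float:
        if factor not in self.FACTORS:
            raise InputValidationError(f"unknown prescription factor {factor!r}")
        return getattr(self, factor)

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FACTORS}


class Encounter(BaseModel):
    mrn: str
    sequence_index: int = Field(ge=1)
    labs: LabPanel
    calcification: CalcificationAssessment
    prescription: Prescription


class ClinicalCase(BaseModel):
    """Problem + solution + partition + outcome for one encounter."""

    mrn: str
    sequence_index: int
    patient_type: PatientType
    states: dict[Analyte, LabState]
    labs: LabPanel
    solution: Prescription
    partition_id: str
    pii: Optional[float] = None  # None marks a corner case

    @property
    def is_corner(self) -> bool:
        return self.pii is None


class CaseBase(BaseModel):
    """Cases indexed by partition.  ``n`` per partition counts the similar
    (non-corner) cases available; the reference subset after outcome filtering
    is always a subset of those."""

    cases: list[ClinicalCase] = Field(default_factory=list)

    def by_partition(self, partition_id: str) -> list[ClinicalCase]:
        return [c for c in self.cases if c.partition_id == partition_id]

    def partition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for c in self.cases:
            counts[c.partition_id] += 1
        return dict(counts)

    def __len__(self) -> int:
        return len(self.cases)


class IngestionError(ValueError):
    """The encounter table violates per-patient sequencing constraints."""


def compute_pii(
    next_labs: LabPanel,
    patient_type: PatientType,
    kb: KnowledgeBase,
) -> Optional[float]:
    """Patient Improvement Indicator: mean of three in-range indicators.

    Scores the prescription written at encounter *i* using the panel drawn at
    encounter *i + 1*.  Each of the m = 3 analytes contributes 1 if it lies
    inside its (type-scoped, inclusive) target range, else 0; the PII is the
    mean, so its codomain is {0, 1/3, 2/3, 1}.  Returns ``None`` (the
    corner-case marker) when any analyte is missing.
    """
    values = next_labs.analyte_values()
    if any(v is None for v in values.values()):
        return None
    hits = 0
    for analyte, value in values.items():
        rng = kb.range_for(analyte, patient_type)
        hits += int(rng.contains(value))
    return hits / len(values)


def _sorted_history(encounters: Iterable[Encounter]) -> dict[str, list[Encounter]]:
    per_mrn: dict[str, list[Encounter]] = defaultdict(list)
    for enc in encounters:
        per_mrn[enc.mrn].append(enc)
    for mrn, encs in per_mrn.items():
        encs.sort(key=lambda e: e.sequence_index)
        seen = [e.sequence_index for e in encs]
        if len(set(seen)) != len(seen):
            raise IngestionError(f"duplicate (mrn, sequence_index) for {mrn}: {seen}")
        if seen != list(range(1, len(seen) + 1)):
            raise IngestionError(
                f"sequence indices for {mrn} must be contiguous from 1, got {seen}"
            )
    return per_mrn


def build_case_base(encounters: Sequence[Encounter], kb: KnowledgeBase) -> CaseBase:
    """Turn longitudinal encounters into a partition-indexed case base.

    One case per encounter: the partition comes from the domain model applied
    to the current (and previous, for trends) panel; the PII comes from the
    next panel of the same patient.  Last or single encounters become corner
    cases.
    """
    cases: list[ClinicalCase] = []
    for mrn, history in _sorted_history(encounters).items():
        panels = [e.labs.with_corrected_calcium(kb) for e in history]
        for i, enc in enumerate(history):
            panel = panels[i]
            if not panel.is_complete():
                raise IngestionError(
                    f"incomplete lab panel for {mrn} encounter {enc.sequence_index}"
                )
            ptype = classify_patient_type(enc.calcification, kb.type_threshold)
            prev_values = panels[i - 1].analyte_values() if i > 0 else None
            states = lab_states(kb, ptype, panel.analyte_values(), prev_values)
            partition_id = assign_partition(kb, ptype, states)
            pii = compute_pii(panels[i + 1], ptype, kb) if i + 1 < len(history) else None
            cases.append(
                ClinicalCase(
                    mrn=mrn,
                    sequence_index=enc.sequence_index,
                    patient_type=ptype,
                    states=states,
                    labs=panel,
                    solution=enc.prescription,
                    partition_id=partition_id,
                    pii=pii,
                )
            )
    return CaseBase(cases=cases)


def retrieve_partition_cases(case_base: CaseBase, test_case: ClinicalCase) -> list[ClinicalCase]:
    """All similar cases: same partition and patient type, outcome defined.

    Corner cases are excluded (they carry no outcome and cannot qualify as
    references).  An empty result is legal; downstream adaptation falls back
    to a directive-only recommendation.
    """
    return [
        c
        for c in case_base.by_partition(test_case.partition_id)
        if c.patient_type is test_case.patient_type and not c.is_corner
    ]


def select_reference_cases(similar: Sequence[ClinicalCase]) -> list[ClinicalCase]:
    """Keep only cases whose outcome improved: PII strictly greater than 0."""
    for c in similar:
        if c.pii is None:
            raise InputValidationError(
                f"case {c.mrn}/{c.sequence_index} has undefined PII; "
                "corner cases cannot be reference candidates"
            )
    return [c for c in similar if c.pii > 0]
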