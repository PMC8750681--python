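"""Scoring system output against clinician prescriptions.

Two complementary views:

* **Dosage concordance** - per encounter, the fraction of recommendation
  factors whose clinician-prescribed dose falls inside the recommended range;
  aggregated per medication as in-range / present tallies and averaged across
  medications (medications with zero present cases are excluded from the
  average).
* **Directive compliance** - per management class, a 3x3 confusion matrix of
  the system's class-level directive against the clinician's observed action
  (start/increase, maintain, stop/decrease) between consecutive encounters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .adaptation import DosageRange, Recommendation
from .cases import Prescription
from .knowledge import (
    Directive,
    InputValidationError,
    KnowledgeBase,
    ManagementClass,
)


class DirectiveLabel(str, enum.Enum):
    START_INCREASE = "start_increase"
    MAINTAIN = "maintain"
    STOP_DECREASE = "stop_decrease"


LABELS = tuple(DirectiveLabel)

#: Collapse the generic directive vocabulary onto the three observable actions.
_DIRECTIVE_TO_LABEL = {
    Directive.START_OR_INCREASE: DirectiveLabel.START_INCREASE,
    Directive.INCREASE_0_25: DirectiveLabel.START_INCREASE,
    Directive.MAINTAIN: DirectiveLabel.MAINTAIN,
    Directive.CONSIDER: DirectiveLabel.MAINTAIN,
    Directive.DECREASE: DirectiveLabel.STOP_DECREASE,
    Directive.DECREASE_OR_STOP: DirectiveLabel.STOP_DECREASE,
    Directive.STOP: DirectiveLabel.STOP_DECREASE,
    Directive.REDUCE_0_25: DirectiveLabel.STOP_DECREASE,
}


def directive_label(directive: Directive) -> DirectiveLabel:
    return _DIRECTIVE_TO_LABEL[directive]


def dosage_in_range(prescribed: float, dosage_range: DosageRange, unit: Optional[str] = None) -> bool:
    """Inclusive membership of a prescribed dose in a recommended range."""
    if unit is not None and unit != dosage_range.unit:
        raise InputValidationError(
            f"unit mismatch: prescription in {unit!r}, range in {dosage_range.unit!r}"
        )
    return dosage_range.contains(prescribed)


def concordance(recommendation: Recommendation, prescription: Prescription) -> Optional[float]:
    """Per-encounter dosage concordance.

    The mean, over the j factors carried by the recommendation (10 for a
    complete one), of the indicator that the clinician's dose lies inside the
    recommended range.  A recommendation without dosage ranges (empty-partition
    fallback) is not scoreable and returns ``None`` rather than 0.
    """
    ranges = recommendation.dosage_ranges
    if not ranges:
        return None
    hits = sum(
        int(dosage_in_range(prescription.dose(name), rng)) for name, rng in ranges.items()
    )
    return hits / len(ranges)


def derive_directive(
    previous: Prescription,
    current: Prescription,
    mclass: ManagementClass,
    kb: KnowledgeBase,
) -> DirectiveLabel:
    """Observed clinician action for one class between consecutive encounters.

    Doses are snapped to each medication's dose step before comparison, and
    summed over the class normalized by the reference maximum so that a switch
    within the class still registers as a net change.
    """
    meds = kb.medications_in_class(mclass)
    if not meds:
        raise InputValidationError(f"no medications in class {mclass.value}")

    def class_load(rx: Prescription) -> float:
        total = 0.0
        for med in meds:
            dose = rx.dose(med.name)
            snapped = round(dose / med.dose_step) * med.dose_step
            total += snapped / med.high
        return total

    before, after = class_load(previous), class_load(current)
    if abs(after - before) < 1e-9:
        return DirectiveLabel.MAINTAIN
    return DirectiveLabel.START_INCREASE if after > before else DirectiveLabel.STOP_DECREASE


@dataclass
class ComplianceMatrix:
    """3x3 counts of (system directive label x clinician action label)."""

    management_class: str
    matrix: pd.DataFrame

    @classmethod
    def from_pairs(
        cls, management_class: str, pairs: Iterable[tuple[DirectiveLabel, DirectiveLabel]]
    ) -> "ComplianceMatrix":
        idx = [l.value for l in LABELS]
        m = pd.DataFrame(0, index=idx, columns=idx, dtype=int)
        m.index.name = "system"
        m.columns.name = "clinician"
        for system, clinician in pairs:
            if not isinstance(system, DirectiveLabel) or not isinstance(clinician, DirectiveLabel):
                raise InputValidationError("labels must be DirectiveLabel values")
            m.loc[system.value, clinician.value] += 1
        return cls(management_class=management_class, matrix=m)

    @property
    def total(self) -> int:
        return int(self.matrix.values.sum())

    @property
    def compliance_rate(self) -> Optional[float]:
        if self.total == 0:
            return None
        return float(np.trace(self.matrix.values) / self.total)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for system in self.matrix.index:
            for clinician in self.matrix.columns:
                rows.append(
                    {
                        "management_class": self.management_class,
                        "system": system,
                        "clinician": clinician,
                        "count": int(self.matrix.loc[system, clinician]),
                    }
                )
        return pd.DataFrame(rows)


def compliance_matrix(
    management_class: str,
    pairs: Sequence[tuple[DirectiveLabel, DirectiveLabel]],
) -> ComplianceMatrix:
    return ComplianceMatrix.from_pairs(management_class, pairs)


@dataclass
class MedicationTally:
    medication: str
    total: int = 0
    present: int = 0
    in_range: int = 0

    @property
    def out_of_range(self) -> int:
        return self.present - self.in_range

    @property
    def concordance(self) -> Optional[float]:
        if self.present == 0:
            return None
        return self.in_range / self.present


@dataclass
class ConcordanceReport:
    """Per-medication in-range/out-of-range tallies plus the overall score.

    ``presence`` controls when a medication counts as present for an
    encounter: ``"either"`` (clinician prescribed a positive dose OR the
    system recommended a positive range - the default) or ``"clinician"``
    (positive prescription only).
    """

    tallies: dict[str, MedicationTally] = field(default_factory=dict)
    presence: str = "either"

    @property
    def overall(self) -> Optional[float]:
        scores = [t.concordance for t in self.tallies.values() if t.present > 0]
        if not scores:
            return None
        return float(np.mean(scores))

    def add(self, recommendation: Recommendation, prescription: Prescription) -> None:
        for name, rng in recommendation.dosage_ranges.items():
            tally = self.tallies.setdefault(name, MedicationTally(medication=name))
            tally.total += 1
            prescribed = prescription.dose(name)
            if self.presence == "either":
                present = prescribed > 0 or rng.upper > 0
            elif self.presence == "clinician":
                present = prescribed > 0
            else:
                raise InputValidationError(f"unknown presence convention {self.presence!r}")
            if present:
                tally.present += 1
                tally.in_range += int(dosage_in_range(prescribed, rng))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tallies.values():
            rows.append(
                {
                    "medication": t.medication,
                    "total_cases": t.total,
                    "present_cases": t.present,
                    "in_range_cases": t.in_range,
                    "out_of_range_cases": t.out_of_range,
                    "concordance_pct": None if t.concordance is None else round(100 * t.concordance, 2),
                }
            )
        return pd.DataFrame(rows)

    def as_dict(self) -> dict:
        return {
            "presence": self.presence,
            "overall_concordance": self.overall,
            "medications": self.to_frame().to_dict(orient="records"),
        }
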