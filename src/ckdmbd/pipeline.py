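"""End-to-end orchestration: hold-out evaluation of the recommender.

The split is chronological on the encounter index (later encounters held
out), mirroring prospective use: the case base is built from earlier
encounters only, and each held-out encounter is recommended against it and
scored against the clinician's actual prescription.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .adaptation import Recommendation, recommend
from .cases import CaseBase, Encounter, build_case_base
from .cohort import GroundTruthRecord
from .evaluation import (
    ComplianceMatrix,
    ConcordanceReport,
    DirectiveLabel,
    concordance,
    derive_directive,
    directive_label,
)
from .knowledge import InputValidationError, KnowledgeBase, ManagementClass, validate_knowledge_base

_CLASS_FIELDS = {
    ManagementClass.CALCIMIMETICS: "calcimimetics",
    ManagementClass.CALCITRIOL: "calcitriol",
    ManagementClass.VITAMIN_D_ANALOGS: "vitamin_d_analogs",
    ManagementClass.CPB: "CPB",
    ManagementClass.NCPB: "NCPB",
    ManagementClass.DIALYSATE: "dialysate_calcium",
}


@dataclass
class EvaluationResult:
    n_train: int
    n_test: int
    n_adapted: int = 0
    n_passthrough: int = 0
    n_fallback: int = 0
    report: ConcordanceReport = field(default_factory=ConcordanceReport)
    compliance: dict[str, ComplianceMatrix] = field(default_factory=dict)
    encounter_concordances: list[float] = field(default_factory=list)
    directive_matches: int = 0
    directive_evaluated: int = 0

    @property
    def overall_concordance(self) -> Optional[float]:
        return self.report.overall

    @property
    def directive_recovery_rate(self) -> Optional[float]:
        if self.directive_evaluated == 0:
            return None
        return self.directive_matches / self.directive_evaluated

    def summary(self) -> dict:
        return {
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_adapted": self.n_adapted,
            "n_passthrough": self.n_passthrough,
            "n_fallback": self.n_fallback,
            "overall_concordance": self.overall_concordance,
            "directive_recovery_rate": self.directive_recovery_rate,
            "per_class_compliance": {
                cls: m.compliance_rate for cls, m in self.compliance.items()
            },
        }


def chronological_split(
    encounters: Sequence[Encounter], n_test: int
) -> tuple[list[Encounter], list[Encounter]]:
    """Hold out the ``n_test`` chronologically latest encounters.

    Ordering is by sequence index (then patient id for determinism), so each
    patient's held-out encounters form a suffix of their history and the
    training histories stay contiguous.
    """
    if n_test < 0 or n_test > len(encounters):
        raise InputValidationError(
            f"test split of {n_test} is not within the {len(encounters)}-encounter table"
        )
    ordered = sorted(encounters, key=lambda e: (e.sequence_index, e.mrn))
    if n_test == 0:
        return list(ordered), []
    return ordered[:-n_test], ordered[-n_test:]


def run_evaluation(
    encounters: Sequence[Encounter],
    kb: KnowledgeBase,
    n_test: int,
    ground_truth: Optional[Sequence[GroundTruthRecord]] = None,
    presence: str = "either",
    quartile_method: str = "linear",
) -> EvaluationResult:
    """Build a case base from the earlier encounters, recommend for each
    held-out encounter, and score dosage concordance and directive compliance.

    Per-medication concordance tallies (and hence the overall score) cover
    adapted recommendations - those produced from two or more reference cases.
    Single-reference passthroughs and empty-partition fallbacks are counted
    separately: the passthrough echoes a foreign prescription by design and
    the fallback carries no ranges to score.  When generator ground truth is
    supplied, the system's class directives are additionally compared with the
    directives the simulated clinician actually applied, over all held-out
    encounters.
    """
    vr = validate_knowledge_base(kb)
    if not vr.passed:
        raise InputValidationError(f"knowledge base failed validation: {vr.as_dict()}")

    train, test = chronological_split(encounters, n_test)
    case_base = build_case_base(train, kb)

    by_key = {(e.mrn, e.sequence_index): e for e in encounters}
    gt_by_key = (
        {(g.mrn, g.sequence_index): g for g in ground_truth} if ground_truth else {}
    )

    result = EvaluationResult(n_train=len(train), n_test=len(test))
    result.report = ConcordanceReport(presence=presence)
    compliance_pairs: dict[str, list[tuple[DirectiveLabel, DirectiveLabel]]] = {
        f: [] for f in _CLASS_FIELDS.values()
    }

    for enc in test:
        previous = by_key.get((enc.mrn, enc.sequence_index - 1))
        rec = recommend(case_base, kb, enc, previous, quartile_method)

        if rec.provenance.fallback_empty_partition:
            result.n_fallback += 1
        elif rec.provenance.single_reference_passthrough:
            result.n_passthrough += 1
        else:
            result.n_adapted += 1
            result.report.add(rec, enc.prescription)
            c = concordance(rec, enc.prescription)
            if c is not None:
                result.encounter_concordances.append(c)

        if previous is not None:
            for mclass, fname in _CLASS_FIELDS.items():
                system = directive_label(rec.directive_set.for_class(mclass))
                clinician = derive_directive(
                    previous.prescription, enc.prescription, mclass, kb
                )
                compliance_pairs[fname].append((system, clinician))

        gt = gt_by_key.get((enc.mrn, enc.sequence_index))
        if gt is not None:
            result.directive_evaluated += 1
            system_directives = {
                fname: rec.directive_set.for_class(mclass).value
                for mclass, fname in _CLASS_FIELDS.items()
            }
            applied = {
                "calcimimetics": gt.applied_directives["calcimimetics"],
                "calcitriol": gt.applied_directives["calcitriol"],
                "vitamin_d_analogs": gt.applied_directives["vitamin_d_analogs"],
                "CPB": gt.applied_directives["CPB"],
                "NCPB": gt.applied_directives["NCPB"],
                "dialysate_calcium": gt.applied_directives["dialysate"],
            }
            if system_directives == applied:
                result.directive_matches += 1

    result.compliance = {
        fname: ComplianceMatrix.from_pairs(fname, pairs)
        for fname, pairs in compliance_pairs.items()
    }
    return result
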