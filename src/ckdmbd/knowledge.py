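"""Expert domain model for CKD-MBD management.

The domain model stratifies maintenance-hemodialysis patients by ectopic
calcification (patient type), classifies the three controlled analytes (PTH,
albumin-corrected calcium, phosphate) against type-scoped target ranges, and
assigns every patient state to one of 33 mutually exclusive partitions, each
carrying a generic per-medication-class directive set.  The model compiles to
IF-THEN production rules: 2 patient types x (3 levels x 2 trends)^3 analyte
states = 432 rules.

The bundled knowledge pack (``data/knowledge_pack.yaml``) is an editable
reconstruction of the expert partition table; all clinical content lives in
the pack, not in code.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class KnowledgeBaseError(Exception):
    """Base class for domain-model errors."""


class KnowledgePackParseError(KnowledgeBaseError):
    """The knowledge pack file could not be parsed against the schema."""


class RuleCompilationError(KnowledgeBaseError):
    """The partition predicates are not exclusive/exhaustive."""

    def __init__(self, message: str, offending: Sequence[tuple] = ()):  # noqa: D107
        super().__init__(message)
        self.offending = list(offending)


class PartitionIntegrityError(KnowledgeBaseError):
    """No partition matched a patient state (impossible for a validated KB)."""


class InputValidationError(KnowledgeBaseError, ValueError):
    """A caller-supplied clinical value is out of its admissible domain."""


class PatientType(str, enum.Enum):
    TYPE_I = "type-I"
    TYPE_II = "type-II"


class Analyte(str, enum.Enum):
    PTH = "PTH"
    PHOSPHATE = "phosphate"
    CORRECTED_CALCIUM = "corrected_calcium"


class Level(str, enum.Enum):
    BELOW = "below"
    WITHIN = "within"
    ABOVE = "above"


class Trend(str, enum.Enum):
    INCREASED = "increased"
    NOT_INCREASED = "not_increased"


class ManagementClass(str, enum.Enum):
    CALCIMIMETICS = "calcimimetics"
    CALCITRIOL = "calcitriol"
    VITAMIN_D_ANALOGS = "vitamin_d_analogs"
    CPB = "CPB"
    NCPB = "NCPB"
    DIALYSATE = "dialysate"


class Directive(str, enum.Enum):
    START_OR_INCREASE = "start_or_increase"
    MAINTAIN = "maintain"  # "As it is"
    DECREASE = "decrease"
    DECREASE_OR_STOP = "decrease_or_stop"
    STOP = "stop"
    CONSIDER = "consider"
    INCREASE_0_25 = "increase_0.25"
    REDUCE_0_25 = "reduce_0.25"


#: Directive vocabulary per management class (generic recommendation template).
ALLOWED_DIRECTIVES: dict[ManagementClass, frozenset[Directive]] = {
    ManagementClass.CALCIMIMETICS: frozenset(
        {Directive.START_OR_INCREASE, Directive.DECREASE, Directive.DECREASE_OR_STOP, Directive.MAINTAIN}
    ),
    ManagementClass.CALCITRIOL: frozenset(
        {
            Directive.START_OR_INCREASE,
            Directive.STOP,
            Directive.DECREASE_OR_STOP,
            Directive.CONSIDER,
            Directive.MAINTAIN,
        }
    ),
    ManagementClass.VITAMIN_D_ANALOGS: frozenset(
        {Directive.CONSIDER, Directive.DECREASE_OR_STOP, Directive.STOP, Directive.MAINTAIN}
    ),
    ManagementClass.CPB: frozenset(
        {Directive.START_OR_INCREASE, Directive.STOP, Directive.DECREASE_OR_STOP, Directive.MAINTAIN}
    ),
    ManagementClass.NCPB: frozenset(
        {Directive.START_OR_INCREASE, Directive.STOP, Directive.DECREASE_OR_STOP, Directive.MAINTAIN}
    ),
    ManagementClass.DIALYSATE: frozenset(
        {Directive.INCREASE_0_25, Directive.REDUCE_0_25, Directive.MAINTAIN}
    ),
}

#: The three analytes that drive partitioning, in canonical order.
PARTITION_ANALYTES: tuple[Analyte, ...] = (
    Analyte.PTH,
    Analyte.CORRECTED_CALCIUM,
    Analyte.PHOSPHATE,
)

#: Selector keys used in partition predicates, paired with (analyte, attribute).
_SELECTOR_KEYS: dict[str, tuple[Analyte, str]] = {
    "pth_level": (Analyte.PTH, "level"),
    "pth_trend": (Analyte.PTH, "trend"),
    "ca_level": (Analyte.CORRECTED_CALCIUM, "level"),
    "ca_trend": (Analyte.CORRECTED_CALCIUM, "trend"),
    "p_level": (Analyte.PHOSPHATE, "level"),
    "p_trend": (Analyte.PHOSPHATE, "trend"),
}


class TargetRange(BaseModel):
    """A target range for one analyte, optionally scoped to a patient type."""

    analyte: Analyte
    patient_type_scope: str = "both"  # "type-I" | "type-II" | "both"
    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "TargetRange":
        if not self.low < self.high:
            raise ValueError(f"target range low must be < high, got {self.low} >= {self.high}")
        if self.patient_type_scope not in {"type-I", "type-II", "both"}:
            raise ValueError(f"unknown patient_type_scope {self.patient_type_scope!r}")
        return self

    def contains(self, value: float) -> bool:
        """Inclusive-bounds membership (the rule base is crisp at the edges)."""
        return self.low <= value <= self.high


class CalcificationAssessment(BaseModel):
    vascular_score: int = Field(ge=0, le=24)
    valvular_present: bool = False


class LabState(BaseModel):
    analyte: Analyte
    level: Level
    trend: Trend

    model_config = {"frozen": True}


#: Directive-set field name -> management class.
DIRECTIVE_FIELDS: dict[str, ManagementClass] = {
    "calcimimetics": ManagementClass.CALCIMIMETICS,
    "calcitriol": ManagementClass.CALCITRIOL,
    "vitamin_d_analogs": ManagementClass.VITAMIN_D_ANALOGS,
    "CPB": ManagementClass.CPB,
    "NCPB": ManagementClass.NCPB,
    "dialysate_calcium": ManagementClass.DIALYSATE,
}


class GenericDirectiveSet(BaseModel):
    """One directive per management class (generic recommendation template)."""

    calcimimetics: Directive
    calcitriol: Directive
    vitamin_d_analogs: Directive
    CPB: Directive
    NCPB: Directive
    dialysate_calcium: Directive

    @model_validator(mode="after")
    def _vocabulary(self) -> "GenericDirectiveSet":
        for fname, mclass in DIRECTIVE_FIELDS.items():
            d = getattr(self, fname)
            if d not in ALLOWED_DIRECTIVES[mclass]:
                raise ValueError(f"directive {d.value!r} is not allowed for class {mclass.value}")
        return self

    def for_class(self, mclass: ManagementClass) -> Directive:
        for fname, mc in DIRECTIVE_FIELDS.items():
            if mc is mclass:
                return getattr(self, fname)
        raise InputValidationError(f"unknown management class {mclass!r}")

    def as_dict(self) -> dict[str, str]:
        return {f: getattr(self, f).value for f in DIRECTIVE_FIELDS}


class PartitionRule(BaseModel):
    """Predicate mapping (patient type, lab-state triple) -> partition membership.

    ``when`` maps selector keys (``pth_level``, ``ca_trend``, ...) to the list of
    admitted values; a missing key admits every value of that attribute.
    """

    partition_id: str
    patient_type: PatientType
    when: dict[str, list[str]] = Field(default_factory=dict)
    directive_set_id: str

    @field_validator("when")
    @classmethod
    def _known_selectors(cls, v: dict[str, list[str]]) -> dict[str, list[str]]:
        for key, values in v.items():
            if key not in _SELECTOR_KEYS:
                raise ValueError(f"unknown selector key {key!r}")
            domain = (
                {m.value for m in Level} if key.endswith("_level") else {m.value for m in Trend}
            )
            bad = set(values) - domain
            if bad:
                raise ValueError(f"selector {key} admits unknown values {sorted(bad)}")
            if not values:
                raise ValueError(f"selector {key} admits no values")
        return v

    def matches(self, patient_type: PatientType, states: Mapping[Analyte, LabState]) -> bool:
        if patient_type is not self.patient_type:
            return False
        for key, allowed in self.when.items():
            analyte, attr = _SELECTOR_KEYS[key]
            if getattr(states[analyte], attr).value not in allowed:
                return False
        return True


@dataclass(frozen=True)
class ProductionRule:
    """One fully grounded IF-THEN rule: a conjunction of patient type and the
    three (level, trend) lab states implies a partition id."""

    patient_type: PatientType
    states: tuple[LabState, ...]  # ordered per PARTITION_ANALYTES
    partition_id: str

    def antecedent(self) -> str:
        parts = [f"patient_type = {self.patient_type.value}"]
        for s in self.states:
            parts.append(f"{s.analyte.value} is {s.level.value} and {s.trend.value}")
        return " AND ".join(parts)


class MedicationSpec(BaseModel):
    """Formulary entry: a prescribable factor with its reference dosage range."""

    name: str
    management_class: ManagementClass
    route: str  # po | iv | dialysate
    unit: str
    low: float = 0.0
    high: float
    dose_step: float = Field(gt=0)

    @model_validator(mode="after")
    def _sane(self) -> "MedicationSpec":
        if not self.low < self.high:
            raise ValueError(f"{self.name}: reference range low must be < high")
        if self.route not in {"po", "iv", "dialysate"}:
            raise ValueError(f"{self.name}: unknown route {self.route!r}")
        return self


@dataclass
class ValidationIssue:
    code: str
    path: str
    message: str


@dataclass
class ValidationReport:
    passed: bool
    n_partitions: int
    n_production_rules: int
    issues: list[ValidationIssue] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "passed": self.passed,
            "n_partitions": self.n_partitions,
            "n_production_rules": self.n_production_rules,
            "issues": [vars(i) for i in self.issues],
        }


class KnowledgeBase(BaseModel):
    """The full domain model: ranges, patient typing, partitions, directives,
    formulary."""

    version: str = "0"
    target_ranges: list[TargetRange]
    type_threshold: int = 5
    corrected_calcium_reference_albumin: float = 4.0
    corrected_calcium_coefficient: float = 0.8
    partition_rules: list[PartitionRule]
    directive_sets: dict[str, GenericDirectiveSet]
    formulary: list[MedicationSpec]
    expected_partition_count: Optional[int] = None

    def range_for(self, analyte: Analyte, patient_type: PatientType) -> TargetRange:
        """The scoped target range (PTH differs between patient types)."""
        scoped = None
        for tr in self.target_ranges:
            if tr.analyte is not analyte:
                continue
            if tr.patient_type_scope == "both":
                scoped = scoped or tr
            elif tr.patient_type_scope == patient_type.value:
                return tr
        if scoped is None:
            raise KnowledgeBaseError(
                f"no target range for {analyte.value} scoped to {patient_type.value}"
            )
        return scoped

    def patient_types(self) -> list[PatientType]:
        return sorted({r.patient_type for r in self.partition_rules}, key=lambda t: t.value)

    def directives_for_partition(self, partition_id: str) -> GenericDirectiveSet:
        for rule in self.partition_rules:
            if rule.partition_id == partition_id:
                return self.directive_sets[rule.directive_set_id]
        raise KnowledgeBaseError(f"unknown partition {partition_id!r}")

    def medications_in_class(self, mclass: ManagementClass) -> list[MedicationSpec]:
        return [m for m in self.formulary if m.management_class is mclass]

    def medication(self, name: str) -> MedicationSpec:
        for m in self.formulary:
            if m.name == name:
                return m
        raise KnowledgeBaseError(f"unknown medication {name!r}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def classify_patient_type(
    assessment: CalcificationAssessment, threshold: int = 5
) -> PatientType:
    """Type a patient from the yearly calcification work-up.

    Type-I: valvular calcification present, or vascular calcification score
    strictly greater than ``threshold`` (out of 24).  Type-II otherwise.
    """
    if not 0 <= assessment.vascular_score <= 24:
        raise InputValidationError(
            f"vascular score must be in [0, 24], got {assessment.vascular_score}"
        )
    if assessment.valvular_present or assessment.vascular_score > threshold:
        return PatientType.TYPE_I
    return PatientType.TYPE_II


def corrected_calcium(
    total_calcium: float,
    albumin: float,
    reference_albumin: float = 4.0,
    coefficient: float = 0.8,
) -> float:
    """Albumin-corrected calcium (Payne correction), mg/dL.

    corrected = total + coefficient * (reference_albumin - albumin)
    """
    if total_calcium <= 0 or albumin <= 0:
        raise InputValidationError("total calcium and albumin must be positive")
    return total_calcium + coefficient * (reference_albumin - albumin)


def classify_lab_state(
    current: float,
    previous: Optional[float],
    target_range: TargetRange,
) -> LabState:
    """Classify one analyte into its 6-state (level x trend) vocabulary.

    Level uses inclusive bounds; the trend compares against the previous
    measurement and defaults to ``not_increased`` when no previous value
    exists (first encounter).
    """
    if current is None:
        raise InputValidationError("current lab value is required")
    if current < target_range.low:
        level = Level.BELOW
    elif current > target_range.high:
        level = Level.ABOVE
    else:
        level = Level.WITHIN
    trend = (
        Trend.INCREASED
        if previous is not None and current > previous
        else Trend.NOT_INCREASED
    )
    return LabState(analyte=target_range.analyte, level=level, trend=trend)


def lab_states(
    kb: KnowledgeBase,
    patient_type: PatientType,
    current: Mapping[Analyte, float],
    previous: Optional[Mapping[Analyte, float]] = None,
) -> dict[Analyte, LabState]:
    """Classify the full analyte triple against the type-scoped ranges."""
    out: dict[Analyte, LabState] = {}
    for analyte in PARTITION_ANALYTES:
        rng = kb.range_for(analyte, patient_type)
        prev = previous.get(analyte) if previous else None
        out[analyte] = classify_lab_state(current[analyte], prev, rng)
    return out


def assign_partition(
    kb: KnowledgeBase,
    patient_type: PatientType,
    states: Mapping[Analyte, LabState],
) -> str:
    """Deterministically map a patient state to its partition id."""
    matches = [r.partition_id for r in kb.partition_rules if r.matches(patient_type, states)]
    if len(matches) == 1:
        return matches[0]
    if not matches:
        raise PartitionIntegrityError(
            f"no partition covers {patient_type.value} state "
            f"{[(s.analyte.value, s.level.value, s.trend.value) for s in states.values()]}"
        )
    raise PartitionIntegrityError(
        f"partitions {matches} overlap on {patient_type.value} state"
    )


def _state_grid(patient_types: Iterable[PatientType]):
    levels = list(Level)
    trends = list(Trend)
    per_analyte = [(lv, tr) for lv in levels for tr in trends]
    for ptype in patient_types:
        for combo in itertools.product(per_analyte, repeat=len(PARTITION_ANALYTES)):
            states = {
                analyte: LabState(analyte=analyte, level=lv, trend=tr)
                for analyte, (lv, tr) in zip(PARTITION_ANALYTES, combo)
            }
            yield ptype, states


def compile_production_rules(kb: KnowledgeBase) -> list[ProductionRule]:
    """Enumerate every (patient type x lab-state triple) grid point as one
    grounded IF-THEN rule.

    Raises :class:`RuleCompilationError` listing offending combinations if any
    grid point is uncovered or covered by more than one partition.
    """
    rules: list[ProductionRule] = []
    uncovered: list[tuple] = []
    overlapping: list[tuple] = []
    for ptype, states in _state_grid(kb.patient_types()):
        matches = [r.partition_id for r in kb.partition_rules if r.matches(ptype, states)]
        key = (ptype.value,) + tuple(
            (s.analyte.value, s.level.value, s.trend.value) for s in states.values()
        )
        if not matches:
            uncovered.append(key)
        elif len(matches) > 1:
            overlapping.append(key + (tuple(matches),))
        else:
            rules.append(
                ProductionRule(
                    patient_type=ptype,
                    states=tuple(states[a] for a in PARTITION_ANALYTES),
                    partition_id=matches[0],
                )
            )
    if uncovered or overlapping:
        raise RuleCompilationError(
            f"partition predicates are not a tiling: {len(uncovered)} uncovered, "
            f"{len(overlapping)} overlapping state combinations",
            offending=uncovered + overlapping,
        )
    return rules


def validate_knowledge_base(kb: KnowledgeBase) -> ValidationReport:
    """Structural validation of a knowledge base.

    Checks partition-id distinctness (and the declared expected count),
    exclusivity/exhaustiveness over the full state grid, directive vocabulary
    conformance, and formulary reference-range sanity.  Returns a
    machine-readable pass/fail report; never raises for content problems.
    """
    issues: list[ValidationIssue] = []

    pids = [r.partition_id for r in kb.partition_rules]
    if len(set(pids)) != len(pids):
        dupes = sorted({p for p in pids if pids.count(p) > 1})
        issues.append(
            ValidationIssue("duplicate_partition_id", "partitions", f"duplicate ids {dupes}")
        )
    if kb.expected_partition_count is not None and len(set(pids)) != kb.expected_partition_count:
        issues.append(
            ValidationIssue(
                "partition_count",
                "partitions",
                f"expected {kb.expected_partition_count} partitions, found {len(set(pids))}",
            )
        )

    n_rules = 0
    try:
        n_rules = len(compile_production_rules(kb))
    except RuleCompilationError as exc:
        issues.append(ValidationIssue("exclusivity_exhaustiveness", "partitions", str(exc)))

    for pid_rule in kb.partition_rules:
        if pid_rule.directive_set_id not in kb.directive_sets:
            issues.append(
                ValidationIssue(
                    "dangling_directive_set",
                    f"partitions/{pid_rule.partition_id}",
                    f"references unknown directive set {pid_rule.directive_set_id!r}",
                )
            )

    # Directive vocabulary is enforced by the GenericDirectiveSet model at parse
    # time; re-check here for KBs assembled programmatically.
    for ds_id, ds in kb.directive_sets.items():
        for fname, mclass in DIRECTIVE_FIELDS.items():
            d = getattr(ds, fname)
            if d not in ALLOWED_DIRECTIVES[mclass]:
                issues.append(
                    ValidationIssue(
                        "directive_vocabulary",
                        f"directive_sets/{ds_id}/{fname}",
                        f"{d.value!r} not allowed for {mclass.value}",
                    )
                )

    seen_meds = set()
    for med in kb.formulary:
        if med.name in seen_meds:
            issues.append(
                ValidationIssue("duplicate_medication", f"formulary/{med.name}", "duplicate entry")
            )
        seen_meds.add(med.name)

    # Range scoping: PTH must be resolvable for both declared patient types.
    for ptype in kb.patient_types():
        for analyte in PARTITION_ANALYTES:
            try:
                kb.range_for(analyte, ptype)
            except KnowledgeBaseError as exc:
                issues.append(ValidationIssue("missing_target_range", "target_ranges", str(exc)))

    return ValidationReport(
        passed=not issues,
        n_partitions=len(set(pids)),
        n_production_rules=n_rules,
        issues=issues,
    )


# ---------------------------------------------------------------------------
# Knowledge pack I/O
# ---------------------------------------------------------------------------

def _pack_to_kb(doc: dict) -> KnowledgeBase:
    try:
        meta = doc.get("meta", {})
        typing = doc.get("patient_typing", {})
        corr = typing.get("corrected_calcium", {})
        return KnowledgeBase(
            version=str(meta.get("version", "0")),
            expected_partition_count=meta.get("expected_partitions"),
            target_ranges=[TargetRange(**tr) for tr in doc["target_ranges"]],
            type_threshold=typing.get("vascular_score_threshold", 5),
            corrected_calcium_reference_albumin=corr.get("reference_albumin", 4.0),
            corrected_calcium_coefficient=corr.get("coefficient", 0.8),
            directive_sets={
                ds_id: GenericDirectiveSet(**ds)
                for ds_id, ds in doc["directive_sets"].items()
            },
            partition_rules=[
                PartitionRule(
                    partition_id=p["id"],
                    patient_type=PatientType(p["patient_type"]),
                    when=p.get("when", {}),
                    directive_set_id=p["directive_set"],
                )
                for p in doc["partitions"]
            ],
            formulary=[MedicationSpec(**m) for m in doc["formulary"]],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise KnowledgePackParseError(f"malformed knowledge pack: {exc}") from exc


def load_knowledge_base(path: Optional[Union[str, Path]] = None) -> KnowledgeBase:
    """Load a knowledge pack from YAML; with no path, load the bundled pack."""
    if path is None:
        ref = resources.files("ckdmbd.data").joinpath("knowledge_pack.yaml")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise KnowledgePackParseError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise KnowledgePackParseError("knowledge pack must be a mapping")
    return _pack_to_kb(doc)
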