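"""Synthetic longitudinal hemodialysis cohorts.

The generator emulates the statistical shape of a real CKD-MBD case base:
~66 patients with up to 13 monthly encounters (~850 cases), a type-I/type-II
split near 44:56, quarterly PTH draws carried forward between measurements,
and prescriptions written by a simulated clinician who follows the knowledge
base's partition directives with configurable adherence.

Lab dynamics are linear-Gaussian: each month

    next = current + sum_over_classes(effect * normalized_dose) + noise

with signed effect directions fixed by standard CKD-MBD pharmacology
(calcimimetics lower PTH and calcium; active vitamin D lowers PTH but raises
calcium and phosphate; phosphate binders lower phosphate, the calcium-based
ones raising calcium; dialysate calcium moves serum calcium).  The simulated
clinician titrates to a fixed per-medication standard dose: "start or
increase" saturates at that dose, "decrease or stop" discontinues.  This
makes the zero-noise, full-adherence regime analytically recoverable end to
end.  Ground truth (generating partition, applied directives, pre-noise
trajectory) is stored alongside and never fed to the pipeline under test.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from .cases import Encounter, LabPanel, Prescription, DIALYSATE_LEVELS
from .knowledge import (
    Analyte,
    CalcificationAssessment,
    Directive,
    InputValidationError,
    KnowledgeBase,
    Level,
    ManagementClass,
    PartitionIntegrityError,
    PatientType,
    Trend,
    assign_partition,
    classify_patient_type,
    corrected_calcium,
    lab_states,
)

_START_DATE = dt.date(2021, 1, 15)

#: Signed lab response per unit normalized dose (dose / reference max) per month.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "calcimimetics": {"pth": -400.0, "total_calcium": -0.6},
    "calcitriol": {"pth": -300.0, "total_calcium": 0.8, "phosphate": 0.6},
    "vitamin_d_analogs": {"pth": -300.0, "total_calcium": 0.8, "phosphate": 0.6},
    "CPB": {"phosphate": -2.0, "total_calcium": 0.8},
    "NCPB": {"phosphate": -4.0},
    # per 0.25 mmol/L step above the 1.25 mmol/L floor
    "dialysate": {"total_calcium": 0.25},
}

#: Standard titration target per medication (the simulated clinician's dose).
DEFAULT_START_DOSES: dict[str, float] = {
    "cinacalcet": 50.0,
    "calcitriol_po": 0.5,
    "calcitriol_iv": 2.0,
    "paricalcitol_iv": 10.0,
    "alfacalcidol": 0.5,
    "calcium_carbonate": 1500.0,
    "calcium_acetate": 2000.0,
    "sevelamer": 2400.0,
    "lanthanum": 1500.0,
}

#: First-line medication the simulated clinician reaches for in each class.
FIRST_LINE: dict[str, str] = {
    "calcimimetics": "cinacalcet",
    "calcitriol": "calcitriol_po",
    "vitamin_d_analogs": "paricalcitol_iv",
    "CPB": "calcium_carbonate",
    "NCPB": "sevelamer",
}

SECOND_LINE: dict[str, str] = {
    "calcimimetics": "cinacalcet",
    "calcitriol": "calcitriol_iv",
    "vitamin_d_analogs": "alfacalcidol",
    "CPB": "calcium_acetate",
    "NCPB": "lanthanum",
}

_LATENT_BOUNDS = {
    "pth": (10.0, 2500.0),
    "phosphate": (1.0, 15.0),
    "total_calcium": (5.5, 13.0),
    "albumin": (2.0, 5.5),
}


class CohortConfig(BaseModel):
    """Study-shaped generator settings."""

    n_patients: int = Field(default=66, ge=1)
    max_encounters: int = Field(default=13, ge=1)
    type_i_fraction: float = Field(default=0.44, ge=0, le=1)
    seed: int = 0
    noise_sd: dict[str, float] = Field(
        default_factory=lambda: {
            "pth": 25.0,
            "phosphate": 0.4,
            "total_calcium": 0.25,
            "albumin": 0.05,
        }
    )
    adherence_prob: float = Field(default=0.9, ge=0, le=1)
    second_line_prob: float = Field(default=0.0, ge=0, le=1)
    pth_measurement_interval: int = Field(default=3, ge=1)
    effects: dict[str, dict[str, float]] = Field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_EFFECTS.items()
    })
    start_doses: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_START_DOSES))


@dataclass
class GroundTruthRecord:
    """What the generator actually did at one encounter (held out from the
    pipeline under test)."""

    mrn: str
    sequence_index: int
    partition_id: str
    kb_directives: dict[str, str]
    applied_directives: dict[str, str]
    pre_noise_labs: dict[str, float] = dc_field(default_factory=dict)


def _apply_policy(
    rng_class_meds: dict[str, list],
    directives: dict[str, Directive],
    previous: Prescription,
    preferred: dict[str, str],
    start_doses: dict[str, float],
) -> Prescription:
    doses = previous.as_dict()
    for mclass, directive in directives.items():
        if mclass == "dialysate":
            conc = doses["dialysate_calcium"]
            if directive is Directive.INCREASE_0_25:
                conc += 0.25
            elif directive is Directive.REDUCE_0_25:
                conc -= 0.25
            doses["dialysate_calcium"] = min(max(conc, DIALYSATE_LEVELS[0]), DIALYSATE_LEVELS[-1])
            continue
        med_names = [m.name for m in rng_class_meds[mclass]]
        if directive is Directive.START_OR_INCREASE:
            doses[preferred[mclass]] = start_doses[preferred[mclass]]
        elif directive in (Directive.DECREASE, Directive.DECREASE_OR_STOP, Directive.STOP):
            for name in med_names:
                doses[name] = 0.0
        # maintain / consider: unchanged
    return Prescription(**doses)


def generate_cohort(
    config: CohortConfig, kb: KnowledgeBase
) -> tuple[list[Encounter], list[GroundTruthRecord]]:
    """Simulate a longitudinal cohort under the knowledge base's own policy.

    Deterministic for a fixed (config, kb).  Returns the encounter table (what
    the pipeline ingests) and the ground-truth log (what the generator did).
    """
    try:
        rng = np.random.default_rng(config.seed)
    except TypeError as exc:  # pragma: no cover
        raise InputValidationError(f"invalid seed: {exc}") from exc

    class_meds = {
        mc.value: kb.medications_in_class(mc)
        for mc in ManagementClass
        if mc is not ManagementClass.DIALYSATE
    }
    med_max = {m.name: m.high for m in kb.formulary}

    encounters: list[Encounter] = []
    ground_truth: list[GroundTruthRecord] = []

    for p in range(config.n_patients):
        mrn = f"SYN{p + 1:04d}"
        is_type_i = rng.random() < config.type_i_fraction
        if is_type_i:
            valvular = bool(rng.random() < 0.3)
            score = int(rng.integers(6, 25)) if not valvular else int(rng.integers(0, 25))
        else:
            valvular = False
            score = int(rng.integers(0, 6))
        calcification = CalcificationAssessment(vascular_score=score, valvular_present=valvular)

        n_enc = config.max_encounters - int(rng.choice([0, 1, 2], p=[0.85, 0.10, 0.05]))
        n_enc = max(1, n_enc)

        latent = {
            "pth": float(np.clip(rng.normal(380.0, 180.0), 40.0, 1200.0)),
            "phosphate": float(np.clip(rng.normal(5.2, 1.2), 2.0, 10.0)),
            "total_calcium": float(np.clip(rng.normal(9.2, 0.8), 6.5, 12.0)),
            "albumin": float(np.clip(rng.normal(3.9, 0.35), 2.8, 4.8)),
        }
        preferred = dict(FIRST_LINE)
        for mclass in list(preferred):
            if rng.random() < config.second_line_prob:
                preferred[mclass] = SECOND_LINE[mclass]

        prev_rx = Prescription()
        last_measured_pth = latent["pth"]
        prev_observed: Optional[dict[Analyte, float]] = None

        for t in range(1, n_enc + 1):
            if (t - 1) % config.pth_measurement_interval == 0:
                last_measured_pth = latent["pth"]
            observed = {
                Analyte.PTH: last_measured_pth,
                Analyte.PHOSPHATE: latent["phosphate"],
                Analyte.CORRECTED_CALCIUM: corrected_calcium(
                    latent["total_calcium"],
                    latent["albumin"],
                    kb.corrected_calcium_reference_albumin,
                    kb.corrected_calcium_coefficient,
                ),
            }
            ptype = classify_patient_type(calcification, kb.type_threshold)
            states = lab_states(kb, ptype, observed, prev_observed)
            partition_id = assign_partition(kb, ptype, states)
            kb_directives = {
                mc: d
                for mc, d in zip(
                    ["calcimimetics", "calcitriol", "vitamin_d_analogs", "CPB", "NCPB", "dialysate"],
                    [
                        kb.directives_for_partition(partition_id).calcimimetics,
                        kb.directives_for_partition(partition_id).calcitriol,
                        kb.directives_for_partition(partition_id).vitamin_d_analogs,
                        kb.directives_for_partition(partition_id).CPB,
                        kb.directives_for_partition(partition_id).NCPB,
                        kb.directives_for_partition(partition_id).dialysate_calcium,
                    ],
                )
            }
            applied = {
                mc: (d if rng.random() < config.adherence_prob else Directive.MAINTAIN)
                for mc, d in kb_directives.items()
            }
            new_rx = _apply_policy(class_meds, applied, prev_rx, preferred, config.start_doses)

            encounters.append(
                Encounter(
                    mrn=mrn,
                    sequence_index=t,
                    labs=LabPanel(
                        encounter_date=_START_DATE + dt.timedelta(days=30 * (t - 1)),
                        pth=observed[Analyte.PTH],
                        phosphate=observed[Analyte.PHOSPHATE],
                        total_calcium=latent["total_calcium"],
                        albumin=latent["albumin"],
                    ),
                    calcification=calcification,
                    prescription=new_rx,
                )
            )
            ground_truth.append(
                GroundTruthRecord(
                    mrn=mrn,
                    sequence_index=t,
                    partition_id=partition_id,
                    kb_directives={k: v.value for k, v in kb_directives.items()},
                    applied_directives={k: v.value for k, v in applied.items()},
                    pre_noise_labs=dict(latent),
                )
            )
            prev_observed = observed

            # advance latent labs one month under the new prescription
            delta = {k: 0.0 for k in ("pth", "phosphate", "total_calcium")}
            for mclass, meds in class_meds.items():
                coefs = config.effects.get(mclass, {})
                load = sum(new_rx.dose(m.name) / med_max[m.name] for m in meds)
                for analyte, coef in coefs.items():
                    delta[analyte] += coef * load
            dialysate_steps = (new_rx.dialysate_calcium - DIALYSATE_LEVELS[0]) / 0.25
            for analyte, coef in config.effects.get("dialysate", {}).items():
                delta[analyte] += coef * dialysate_steps
            for key in latent:
                d = delta.get(key, 0.0)
                noise = rng.normal(0.0, config.noise_sd.get(key, 0.0)) if config.noise_sd.get(key, 0.0) > 0 else 0.0
                lo, hi = _LATENT_BOUNDS[key]
                latent[key] = float(np.clip(latent[key] + d + noise, lo, hi))

            prev_rx = new_rx

    return encounters, ground_truth


def _representative(level: Level, low: float, high: float) -> float:
    span = high - low
    if level is Level.BELOW:
        return max(low - 0.2 * span, 0.05 * low)
    if level is Level.ABOVE:
        return high + 0.2 * span
    return (low + high) / 2.0


def generate_partition_grid(kb: KnowledgeBase) -> list[Encounter]:
    """One synthetic encounter per partition (plus a previous encounter that
    establishes the trend), covering every partition in the knowledge base.

    Raises :class:`PartitionIntegrityError` naming any partition whose
    representative state does not map back to it.
    """
    encounters: list[Encounter] = []
    selector_defaults = {
        "pth_level": [l.value for l in Level],
        "pth_trend": [t.value for t in Trend],
        "ca_level": [l.value for l in Level],
        "ca_trend": [t.value for t in Trend],
        "p_level": [l.value for l in Level],
        "p_trend": [t.value for t in Trend],
    }
    analyte_keys = {
        Analyte.PTH: ("pth_level", "pth_trend"),
        Analyte.CORRECTED_CALCIUM: ("ca_level", "ca_trend"),
        Analyte.PHOSPHATE: ("p_level", "p_trend"),
    }

    for rule in kb.partition_rules:
        ptype = rule.patient_type
        current: dict[Analyte, float] = {}
        previous: dict[Analyte, float] = {}
        for analyte, (level_key, trend_key) in analyte_keys.items():
            levels = rule.when.get(level_key, selector_defaults[level_key])
            trends = rule.when.get(trend_key, selector_defaults[trend_key])
            level = Level(levels[0])
            # prefer the no-trend default so the previous panel can equal the current
            trend = (
                Trend.NOT_INCREASED
                if Trend.NOT_INCREASED.value in trends
                else Trend(trends[0])
            )
            rng_ = kb.range_for(analyte, ptype)
            value = _representative(level, rng_.low, rng_.high)
            current[analyte] = value
            previous[analyte] = value * 0.9 if trend is Trend.INCREASED else value

        states = lab_states(kb, ptype, current, previous)
        recovered = assign_partition(kb, ptype, states)
        if recovered != rule.partition_id:
            raise PartitionIntegrityError(
                f"partition {rule.partition_id} is unreachable: representative state "
                f"maps to {recovered}"
            )

        calcification = CalcificationAssessment(
            vascular_score=12 if ptype is PatientType.TYPE_I else 2,
            valvular_present=False,
        )
        albumin = kb.corrected_calcium_reference_albumin  # correction-neutral
        mrn = f"GRID-{rule.partition_id}"
        for seq, values in ((1, previous), (2, current)):
            encounters.append(
                Encounter(
                    mrn=mrn,
                    sequence_index=seq,
                    labs=LabPanel(
                        encounter_date=_START_DATE + dt.timedelta(days=30 * (seq - 1)),
                        pth=values[Analyte.PTH],
                        phosphate=values[Analyte.PHOSPHATE],
                        total_calcium=values[Analyte.CORRECTED_CALCIUM],
                        albumin=albumin,
                    ),
                    calcification=calcification,
                    prescription=Prescription(),
                )
            )
    return encounters
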