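"""File formats: encounter tables, case bases, recommendations, reports.

Encounter tables are flat CSV or JSONL, one row per encounter, with units in
the column names (see :data:`ENCOUNTER_COLUMNS`).  Missing PTH values (drawn
quarterly in practice) and missing calcification assessments (reassessed
yearly) are carried forward from the patient's prior rows at read time.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .adaptation import Recommendation
from .cases import (
    CaseBase,
    ClinicalCase,
    Encounter,
    IngestionError,
    LabPanel,
    Prescription,
)
from .cohort import GroundTruthRecord
from .knowledge import CalcificationAssessment

PathLike = Union[str, Path]

#: Column dictionary for the encounter table (name -> description with units).
ENCOUNTER_COLUMNS: dict[str, str] = {
    "mrn": "patient medical record number (string)",
    "sequence_index": "1-based encounter index, contiguous per patient",
    "encounter_date": "ISO calendar date",
    "pth_pg_ml": "intact PTH, pg/mL (blank: carried forward from last draw)",
    "phosphate_mg_dl": "serum phosphate, mg/dL",
    "total_calcium_mg_dl": "total serum calcium, mg/dL",
    "albumin_g_dl": "serum albumin, g/dL",
    "vascular_score": "vascular calcification score 0-24 (blank: carried forward)",
    "valvular_present": "valvular calcification present, boolean (blank: carried forward)",
    "cinacalcet_mg_day": "prescribed cinacalcet, mg/day",
    "calcitriol_po_ug_day": "prescribed oral calcitriol, ug/day",
    "calcitriol_iv_ug_week": "prescribed IV calcitriol, ug/week",
    "paricalcitol_iv_ug_week": "prescribed IV paricalcitol, ug/week",
    "alfacalcidol_ug_day": "prescribed alfacalcidol, ug/day",
    "calcium_carbonate_mg_day": "prescribed calcium carbonate, mg/day",
    "calcium_acetate_mg_day": "prescribed calcium acetate, mg/day",
    "sevelamer_mg_day": "prescribed sevelamer, mg/day",
    "lanthanum_mg_day": "prescribed lanthanum, mg/day",
    "dialysate_calcium_mmol_l": "dialysate calcium concentration, mmol/L",
}

_RX_COLUMNS = {
    "cinacalcet": "cinacalcet_mg_day",
    "calcitriol_po": "calcitriol_po_ug_day",
    "calcitriol_iv": "calcitriol_iv_ug_week",
    "paricalcitol_iv": "paricalcitol_iv_ug_week",
    "alfacalcidol": "alfacalcidol_ug_day",
    "calcium_carbonate": "calcium_carbonate_mg_day",
    "calcium_acetate": "calcium_acetate_mg_day",
    "sevelamer": "sevelamer_mg_day",
    "lanthanum": "lanthanum_mg_day",
    "dialysate_calcium": "dialysate_calcium_mmol_l",
}


def encounters_to_frame(encounters: Sequence[Encounter]) -> pd.DataFrame:
    rows = []
    for e in encounters:
        row = {
            "mrn": e.mrn,
            "sequence_index": e.sequence_index,
            "encounter_date": e.labs.encounter_date.isoformat(),
            "pth_pg_ml": e.labs.pth,
            "phosphate_mg_dl": e.labs.phosphate,
            "total_calcium_mg_dl": e.labs.total_calcium,
            "albumin_g_dl": e.labs.albumin,
            "vascular_score": e.calcification.vascular_score,
            "valvular_present": e.calcification.valvular_present,
        }
        for attr, col in _RX_COLUMNS.items():
            row[col] = e.prescription.dose(attr)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(ENCOUNTER_COLUMNS))


def write_encounters(encounters: Sequence[Encounter], path: PathLike) -> None:
    path = Path(path)
    frame = encounters_to_frame(encounters)
    if path.suffix == ".jsonl":
        path.write_text(
            "\n".join(json.dumps(rec) for rec in frame.to_dict(orient="records")) + "\n",
            encoding="utf-8",
        )
    else:
        frame.to_csv(path, index=False)


def _row_to_encounter(
    row: dict,
    carried_pth: Optional[float],
    carried_calc: Optional[CalcificationAssessment],
) -> tuple[Encounter, float, CalcificationAssessment]:
    def _num(key: str) -> Optional[float]:
        v = row.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return float(v)

    pth = _num("pth_pg_ml")
    if pth is None:
        if carried_pth is None:
            raise IngestionError(
                f"first encounter for {row.get('mrn')} is missing pth_pg_ml"
            )
        pth = carried_pth
    score = _num("vascular_score")
    valv = row.get("valvular_present")
    if score is None:
        if carried_calc is None:
            raise IngestionError(
                f"first encounter for {row.get('mrn')} is missing the calcification assessment"
            )
        calc = carried_calc
    else:
        calc = CalcificationAssessment(
            vascular_score=int(score),
            valvular_present=bool(valv) if not pd.isna(valv) else False,
        )
    enc = Encounter(
        mrn=str(row["mrn"]),
        sequence_index=int(row["sequence_index"]),
        labs=LabPanel(
            encounter_date=dt.date.fromisoformat(str(row["encounter_date"])),
            pth=pth,
            phosphate=_num("phosphate_mg_dl"),
            total_calcium=_num("total_calcium_mg_dl"),
            albumin=_num("albumin_g_dl"),
        ),
        calcification=calc,
        prescription=Prescription(
            **{attr: _num(col) or 0.0 for attr, col in _RX_COLUMNS.items() if attr != "dialysate_calcium"},
            dialysate_calcium=_num("dialysate_calcium_mmol_l") or 1.25,
        ),
    )
    return enc, pth, calc


def read_encounters(path: PathLike) -> list[Encounter]:
    """Read an encounter table (CSV or JSONL), carrying PTH and calcification
    forward within each patient's history."""
    path = Path(path)
    if path.suffix == ".jsonl":
        frame = pd.DataFrame(
            [json.loads(line) for line in path.read_text(encoding="utf-8").splitlines() if line]
        )
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
    missing = {"mrn", "sequence_index", "encounter_date"} - set(frame.columns)
    if missing:
        raise IngestionError(f"encounter table is missing columns {sorted(missing)}")
    frame = frame.sort_values(["mrn", "sequence_index"], kind="stable")
    encounters: list[Encounter] = []
    carried: dict[str, tuple[Optional[float], Optional[CalcificationAssessment]]] = {}
    for _, row in frame.iterrows():
        mrn = str(row["mrn"])
        pth0, calc0 = carried.get(mrn, (None, None))
        enc, pth, calc = _row_to_encounter(dict(row), pth0, calc0)
        carried[mrn] = (pth, calc)
        encounters.append(enc)
    return encounters


# ---------------------------------------------------------------------------
# Case base persistence
# ---------------------------------------------------------------------------

def write_case_base(case_base: CaseBase, path: PathLike) -> None:
    """JSONL, one case per line, plus a partition-index sidecar."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for case in case_base.cases:
            fh.write(case.model_dump_json() + "\n")
    sidecar = path.with_suffix(path.suffix + ".index.json")
    sidecar.write_text(
        json.dumps(case_base.partition_counts(), indent=2, sort_keys=True), encoding="utf-8"
    )


def read_case_base(path: PathLike) -> CaseBase:
    cases = [
        ClinicalCase.model_validate_json(line)
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line
    ]
    return CaseBase(cases=cases)


def write_recommendation(recommendation: Recommendation, path: PathLike) -> None:
    Path(path).write_text(recommendation.model_dump_json(indent=2) + "\n", encoding="utf-8")


def read_recommendation(path: PathLike) -> Recommendation:
    return Recommendation.model_validate_json(Path(path).read_text(encoding="utf-8"))


def write_ground_truth(records: Sequence[GroundTruthRecord], path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(asdict(rec)) + "\n")


def read_ground_truth(path: PathLike) -> list[GroundTruthRecord]:
    return [
        GroundTruthRecord(**json.loads(line))
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line
    ]


class RunConfig(BaseModel):
    """Run-level configuration shared by the CLI commands."""

    kb_path: Optional[str] = None  # None: bundled knowledge pack
    case_table_path: Optional[str] = None
    output_dir: str = "."
    presence: str = "either"  # concordance presence convention
    quartile_method: str = "linear"
    log_level: str = "INFO"
    seed: int = 0


def load_run_config(path: Optional[PathLike]) -> RunConfig:
    if path is None:
        return RunConfig()
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return RunConfig(**doc)
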