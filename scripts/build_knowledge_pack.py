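"""One-off author script for the bundled knowledge pack.

Emits src/ckdmbd/data/knowledge_pack.yaml: 33 partitions tiling the
2 x 6^3 state grid (type-I: 18 = PTH x Ca x P-above-vs-not; type-II: 15 =
PTH x Ca with the P split only where Ca is not high), each with a directive
set following KDIGO-style management logic.
"""

import sys
from pathlib import Path

import yaml

LEVELS = ["above", "within", "below"]


def directive_set(ptype, pth, ca, p_spec):
    """p_spec in {'above', 'not_above', 'any'}."""
    p_above = p_spec == "above"

    if pth == "above":
        calcimimetics = "start_or_increase"
    elif pth == "within":
        calcimimetics = "maintain"
    else:
        calcimimetics = "decrease_or_stop"

    if pth == "above":
        if ca == "above" or p_above:
            calcitriol, vitd = "stop", "stop"
        else:
            calcitriol, vitd = "start_or_increase", "consider"
    elif pth == "within":
        if ca == "above":
            calcitriol, vitd = "decrease_or_stop", "decrease_or_stop"
        else:
            calcitriol, vitd = "maintain", "maintain"
    else:  # PTH below: oversuppression, withdraw vitamin D sterols
        calcitriol, vitd = "decrease_or_stop", "decrease_or_stop"

    if ca == "above":
        cpb = "stop"
    elif p_above and ca == "below":
        cpb = "start_or_increase"
    else:
        cpb = "maintain"

    ncpb = "start_or_increase" if p_above else "maintain"

    if ca == "above":
        dialysate = "reduce_0.25"
    elif ca == "below":
        dialysate = "increase_0.25"
    else:
        dialysate = "maintain"

    return {
        "calcimimetics": calcimimetics,
        "calcitriol": calcitriol,
        "vitamin_d_analogs": vitd,
        "CPB": cpb,
        "NCPB": ncpb,
        "dialysate_calcium": dialysate,
    }


def main(out_path):
    partitions = []
    directive_sets = {}
    ds_index = {}

    def ds_id_for(ds):
        key = tuple(sorted(ds.items()))
        if key not in ds_index:
            ds_index[key] = f"DS{len(ds_index) + 1:02d}"
            directive_sets[ds_index[key]] = ds
        return ds_index[key]

    n = 0
    # Type-I: 18 partitions
    for pth in LEVELS:
        for ca in LEVELS:
            for p_spec in ("above", "not_above"):
                n += 1
                when = {"pth_level": [pth], "ca_level": [ca]}
                when["p_level"] = ["above"] if p_spec == "above" else ["within", "below"]
                partitions.append(
                    {
                        "id": f"T{n}",
                        "patient_type": "type-I",
                        "when": when,
                        "directive_set": ds_id_for(directive_set("type-I", pth, ca, p_spec)),
                    }
                )
    # Type-II: 15 partitions
    for pth in LEVELS:
        for ca in LEVELS:
            specs = ("any",) if ca == "above" else ("above", "not_above")
            for p_spec in specs:
                n += 1
                when = {"pth_level": [pth], "ca_level": [ca]}
                if p_spec == "above":
                    when["p_level"] = ["above"]
                elif p_spec == "not_above":
                    when["p_level"] = ["within", "below"]
                partitions.append(
                    {
                        "id": f"T{n}",
                        "patient_type": "type-II",
                        "when": when,
                        "directive_set": ds_id_for(directive_set("type-II", pth, ca, p_spec)),
                    }
                )
    assert n == 33, n

    doc = {
        "meta": {
            "name": "ckdmbd-reconstructed-domain-model",
            "version": "1.0",
            "expected_partitions": 33,
            "notes": (
                "Editable reconstruction of the expert partition table for CKD-MBD "
                "management. Partition predicates: omitted selector keys admit any "
                "value. Trends (increased / not_increased vs the previous "
                "measurement) are part of the state space and of the compiled "
                "production-rule antecedents; the reconstructed partitions do not "
                "discriminate on trend."
            ),
        },
        "target_ranges": [
            {"analyte": "PTH", "patient_type_scope": "type-I", "low": 150, "high": 300},
            {"analyte": "PTH", "patient_type_scope": "type-II", "low": 130, "high": 600},
            {"analyte": "phosphate", "patient_type_scope": "both", "low": 3.5, "high": 5.5},
            {"analyte": "corrected_calcium", "patient_type_scope": "both", "low": 7.5, "high": 10.2},
        ],
        "patient_typing": {
            "vascular_score_threshold": 5,
            "corrected_calcium": {"reference_albumin": 4.0, "coefficient": 0.8},
        },
        "directive_sets": directive_sets,
        "partitions": partitions,
        "formulary": [
            {"name": "cinacalcet", "management_class": "calcimimetics", "route": "po",
             "unit": "mg/day", "low": 0, "high": 100, "dose_step": 25},
            {"name": "calcitriol_po", "management_class": "calcitriol", "route": "po",
             "unit": "ug/day", "low": 0, "high": 2.0, "dose_step": 0.25},
            {"name": "calcitriol_iv", "management_class": "calcitriol", "route": "iv",
             "unit": "ug/week", "low": 0, "high": 10, "dose_step": 0.5},
            {"name": "paricalcitol_iv", "management_class": "vitamin_d_analogs", "route": "iv",
             "unit": "ug/week", "low": 0, "high": 50, "dose_step": 2.5},
            {"name": "alfacalcidol", "management_class": "vitamin_d_analogs", "route": "po",
             "unit": "ug/day", "low": 0, "high": 3, "dose_step": 0.25},
            {"name": "calcium_carbonate", "management_class": "CPB", "route": "po",
             "unit": "mg/day", "low": 0, "high": 3750, "dose_step": 250},
            {"name": "calcium_acetate", "management_class": "CPB", "route": "po",
             "unit": "mg/day", "low": 0, "high": 6000, "dose_step": 500},
            {"name": "sevelamer", "management_class": "NCPB", "route": "po",
             "unit": "mg/day", "low": 0, "high": 13000, "dose_step": 400},
            {"name": "lanthanum", "management_class": "NCPB", "route": "po",
             "unit": "mg/day", "low": 0, "high": 3750, "dose_step": 250},
            {"name": "dialysate_calcium", "management_class": "dialysate", "route": "dialysate",
             "unit": "mmol/L", "low": 1.25, "high": 1.75, "dose_step": 0.25},
        ],
    }

    Path(out_path).write_text(
        yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8"
    )
    print(f"wrote {out_path}: {len(partitions)} partitions, {len(directive_sets)} directive sets")


if __name__ == "__main__":
    main(sys.argv[1] if len(sys.argv) > 1 else "src/ckdmbd/data/knowledge_pack.yaml")
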