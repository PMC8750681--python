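"""Dosage-range estimation and directive-constrained case adaptation."""

import pytest
from hypothesis import given, settings, strategies as st

from ckdmbd import (
    CaseBase,
    ManagementClass,
    Prescription,
    build_case_base,
    estimate_dosage_range,
    recommend,
    select_medication_within_class,
)
from ckdmbd.adaptation import adapt
from ckdmbd.knowledge import GenericDirectiveSet, InputValidationError

from conftest import make_encounter
from test_cases import _case


def quartile_oracle(values):
    """Independent sorted-position quartile oracle (linear interpolation)."""
    s = sorted(values)
    n = len(s)

    def q(p):
        if n == 1:
            return s[0]
        pos = p * (n - 1)
        lo = int(pos)
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return s[lo] * (1 - frac) + s[hi] * frac

    return q(0.25), q(0.75)


class TestIQR:
    @pytest.mark.parametrize(
        "doses,expected",
        [
            ([25, 25, 50, 50], (25, 50)),
            ([30], (30, 30)),
            ([0, 0, 0, 0], (0, 0)),
            ([10, 20, 30, 40, 50], (20, 40)),
        ],
    )
    def test_linear_interpolation_quartiles(self, doses, expected):
        assert estimate_dosage_range(doses) == pytest.approx(expected)

    def test_empty_list_rejected(self):
        with pytest.raises(InputValidationError):
            estimate_dosage_range([])

    @settings(max_examples=300, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=5000), min_size=1, max_size=40))
    def test_matches_sorted_position_oracle(self, doses):
        got = estimate_dosage_range(doses)
        assert got == pytest.approx(quartile_oracle(doses))

    @given(st.lists(st.floats(min_value=0, max_value=5000), min_size=1, max_size=40))
    def test_iqr_contained_in_data_range(self, doses):
        lo, hi = estimate_dosage_range(doses)
        assert min(doses) - 1e-9 <= lo <= hi <= max(doses) + 1e-9

    def test_tukey_hinges_alternative(self):
        assert estimate_dosage_range([1, 2, 3, 4, 5], method="tukey") == (2, 4)


class TestMedicationSelection:
    def test_most_frequent_medication_wins(self, kb):
        refs = (
            [_case(rx=Prescription(sevelamer=2400), mrn=f"S{i}") for i in range(3)]
            + [_case(rx=Prescription(lanthanum=750), mrn="L0")]
        )
        med, used = select_medication_within_class(refs, ManagementClass.NCPB, kb)
        assert med.name == "sevelamer" and used == 3

    def test_single_option_class(self, kb):
        refs = [_case(rx=Prescription(cinacalcet=25))]
        med, _ = select_medication_within_class(refs, ManagementClass.CALCIMIMETICS, kb)
        assert med.name == "cinacalcet"

    def test_tie_breaks_by_formulary_order(self, kb):
        refs = [
            _case(rx=Prescription(calcium_carbonate=500), mrn="A"),
            _case(rx=Prescription(calcium_acetate=1000), mrn="B"),
        ]
        med, used = select_medication_within_class(refs, ManagementClass.CPB, kb)
        assert med.name == "calcium_carbonate" and used == 1

    def test_unused_class_falls_back_to_first_entry(self, kb):
        refs = [_case(rx=Prescription(sevelamer=2400))]
        med, used = select_medication_within_class(refs, ManagementClass.CPB, kb)
        assert med.name == "calcium_carbonate" and used == 0


def _table5_directives():
    return GenericDirectiveSet(
        calcimimetics="start_or_increase",
        calcitriol="stop",
        vitamin_d_analogs="stop",
        CPB="stop",
        NCPB="start_or_increase",
        dialysate_calcium="reduce_0.25",
    )


class TestAdapt:
    def test_table5_scenario(self, kb):
        """Classic severe case: cinacalcet IQR 25-50, vitamin D and CPB zeroed,
        NCPB started, dialysate lowered."""
        refs = [
            _case(rx=Prescription(cinacalcet=d, sevelamer=s), mrn=f"R{i}")
            for i, (d, s) in enumerate([(25, 2400), (25, 2400), (50, 2400), (50, 2400)])
        ]
        current = Prescription(calcium_carbonate=1500, dialysate_calcium=1.5)
        rec = adapt(_table5_directives(), refs, kb, current, "T1", "type-I")
        assert len(rec.dosage_ranges) == 10
        cina = rec.dosage_ranges["cinacalcet"]
        assert (cina.lower, cina.upper) == (25, 50)
        for stopped in ("calcitriol_po", "calcitriol_iv", "paricalcitol_iv",
                        "alfacalcidol", "calcium_carbonate", "calcium_acetate"):
            rng = rec.dosage_ranges[stopped]
            assert (rng.lower, rng.upper) == (0, 0)
        sev = rec.dosage_ranges["sevelamer"]
        assert (sev.lower, sev.upper) == (2400, 2400)
        dial = rec.dosage_ranges["dialysate_calcium"]
        assert (dial.lower, dial.upper) == (1.25, 1.25)

    def test_single_reference_is_echoed_unmodified(self, kb):
        echo_rx = Prescription(cinacalcet=75, sevelamer=3200, dialysate_calcium=1.5)
        rec = adapt(_table5_directives(), [_case(rx=echo_rx)], kb, Prescription(), "T1", "type-I")
        assert rec.provenance.single_reference_passthrough
        for name, rng in rec.dosage_ranges.items():
            assert rng.lower == rng.upper == echo_rx.dose(name)

    def test_empty_reference_set_is_directive_only_fallback(self, kb):
        rec = adapt(_table5_directives(), [], kb, Prescription(), "T1", "type-I")
        assert rec.provenance.fallback_empty_partition
        assert rec.dosage_ranges == {}

    def test_start_floor_is_at_least_one_dose_step(self, kb):
        refs = [_case(rx=Prescription(cinacalcet=25), mrn=f"R{i}") for i in range(3)]
        rec = adapt(_table5_directives(), refs, kb, Prescription(), "T1", "type-I")
        assert rec.dosage_ranges["cinacalcet"].lower >= 25  # one 25 mg step

    def test_start_floor_respects_current_dose(self, kb):
        refs = [_case(rx=Prescription(cinacalcet=25), mrn=f"R{i}") for i in range(3)]
        current = Prescription(cinacalcet=50)
        rec = adapt(_table5_directives(), refs, kb, current, "T1", "type-I")
        assert rec.dosage_ranges["cinacalcet"].lower >= 50

    def test_maintain_brackets_the_standing_dose(self, kb):
        directives = GenericDirectiveSet(
            calcimimetics="maintain", calcitriol="maintain", vitamin_d_analogs="maintain",
            CPB="maintain", NCPB="maintain", dialysate_calcium="maintain",
        )
        refs = [_case(rx=Prescription(sevelamer=d), mrn=f"R{i}") for i, d in enumerate([800, 1600])]
        current = Prescription(sevelamer=4000, dialysate_calcium=1.5)
        rec = adapt(directives, refs, kb, current, "T26", "type-II")
        rng = rec.dosage_ranges["sevelamer"]
        assert rng.lower <= 4000 <= rng.upper
        assert rec.dosage_ranges["dialysate_calcium"].lower == 1.5

    def test_decrease_or_stop_caps_below_current(self, kb):
        directives = GenericDirectiveSet(
            calcimimetics="decrease_or_stop", calcitriol="maintain", vitamin_d_analogs="maintain",
            CPB="maintain", NCPB="maintain", dialysate_calcium="maintain",
        )
        refs = [_case(rx=Prescription(cinacalcet=d), mrn=f"R{i}") for i, d in enumerate([50, 75])]
        current = Prescription(cinacalcet=50)
        rec = adapt(directives, refs, kb, current, "T26", "type-II")
        rng = rec.dosage_ranges["cinacalcet"]
        assert rng.lower == 0 and rng.upper <= 25

    def test_ranges_within_formulary_reference_ranges(self, kb):
        refs = [
            _case(rx=Prescription(cinacalcet=100, sevelamer=13000), mrn=f"R{i}")
            for i in range(4)
        ]
        rec = adapt(_table5_directives(), refs, kb, Prescription(), "T1", "type-I")
        for name, rng in rec.dosage_ranges.items():
            med = kb.medication(name)
            assert med.low <= rng.lower <= rng.upper <= med.high


class TestRecommendEndToEnd:
    def test_complete_recommendation_covers_ten_factors(self, kb):
        encs = []
        for i in range(4):
            encs.append(make_encounter(mrn=f"P{i}", seq=1, rx=Prescription(sevelamer=2400)))
            encs.append(make_encounter(mrn=f"P{i}", seq=2, rx=Prescription(sevelamer=2400)))
        cb = build_case_base(encs, kb)
        test_enc = make_encounter(mrn="NEW", seq=1)
        rec = recommend(cb, kb, test_enc)
        assert len(rec.dosage_ranges) == 10
        assert set(rec.dosage_ranges) == set(Prescription.FACTORS)

    def test_stable_patient_gets_all_maintain_bracketing_current(self, kb):
        encs = []
        for i in range(4):
            rx = Prescription(sevelamer=2400)
            encs.append(make_encounter(mrn=f"P{i}", seq=1, rx=rx))
            encs.append(make_encounter(mrn=f"P{i}", seq=2, rx=rx))
        cb = build_case_base(encs, kb)
        prev = make_encounter(mrn="NEW", seq=1, rx=Prescription(sevelamer=2400))
        enc = make_encounter(mrn="NEW", seq=2, rx=Prescription())
        rec = recommend(cb, kb, enc, previous=prev)
        assert all(d == "maintain" for d in rec.directive_set.as_dict().values())
        rng = rec.dosage_ranges["sevelamer"]
        assert rng.lower <= 2400 <= rng.upper

    def test_empty_partition_never_crashes(self, kb):
        cb = CaseBase()
        rec = recommend(cb, kb, make_encounter(mrn="X", seq=1))
        assert rec.provenance.fallback_empty_partition

    def test_recommend_is_deterministic(self, kb):
        encs = [make_encounter(mrn=f"P{i}", seq=s) for i in range(3) for s in (1, 2)]
        cb = build_case_base(encs, kb)
        enc = make_encounter(mrn="NEW", seq=1)
        assert recommend(cb, kb, enc) == recommend(cb, kb, enc)
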