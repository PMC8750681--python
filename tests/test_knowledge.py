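"""Domain model: patient typing, lab-state classification, partitioning,
production-rule compilation, knowledge-pack validation."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ckdmbd import (
    Analyte,
    CalcificationAssessment,
    Directive,
    LabState,
    Level,
    PatientType,
    TargetRange,
    Trend,
    assign_partition,
    classify_lab_state,
    classify_patient_type,
    compile_production_rules,
    corrected_calcium,
    validate_knowledge_base,
)
from ckdmbd.knowledge import (
    GenericDirectiveSet,
    InputValidationError,
    PartitionRule,
    RuleCompilationError,
    lab_states,
)


def _state_triple(level=Level.WITHIN, trend=Trend.NOT_INCREASED):
    return {
        a: LabState(analyte=a, level=level, trend=trend)
        for a in (Analyte.PTH, Analyte.CORRECTED_CALCIUM, Analyte.PHOSPHATE)
    }


class TestPatientTyping:
    @pytest.mark.parametrize(
        "score,valvular,expected",
        [
            (6, False, PatientType.TYPE_I),   # moderate vascular calcification
            (5, False, PatientType.TYPE_II),  # mild: at or under the cutoff
            (0, True, PatientType.TYPE_I),    # valvular involvement alone suffices
            (24, False, PatientType.TYPE_I),
            (0, False, PatientType.TYPE_II),
        ],
    )
    def test_calcification_cutoff(self, score, valvular, expected):
        a = CalcificationAssessment(vascular_score=score, valvular_present=valvular)
        assert classify_patient_type(a) is expected

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CalcificationAssessment(vascular_score=25)

    @given(st.integers(min_value=0, max_value=24))
    def test_threshold_is_the_only_switch_point(self, score):
        a = CalcificationAssessment(vascular_score=score, valvular_present=False)
        expected = PatientType.TYPE_I if score > 5 else PatientType.TYPE_II
        assert classify_patient_type(a) is expected


class TestCorrectedCalcium:
    @pytest.mark.parametrize(
        "total,albumin,expected",
        [(9.0, 4.0, 9.0), (8.0, 3.0, 8.8), (9.0, 5.0, 8.2)],
    )
    def test_payne_correction(self, total, albumin, expected):
        assert corrected_calcium(total, albumin) == pytest.approx(expected)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(InputValidationError):
            corrected_calcium(0.0, 4.0)
        with pytest.raises(InputValidationError):
            corrected_calcium(9.0, -1.0)


class TestLabState:
    PTH_I = TargetRange(analyte=Analyte.PTH, patient_type_scope="type-I", low=150, high=300)
    PHOS = TargetRange(analyte=Analyte.PHOSPHATE, low=3.5, high=5.5)
    CA = TargetRange(analyte=Analyte.CORRECTED_CALCIUM, low=7.5, high=10.2)

    @pytest.mark.parametrize(
        "current,previous,rng,level,trend",
        [
            (200, 180, PTH_I, Level.WITHIN, Trend.INCREASED),
            (5.5, 5.5, PHOS, Level.WITHIN, Trend.NOT_INCREASED),  # inclusive upper bound
            (3.5, None, PHOS, Level.WITHIN, Trend.NOT_INCREASED),  # inclusive lower bound
            (7.0, None, CA, Level.BELOW, Trend.NOT_INCREASED),
            (10.21, 10.0, CA, Level.ABOVE, Trend.INCREASED),
            (149.9, 200.0, PTH_I, Level.BELOW, Trend.NOT_INCREASED),
        ],
    )
    def test_level_and_trend(self, current, previous, rng, level, trend):
        s = classify_lab_state(current, previous, rng)
        assert (s.level, s.trend) == (level, trend)

    @given(
        st.floats(min_value=0.1, max_value=1000, allow_nan=False),
        st.floats(min_value=0.1, max_value=1000, allow_nan=False),
    )
    def test_level_monotone_in_current_value(self, a, b):
        lo, hi = sorted((a, b))
        order = {Level.BELOW: 0, Level.WITHIN: 1, Level.ABOVE: 2}
        la = classify_lab_state(lo, None, self.PTH_I).level
        lb = classify_lab_state(hi, None, self.PTH_I).level
        assert order[la] <= order[lb]


class TestPartitioning:
    def test_all_within_type_ii_maps_to_all_maintain(self, kb):
        states = _state_triple()
        pid = assign_partition(kb, PatientType.TYPE_II, states)
        ds = kb.directives_for_partition(pid)
        assert all(d is Directive.MAINTAIN for d in ds.__dict__.values() if isinstance(d, Directive))

    def test_exhaustive_and_exclusive_over_full_grid(self, kb):
        per_analyte = list(itertools.product(Level, Trend))
        n = 0
        for ptype in PatientType:
            for combo in itertools.product(per_analyte, repeat=3):
                states = {
                    a: LabState(analyte=a, level=lv, trend=tr)
                    for a, (lv, tr) in zip(
                        (Analyte.PTH, Analyte.CORRECTED_CALCIUM, Analyte.PHOSPHATE), combo
                    )
                }
                assign_partition(kb, ptype, states)  # raises unless exactly one match
                n += 1
        assert n == 432

    def test_assignment_is_deterministic(self, kb):
        states = _state_triple(Level.ABOVE, Trend.INCREASED)
        pids = {assign_partition(kb, PatientType.TYPE_I, states) for _ in range(3)}
        assert len(pids) == 1

    def test_table5_style_partition_exists(self, kb):
        """Severe case: high PTH with hypercalcemia and hyperphosphatemia gets
        the classic calcimimetic-up / vitamin-D-off / CPB-off / NCPB-up /
        dialysate-down set."""
        expected = {
            "calcimimetics": "start_or_increase",
            "calcitriol": "stop",
            "vitamin_d_analogs": "stop",
            "CPB": "stop",
            "NCPB": "start_or_increase",
            "dialysate_calcium": "reduce_0.25",
        }
        sets = [kb.directive_sets[r.directive_set_id].as_dict() for r in kb.partition_rules]
        assert expected in sets


class TestProductionRules:
    def test_bundled_kb_compiles_to_432_rules(self, kb):
        rules = compile_production_rules(kb)
        assert len(rules) == 432
        assert len({(r.patient_type, r.states) for r in rules}) == 432

    def test_single_type_restriction_compiles_to_216(self, kb):
        restricted = kb.model_copy(
            update={
                "partition_rules": [
                    r for r in kb.partition_rules if r.patient_type is PatientType.TYPE_I
                ],
                "expected_partition_count": 18,
            }
        )
        assert len(compile_production_rules(restricted)) == 216

    def test_uncovered_combination_is_a_compilation_error(self, kb):
        broken = kb.model_copy(update={"partition_rules": kb.partition_rules[1:]})
        with pytest.raises(RuleCompilationError) as err:
            compile_production_rules(broken)
        assert err.value.offending

    def test_rule_lookup_agrees_with_assignment(self, kb):
        rules = compile_production_rules(kb)
        for rule in rules[::37]:
            states = {s.analyte: s for s in rule.states}
            assert assign_partition(kb, rule.patient_type, states) == rule.partition_id


class TestValidation:
    def test_bundled_pack_passes(self, kb):
        report = validate_knowledge_base(kb)
        assert report.passed
        assert report.n_partitions == 33
        assert report.n_production_rules == 432

    def test_duplicate_partition_predicate_fails_exclusivity(self, kb):
        dup = kb.partition_rules[0].model_copy(update={"partition_id": "T99"})
        bad = kb.model_copy(update={"partition_rules": kb.partition_rules + [dup]})
        report = validate_knowledge_base(bad)
        assert not report.passed
        assert any(i.code == "exclusivity_exhaustiveness" for i in report.issues)

    def test_directive_outside_template_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            GenericDirectiveSet(
                calcimimetics="start_or_increase",
                calcitriol="maintain",
                vitamin_d_analogs="maintain",
                CPB="maintain",
                NCPB="maintain",
                dialysate_calcium="reduce by 0.5",
            )
        with pytest.raises(ValueError):
            # 'stop' is not a calcimimetic option; the template says stop-or-decrease
            GenericDirectiveSet(
                calcimimetics="stop",
                calcitriol="maintain",
                vitamin_d_analogs="maintain",
                CPB="maintain",
                NCPB="maintain",
                dialysate_calcium="maintain",
            )

    def test_unknown_selector_key_rejected(self):
        with pytest.raises(ValueError):
            PartitionRule(
                partition_id="T1",
                patient_type="type-I",
                when={"magnesium_level": ["above"]},
                directive_set_id="DS01",
            )


def test_pth_range_is_type_scoped(kb):
    r1 = kb.range_for(Analyte.PTH, PatientType.TYPE_I)
    r2 = kb.range_for(Analyte.PTH, PatientType.TYPE_II)
    assert (r1.low, r1.high) == (150, 300)
    assert (r2.low, r2.high) == (130, 600)
    states_i = lab_states(kb, PatientType.TYPE_I, {
        Analyte.PTH: 400.0, Analyte.CORRECTED_CALCIUM: 9.0, Analyte.PHOSPHATE: 4.5})
    states_ii = lab_states(kb, PatientType.TYPE_II, {
        Analyte.PTH: 400.0, Analyte.CORRECTED_CALCIUM: 9.0, Analyte.PHOSPHATE: 4.5})
    assert states_i[Analyte.PTH].level is Level.ABOVE
    assert states_ii[Analyte.PTH].level is Level.WITHIN
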