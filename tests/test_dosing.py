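"""Rule-engine unit and property tests.

The calculation-weight property tests check the implementation against an
independent literal transcription of the five branch sentences, and verify
that the rules are exhaustive and mutually exclusive over the full input
grid.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lasafe.dosing import (
    assess_risk_factors,
    compute_bmi,
    compute_ibw_devine,
    determine_calculation_weight,
    is_overdose,
    max_safe_dose,
    max_safe_mixture,
    mg_to_max_volume,
    DoseConfigurationError,
)
from lasafe.models import (
    AnestheticSpec,
    DoseMode,
    MixtureComponent,
    MixturePlan,
    PatientRecord,
    RiskFactor,
    Sex,
)

# --------------------------------------------------------------------------
# independent oracle: literal transcription of the five CW branch sentences


def cw_oracle(aw: float, ibw: float, bmi: float):
    fired = []
    if aw <= 70 and bmi < 30 and ibw > aw:
        fired.append((1, aw))
    if aw <= 70 and bmi < 30 and ibw <= aw:
        fired.append((2, ibw))
    if aw <= 70 and bmi >= 30:
        fired.append((3, ibw))
    if aw > 70 and ibw > 70:
        fired.append((4, 70.0))
    if aw > 70 and ibw <= 70:
        fired.append((5, ibw))
    return fired


def make_patient(**overrides) -> PatientRecord:
    base = dict(age=45, sex=Sex.MALE, height=175.0, actual_weight=70.0)
    base.update(overrides)
    return PatientRecord(**base)


class TestAnthropometry:
    @pytest.mark.parametrize(
        "weight,height,expected",
        [
            (70, 170, 24.22),
            (50, 100, 50.0),
            (87, 170, 30.10),
        ],
    )
    def test_bmi_examples(self, weight, height, expected):
        assert compute_bmi(weight, height) == pytest.approx(expected, abs=0.01)

    def test_bmi_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            compute_bmi(0, 170)
        with pytest.raises(ValueError):
            compute_bmi(70, -1)

    @pytest.mark.parametrize(
        "sex,height,expected",
        [
            (Sex.MALE, 152.4, 50.0),
            (Sex.FEMALE, 152.4, 45.5),
            (Sex.MALE, 177.8, 73.0),
            (Sex.FEMALE, 165.0, 45.5 + 2.3 * (165 / 2.54 - 60)),
        ],
    )
    def test_devine_examples(self, sex, height, expected):
        assert compute_ibw_devine(sex, height) == pytest.approx(expected, abs=1e-9)

    def test_devine_rejects_heights_outside_validated_range(self):
        with pytest.raises(ValueError):
            compute_ibw_devine(Sex.MALE, 120.0)

    def test_devine_extrapolates_below_reference_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="lasafe.dosing"):
            ibw = compute_ibw_devine(Sex.FEMALE, 140.0)
        assert ibw < 45.5
        assert "extrapolated" in caplog.text


class TestCalculationWeight:
    @pytest.mark.parametrize(
        "aw,ibw,bmi,cw,rule",
        [
            (60, 65, 22, 60, 1),
            (60, 55, 22, 55, 2),
            (65, 48, 31, 48, 3),
            (100, 80, 29, 70, 4),
            (90, 62, 33, 62, 5),
        ],
    )
    def test_branch_examples(self, aw, ibw, bmi, cw, rule):
        result = determine_calculation_weight(aw, ibw, bmi)
        assert result.cw == pytest.approx(cw)
        assert result.cw_rule == rule

    @given(
        aw=st.floats(0.1, 200),
        ibw=st.floats(0.1, 120),
        bmi=st.floats(0.1, 60),
    )
    def test_rules_exhaustive_exclusive_and_match_oracle(self, aw, ibw, bmi):
        fired = cw_oracle(aw, ibw, bmi)
        assert len(fired) == 1, "exactly one branch sentence must apply"
        rule, cw = fired[0]
        result = determine_calculation_weight(aw, ibw, bmi)
        assert result.cw_rule == rule
        assert result.cw == pytest.approx(min(cw, 70.0))

    @given(
        aw=st.floats(0.1, 200),
        ibw=st.floats(0.1, 120),
        bmi=st.floats(0.1, 60),
    )
    def test_cap_and_bound_invariants(self, aw, ibw, bmi):
        result = determine_calculation_weight(aw, ibw, bmi)
        assert 0 < result.cw <= 70.0
        assert result.cw <= max(aw, ibw) + 1e-12


class TestRiskFactors:
    def test_no_factors(self):
        risk = assess_risk_factors(make_patient(), ())
        assert risk.factors_present == frozenset()
        assert risk.adjustment_factor == 1.0

    def test_single_factor_age(self):
        risk = assess_risk_factors(make_patient(age=72), ())
        assert risk.factors_present == {RiskFactor.AGE_GE_70}
        assert risk.adjustment_factor == 0.8

    def test_two_factors(self):
        risk = assess_risk_factors(make_patient(age=72, gfr=40), ())
        assert risk.factors_present == {RiskFactor.AGE_GE_70, RiskFactor.RENAL}
        assert risk.adjustment_factor == 0.7

    @pytest.mark.parametrize(
        "overrides,factor",
        [
            ({"gfr": 49.9}, RiskFactor.RENAL),
            ({"prothrombin_time": 49.9}, RiskFactor.HEPATIC),
            ({"lvef": 30.0}, RiskFactor.HEART_FAILURE),
            ({"pregnant": True, "sex": Sex.FEMALE}, RiskFactor.PREGNANCY),
            ({"medications": ("Ciprofloxacin",)}, RiskFactor.CYP_INHIBITOR),
        ],
    )
    def test_each_factor_threshold(self, overrides, factor):
        risk = assess_risk_factors(make_patient(**overrides), {"ciprofloxacin"})
        assert risk.factors_present == {factor}

    @pytest.mark.parametrize(
        "overrides",
        [
            {"gfr": 50.0},  # at the threshold: not renal dysfunction
            {"prothrombin_time": 50.0},
            {"lvef": 30.1},  # strictly above the LVEF cutoff
            {"age": 69},
        ],
    )
    def test_threshold_boundaries_are_on_the_printed_side(self, overrides):
        risk = assess_risk_factors(make_patient(**overrides), ())
        assert risk.factors_present == frozenset()

    def test_missing_markers_are_not_risk_factors(self):
        patient = make_patient(gfr=None, prothrombin_time=None, lvef=None)
        assert assess_risk_factors(patient, ()).adjustment_factor == 1.0


ROPI = AnestheticSpec(name="ropivacaine", dose_limit=3.0, concentration=7.5)
LEVO = AnestheticSpec(name="levobupivacaine", dose_limit=2.0, concentration=5.0)


class TestMaxSafeDose:
    def test_comprehensive_no_risk(self):
        # 80 kg, IBW 73 kg (177.8 cm male) → rule 5, CW 70 after... IBW>70?
        # 177.8 cm male IBW = 73 > 70 and AW 80 > 70 → rule 4, CW = 70.
        patient = make_patient(height=177.8, actual_weight=80.0)
        result = max_safe_dose(patient, ROPI, DoseMode.COMPREHENSIVE)
        assert result.max_mg == pytest.approx(210.0)
        assert result.max_ml == 28
        assert any("rule 4" in t for t in result.trace)

    def test_one_risk_factor_cuts_20pct(self):
        patient = make_patient(height=177.8, actual_weight=80.0, age=75)
        result = max_safe_dose(patient, ROPI)
        assert result.max_mg == pytest.approx(168.0)

    def test_two_risk_factors_cut_30pct(self):
        patient = make_patient(height=177.8, actual_weight=80.0, age=75, gfr=30)
        result = max_safe_dose(patient, ROPI)
        assert result.max_mg == pytest.approx(147.0)

    def test_simplified_aw(self):
        patient = make_patient(actual_weight=55.0, height=170.0, age=80)
        result = max_safe_dose(patient, ROPI, DoseMode.SIMPLIFIED_AW)
        # bare AW × limit: no cap, no risk reduction
        assert result.max_mg == pytest.approx(165.0)

    def test_simplified_ibw(self):
        patient = make_patient(height=177.8, actual_weight=120.0)
        result = max_safe_dose(patient, ROPI, DoseMode.SIMPLIFIED_IBW)
        assert result.max_mg == pytest.approx(73.0 * 3.0)

    def test_missing_dose_limit_is_configuration_error(self):
        bad = AnestheticSpec.model_construct(
            name="x", dose_limit=None, concentration=None
        )
        with pytest.raises(DoseConfigurationError):
            max_safe_dose(make_patient(), bad)

    def test_comprehensive_never_exceeds_cap_times_limit(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            patient = make_patient(
                age=int(rng.integers(18, 91)),
                sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                height=float(rng.uniform(145, 200)),
                actual_weight=float(rng.uniform(40, 140)),
            )
            result = max_safe_dose(patient, ROPI)
            assert result.max_mg <= 70 * ROPI.dose_limit + 1e-9

    def test_adding_risk_factors_never_raises_dose(self):
        base = make_patient(height=170.0, actual_weight=65.0)
        seq = [
            base,
            base.model_copy(update={"age": 75}),
            base.model_copy(update={"age": 75, "gfr": 30.0}),
            base.model_copy(update={"age": 75, "gfr": 30.0, "lvef": 25.0}),
        ]
        doses = [max_safe_dose(p, ROPI).max_mg for p in seq]
        assert all(a >= b for a, b in zip(doses, doses[1:]))
        assert doses[2] == pytest.approx(doses[3])  # stable at ≥2 factors


class TestVolumeConversion:
    @pytest.mark.parametrize(
        "mg,conc,ml", [(210, 7.5, 28), (209, 7.5, 27), (0, 5.0, 0)]
    )
    def test_floor_examples(self, mg, conc, ml):
        assert mg_to_max_volume(mg, conc) == ml

    def test_rejects_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            mg_to_max_volume(100, 0)

    @given(mg=st.floats(0, 5000), conc=st.floats(0.1, 50))
    def test_volume_consistency_invariant(self, mg, conc):
        ml = mg_to_max_volume(mg, conc)
        assert ml * conc <= mg + 1e-9
        assert mg < (ml + 1) * conc + 1e-6


class TestMixtures:
    def test_single_component_degenerates_to_standalone(self):
        patient = make_patient(height=177.8, actual_weight=80.0)
        plan = MixturePlan(components=(MixtureComponent(drug=ROPI, proportion=1.0),))
        mixed = max_safe_mixture(patient, plan)[0]
        alone = max_safe_dose(patient, ROPI)
        assert mixed.max_mg == pytest.approx(alone.max_mg)
        assert mixed.max_ml == alone.max_ml

    def test_even_split_halves_each_budget(self):
        patient = make_patient(height=177.8, actual_weight=80.0)
        plan = MixturePlan(
            components=(
                MixtureComponent(drug=ROPI, proportion=0.5),
                MixtureComponent(drug=LEVO, proportion=0.5),
            )
        )
        results = max_safe_mixture(patient, plan)
        assert results[0].max_mg == pytest.approx(105.0)  # half of 210
        assert results[1].max_mg == pytest.approx(70.0)  # half of 140

    @given(split=st.floats(0.01, 0.99))
    def test_budget_conservation(self, split):
        patient = make_patient(height=160.0, actual_weight=95.0, age=74)
        plan = MixturePlan(
            components=(
                MixtureComponent(drug=ROPI, proportion=split),
                MixtureComponent(drug=LEVO, proportion=1.0 - split),
            )
        )
        results = max_safe_mixture(patient, plan)
        budget = sum(
            r.max_mg / max_safe_dose(patient, c.drug).max_mg
            for r, c in zip(results, plan.components)
        )
        assert budget == pytest.approx(1.0, abs=1e-9)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            MixturePlan(
                components=(
                    MixtureComponent(drug=ROPI, proportion=0.5),
                    MixtureComponent(drug=LEVO, proportion=0.6),
                )
            )


class TestOverdosePredicate:
    def test_equal_to_reference_is_safe(self):
        patient = make_patient(actual_weight=55.0, height=170.0)
        ref = max_safe_dose(patient, ROPI, DoseMode.SIMPLIFIED_AW)
        assert ref.max_mg == pytest.approx(165.0)
        assert not is_overdose(165.0, ref, "mg")
        assert is_overdose(165.0 + 1e-9, ref, "mg")

    def test_ml_comparison_uses_floored_volume(self):
        patient = make_patient(height=177.8, actual_weight=80.0)
        ref = max_safe_dose(patient, ROPI)  # 210 mg → 28 mL
        assert is_overdose(20.6, ref, "mL") is False
        assert is_overdose(29, ref, "mL") is True

    def test_unit_mismatch_without_concentration_errors(self):
        ref = max_safe_dose(
            make_patient(),
            AnestheticSpec(name="plain", dose_limit=3.0),
        )
        with pytest.raises(ValueError):
            is_overdose(10, ref, "mL")
        assert is_overdose(10, ref, "mL", concentration=7.5) in (True, False)
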