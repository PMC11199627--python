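"""Profiles: BMI, energy targets, macro ranges and input encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutriplan.profiles import (EnergyRule, MacroTargets, UserProfile,
                                compute_bmi, compute_energy_target,
                                derive_macro_targets, encode_profile,
                                ensure_target_ei, read_profiles_csv,
                                write_profiles_csv, NUTRIENTS,
                                PROFILE_VECTOR_FIELDS)


def make_profile(**overrides):
    base = dict(user_id="u", weight=68.0, height=1.73, age=41, bmr=1596.83,
                pal=1.195, group="Healthy adults")
    base.update(overrides)
    return UserProfile(**base)


class TestBMI:
    @pytest.mark.parametrize("weight,height,expected", [
        (68, 1.73, 22.72), (100, 2.0, 25.00), (130, 1.64, 48.33)])
    def test_worked_examples(self, weight, height, expected):
        assert compute_bmi(weight, height) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("weight,height", [(0, 1.7), (70, 0), (-5, 1.7)])
    def test_nonpositive_inputs_rejected(self, weight, height):
        with pytest.raises(ValueError):
            compute_bmi(weight, height)


class TestEnergyTarget:
    def test_middle_branch(self):
        profile = make_profile()  # BMI 22.72
        assert compute_energy_target(profile) == pytest.approx(1908.21, abs=0.005)

    def test_upper_branch_subtracts_adjustment(self):
        profile = make_profile(weight=130, height=1.64, bmr=1980.25,
                               group="Adults who are obese")  # BMI 48.33
        assert compute_energy_target(profile) == pytest.approx(1866.40, abs=0.005)

    def test_boundary_bmi_gets_the_gain_adjustment(self):
        # BMI exactly at the low threshold belongs to the underweight branch
        height = 1.8
        weight = 18.5 * height ** 2
        profile = make_profile(weight=weight, height=height, bmr=1500, pal=1.2)
        assert compute_energy_target(profile) == pytest.approx(
            1500 * 1.2 + 500)

    @given(bmi=st.floats(15.0, 60.0))
    @settings(derandomize=True, max_examples=60)
    def test_branches_partition_and_jump_by_d(self, bmi):
        height = 1.8
        profile = make_profile(weight=bmi * height ** 2, height=height,
                               bmr=2000, pal=1.3)
        rule = EnergyRule()
        base = 2000 * 1.3
        target = compute_energy_target(profile, rule)
        if bmi <= rule.bmi_low:
            assert target == base + rule.d_adjust
        elif bmi >= rule.bmi_high:
            assert target == base - rule.d_adjust
        else:
            assert target == base


class TestMacroTargets:
    def test_percent_ranges_convert_via_atwater(self, guidelines):
        profile = make_profile(bmr=2000 / 1.0, pal=1.0)  # EI = 2000 kcal
        targets = derive_macro_targets(profile, guidelines)
        assert targets.min_val["carbohydrate"] == pytest.approx(225.0)
        assert targets.max_val["carbohydrate"] == pytest.approx(300.0)
        assert targets.min_val["sfa"] == pytest.approx(0.0)
        assert targets.max_val["sfa"] == pytest.approx(0.10 * 2000 / 9)

    def test_homogeneous_in_energy(self, guidelines):
        p1 = make_profile(bmr=1500, pal=1.0)
        p2 = make_profile(bmr=3000, pal=1.0)
        t1 = derive_macro_targets(p1, guidelines)
        t2 = derive_macro_targets(p2, guidelines)
        for nutrient in NUTRIENTS:
            assert t2.max_val[nutrient] == pytest.approx(
                2 * t1.max_val[nutrient])
            assert t2.min_val[nutrient] == pytest.approx(
                2 * t1.min_val[nutrient])

    def test_group_override_tightens_sfa_for_cvd(self, guidelines):
        p = make_profile(group="Adults with CVD", has_cvd=True,
                         weight=130, height=1.64, bmr=1980.25)
        t = derive_macro_targets(p, guidelines)
        ei = ensure_target_ei(p)
        assert t.max_val["sfa"] == pytest.approx(0.07 * ei / 9)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            MacroTargets({n: 10 for n in NUTRIENTS},
                         {n: (5 if n == "fat" else 20) for n in NUTRIENTS})


class TestEncodeProfile:
    def test_bounds_map_to_unit_interval(self, guidelines):
        bounds = guidelines["normalization_bounds"]
        low = make_profile(weight=46, height=1.73)
        high = make_profile(weight=180, height=1.64,
                            group="Adults who are obese")
        assert encode_profile(low, bounds)[0] == 0.0
        assert encode_profile(high, bounds)[0] == 1.0

    def test_flags_encode_binary_tail(self, guidelines):
        p = make_profile(group="Adults with CVD", has_cvd=True, weight=130,
                         height=1.64)
        vec = encode_profile(p, guidelines["normalization_bounds"])
        assert vec.shape == (len(PROFILE_VECTOR_FIELDS),)
        assert tuple(vec[-3:]) == (1.0, 0.0, 0.0)
        assert np.all((vec >= 0) & (vec <= 1))

    def test_missing_bound_is_config_error(self, guidelines):
        bounds = {k: v for k, v in
                  guidelines["normalization_bounds"].items() if k != "age"}
        with pytest.raises(ValueError, match="age"):
            encode_profile(make_profile(), bounds)

    def test_deterministic(self, guidelines):
        bounds = guidelines["normalization_bounds"]
        p = make_profile()
        assert np.array_equal(encode_profile(p, bounds),
                              encode_profile(p, bounds))


class TestProfileValidation:
    def test_inconsistent_bmi_rejected(self):
        with pytest.raises(ValueError, match="BMI"):
            make_profile(bmi=30.0)

    def test_group_flag_consistency_enforced(self):
        with pytest.raises(ValueError, match="CVD"):
            make_profile(group="Adults with CVD", has_cvd=False)

    def test_pal_floor(self):
        with pytest.raises(ValueError, match="PAL"):
            make_profile(pal=0.8)


class TestProfileCSV:
    def test_reference_cohort_loads_fully(self, reference_users):
        assert len(reference_users) == 20
        by_id = {p.user_id: p for p in reference_users}
        assert by_id["13"].has_cvd and by_id["13"].has_iron_def
        assert by_id["15"].has_t2d

    def test_round_trip(self, reference_users, tmp_path):
        out = tmp_path / "users.csv"
        write_profiles_csv(reference_users, out)
        again = read_profiles_csv(out)
        for a, b in zip(reference_users, again):
            assert a.user_id == b.user_id
            assert a.weight == pytest.approx(b.weight)
            assert a.group == b.group
            assert a.has_cvd == b.has_cvd
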