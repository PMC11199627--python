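"""Synthetic cohort, meal database and ground-truth plan generators."""

from collections import Counter

import numpy as np
import pytest

from nutriplan.meals import SLOTS
from nutriplan.profiles import compute_bmi, write_profiles_csv
from nutriplan.synth import (GROUP_COUNTS, SLOT_NUTRITION, CohortSpec,
                             MealDistSpec, _truncnorm_parent,
                             assemble_truth_plans, simulate_meal_db,
                             simulate_profiles, truth_plans_frame)


class TestCohort:
    def test_reference_size_reproduces_group_counts_exactly(self):
        profiles = simulate_profiles(CohortSpec(n_users=3000, seed=0))
        counts = Counter(p.group for p in profiles)
        assert dict(counts) == GROUP_COUNTS
        assert counts["Adults with CVD"] == 706

    def test_fixed_seed_gives_byte_identical_csv(self, tmp_path):
        for name in ("a.csv", "b.csv"):
            write_profiles_csv(
                simulate_profiles(CohortSpec(n_users=60, seed=21)),
                tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() \
            == (tmp_path / "b.csv").read_bytes()

    def test_internal_consistency_and_group_constraints(self):
        profiles = simulate_profiles(CohortSpec(n_users=400, seed=3))
        for p in profiles:
            assert abs(p.bmi - compute_bmi(p.weight, p.height)) < 0.005
            assert 46 <= p.weight <= 180
            assert 1.60 <= p.height <= 2.0
            assert p.target_ei > 0
            if p.group == "Adults who are obese":
                assert p.bmi >= 30 - 0.05
            if p.group == "Adults who are overweight":
                assert 25 - 0.05 <= p.bmi <= 30 + 0.05
            if p.group == "Healthy adolescents":
                assert 15 <= p.age <= 19
            if p.group == "Healthy older adults":
                assert p.age >= 65
            if p.group == "Athletes":
                assert p.pal >= 1.7

    def test_sexes_balanced(self):
        profiles = simulate_profiles(CohortSpec(n_users=3000, seed=4))
        counts = Counter(p.sex for p in profiles)
        assert abs(counts["male"] - counts["female"]) <= len(GROUP_COUNTS)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(n_users=10, proportions={"Healthy adults": 0.5})


class TestMealDb:
    def test_slot_counts_default_to_published_sizes(self, tiny_db):
        db = simulate_meal_db(MealDistSpec(seed=1))
        assert db.slot_counts() == {"breakfast": 286, "morning snack": 258,
                                    "lunch": 255, "afternoon snack": 253,
                                    "dinner": 238, "supper": 59}
        assert db.vocab_size == 1349

    def test_marginals_match_targets_within_sampling_error(self):
        db = simulate_meal_db(MealDistSpec(seed=2))
        for slot in SLOTS:
            mean, std = SLOT_NUTRITION[slot]["calories"]
            n = len(db.by_slot[slot])
            sample = [db[i].calories for i in db.by_slot[slot]]
            assert abs(np.mean(sample) - mean) < 3 * std / np.sqrt(n)

    def test_zero_std_collapses_slot(self):
        nutrition = {s: {k: (v[0], 0.0) for k, v in d.items()}
                     for s, d in SLOT_NUTRITION.items()}
        db = simulate_meal_db(MealDistSpec(
            slot_nutrition=nutrition,
            slot_counts={s: 4 for s in SLOTS}, seed=3))
        for slot in SLOTS:
            cals = {db[i].calories for i in db.by_slot[slot]}
            assert len(cals) == 1

    def test_no_negative_nutrients_and_sfa_bounded(self):
        db = simulate_meal_db(MealDistSpec(seed=4))
        for m in db.meals:
            assert min(m.calories, m.protein, m.carbohydrate, m.fat,
                       m.sfa) >= 0
            assert m.sfa <= m.fat + 1e-9

    def test_deterministic_under_seed(self):
        a = simulate_meal_db(MealDistSpec(seed=5))
        b = simulate_meal_db(MealDistSpec(seed=5))
        assert all(x == y for x, y in zip(a.meals, b.meals))


class TestTruncnormMatching:
    @pytest.mark.parametrize("mean,std", [(423.75, 157.87), (169.16, 136.85),
                                          (600.19, 259.45)])
    def test_parent_parameters_recover_target_moments(self, mean, std):
        from scipy import stats
        mu, sigma = _truncnorm_parent(mean, std)
        dist = stats.truncnorm(-mu / sigma, np.inf, loc=mu, scale=sigma)
        assert dist.mean() == pytest.approx(mean, rel=1e-6)
        assert dist.std() == pytest.approx(std, rel=1e-6)

    def test_infeasible_cv_returns_none(self):
        # a zero-truncated normal cannot exceed CV = 1 (e.g. 1.28 +/- 2.20)
        assert _truncnorm_parent(1.28, 2.20) is None


class TestTruthPlans:
    def test_plan_count_is_users_times_days(self, small_cohort, tiny_db):
        plans = assemble_truth_plans(small_cohort[:10], tiny_db,
                                     days_per_user=28, seed=6)
        assert len(plans) == 10 * 28

    def test_accepted_plans_within_energy_tolerance(self, small_cohort,
                                                    tiny_db):
        by_id = {p.user_id: p for p in small_cohort}
        plans = assemble_truth_plans(small_cohort[:20], tiny_db,
                                     days_per_user=2, seed=7)
        for tp in plans:
            target = by_id[tp.profile_id].target_ei
            assert tp.rel_energy_error == pytest.approx(
                abs(tp.plan.ei_raw - target) / target, rel=1e-9)
            if tp.accepted:
                assert tp.rel_energy_error <= 0.10

    def test_planted_exact_solution_is_found(self, small_cohort, guidelines):
        """A database where one meal per slot sums exactly to the target."""
        from nutriplan.meals import Meal, MealDatabase
        from nutriplan.synth import SLOT_NUTRITION
        profile = small_cohort[0]
        shares = np.array([SLOT_NUTRITION[s]["calories"][0] for s in SLOTS])
        shares = shares / shares.sum() * profile.target_ei
        meals = [Meal(meal_id=i, name=f"exact {s}", slot=s,
                      calories=float(shares[i]), protein=10,
                      carbohydrate=30, fat=8, sfa=2)
                 for i, s in enumerate(SLOTS)]
        # decoys far from every slot share
        decoys = [Meal(meal_id=6 + i, name=f"decoy {s}", slot=s,
                       calories=float(shares[i] * 3 + 500), protein=10,
                       carbohydrate=30, fat=8, sfa=2)
                  for i, s in enumerate(SLOTS)]
        db = MealDatabase(meals + decoys)
        plans = assemble_truth_plans([profile], db, days_per_user=1, seed=8)
        assert plans[0].plan.ei_raw == pytest.approx(profile.target_ei)

    def test_frame_layout(self, small_cohort, tiny_db):
        plans = assemble_truth_plans(small_cohort[:3], tiny_db,
                                     days_per_user=2, seed=9)
        frame = truth_plans_frame(plans)
        assert list(frame.columns) == ["profile_id", "day"] \
            + [f"meal_{t}" for t in range(6)]
        assert len(frame) == 6
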