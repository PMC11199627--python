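"""Plan generation, weekly masking and the portion optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutriplan.meals import MealDatabase, SLOTS
from nutriplan.model import DietVAE, ModelConfig
from nutriplan.planner import (DailyPlan, PortionAdjustment, generate_daily,
                               generate_weekly, optimize_portions)
from nutriplan.synth import MealDistSpec, simulate_meal_db
from tests.test_meals import make_meal


def plan_from_calories(calories):
    meals = [make_meal(meal_id=i, slot=slot, name=f"{slot} {i}",
                       calories=c, protein=c / 20, carbohydrate=c / 8,
                       fat=c / 40, sfa=c / 120)
             for i, (slot, c) in enumerate(zip(SLOTS, calories))]
    return DailyPlan(meals=meals)


class TestOptimizer:
    def test_hand_arithmetic(self):
        plan = plan_from_calories([400, 150, 500, 150, 300, 100])  # 1600
        adjusted = optimize_portions(plan, 2000.0)
        assert adjusted.portion_factor == pytest.approx(1.25)
        assert adjusted.ei_adjusted == pytest.approx(2000.0)
        adj = PortionAdjustment(ei_target=2000, ei_plan=1600)
        assert adj.diff_frac == pytest.approx(0.25)

    def test_matching_energy_is_identity(self):
        plan = plan_from_calories([400, 150, 500, 150, 300, 100])
        adjusted = optimize_portions(plan, plan.ei_raw)
        assert adjusted.portion_factor == pytest.approx(1.0)

    def test_nutrients_scale_with_energy(self):
        plan = plan_from_calories([400, 150, 500, 150, 300, 100])
        adjusted = optimize_portions(plan, 2000.0)
        assert np.allclose(adjusted.nutrients_adjusted,
                           1.25 * plan.nutrients_raw)

    def test_degenerate_plan_rejected(self):
        plan = plan_from_calories([0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="non-positive"):
            optimize_portions(plan, 2000.0)

    @given(ei_plan=st.floats(500, 5000), ei_target=st.floats(800, 4000))
    @settings(derandomize=True, max_examples=80)
    def test_exactness_property(self, ei_plan, ei_target):
        """Adjusted energy hits the target to float rounding for any plan."""
        share = ei_plan / 6
        plan = plan_from_calories([share] * 6)
        adjusted = optimize_portions(plan, ei_target)
        assert abs(adjusted.ei_adjusted - ei_target) / ei_target < 1e-9


class TestDailyPlan:
    def test_slot_order_enforced(self):
        meals = [make_meal(meal_id=i, slot=s) for i, s in enumerate(SLOTS)]
        meals[0], meals[1] = meals[1], meals[0]
        with pytest.raises(ValueError, match="slot order"):
            DailyPlan(meals=meals)

    def test_energy_bookkeeping(self):
        plan = plan_from_calories([400, 150, 500, 150, 300, 100])
        plan = optimize_portions(plan, 1800)
        assert plan.ei_adjusted == pytest.approx(
            plan.portion_factor * plan.ei_raw, rel=1e-12)


@pytest.fixture(scope="module")
def single_choice_db():
    meals = [make_meal(meal_id=i, slot=s, name=f"only {s}")
             for i, s in enumerate(SLOTS)]
    return MealDatabase(meals)


class TestGeneration:
    def test_single_meal_per_slot_is_forced(self, single_choice_db,
                                            guidelines, reference_users):
        model = DietVAE(ModelConfig(vocab_size=6, encoder_hidden=8,
                                    latent_dim=4, decoder_hidden=8, seed=2),
                        bounds=guidelines["normalization_bounds"])
        plan = generate_daily(reference_users[0], model, single_choice_db,
                              seed=1)
        assert plan.meal_ids == list(range(6))
        assert [m.slot for m in plan.meals] == list(SLOTS)

    def test_fixed_seed_reproduces_plan(self, tiny_db, tiny_model,
                                        reference_users):
        a = generate_daily(reference_users[0], tiny_model, tiny_db, seed=4)
        b = generate_daily(reference_users[0], tiny_model, tiny_db, seed=4)
        assert a.meal_ids == b.meal_ids

    def test_weekly_hard_mask_gives_unique_slots(self, tiny_db, tiny_model,
                                                 reference_users):
        week = generate_weekly(reference_users[0], tiny_model, tiny_db,
                               seed=5, mask_lambda=0.0)
        for t in range(6):
            ids = [day.meal_ids[t] for day in week.days]
            assert len(set(ids)) == 7  # 8 meals per slot, 7 distinct days

    def test_unit_lambda_disables_masking(self, tiny_db):
        from nutriplan.planner import _WeeklyMask
        mask = _WeeklyMask(tiny_db, mask_lambda=1.0)
        mask.record("breakfast", tiny_db.by_slot["breakfast"][0])
        assert np.all(mask.weights("breakfast") == 1.0)  # no-op: repeats ok

    def test_zero_lambda_removes_used_meals(self, tiny_db):
        from nutriplan.planner import _WeeklyMask
        mask = _WeeklyMask(tiny_db, mask_lambda=0.0)
        used = tiny_db.by_slot["breakfast"][0]
        mask.record("breakfast", used)
        assert mask.weights("breakfast")[used] == 0.0

    def test_pool_exhaustion_resets_least_recently_used(self, guidelines,
                                                        reference_users):
        spec = MealDistSpec(slot_counts={s: 3 for s in SLOTS}, seed=9)
        db = simulate_meal_db(spec)
        model = DietVAE(ModelConfig(vocab_size=db.vocab_size,
                                    encoder_hidden=8, latent_dim=4,
                                    decoder_hidden=8, seed=3),
                        bounds=guidelines["normalization_bounds"])
        week = generate_weekly(reference_users[0], model, db, seed=6,
                               mask_lambda=0.0)
        for t in range(6):
            ids = [day.meal_ids[t] for day in week.days]
            assert len(set(ids[:3])) == 3       # pool exhausted by day 3
            assert len(set(ids)) == 3           # then recycled

    def test_optimized_week_hits_target_every_day(self, tiny_db, tiny_model,
                                                  reference_users):
        profile = reference_users[10]
        week = generate_weekly(profile, tiny_model, tiny_db, seed=7)
        for day in week.days:
            assert day.ei_adjusted == pytest.approx(profile.target_ei,
                                                    rel=1e-12)

    def test_vocabulary_mismatch_rejected(self, tiny_db, guidelines,
                                          reference_users):
        model = DietVAE(ModelConfig(vocab_size=5, encoder_hidden=8,
                                    latent_dim=4, decoder_hidden=8),
                        bounds=guidelines["normalization_bounds"])
        with pytest.raises(ValueError, match="vocabulary"):
            generate_daily(reference_users[0], model, tiny_db)
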