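"""Inference: daily/weekly meal-plan generation and the portion optimizer.

A daily plan is one meal per slot (breakfast through supper), selected by
running the decoder on a fresh latent sample and taking the most probable
admissible meal per slot. A weekly plan repeats this seven times with seven
independent latent draws; a masking scheme multiplies the probability of
meals already chosen earlier in the week for the same slot by a factor
``mask_lambda`` (default 0 = hard removal) so the week stays varied. When a
slot's unused pool empties mid-week the mask forgets its least-recently-used
entries until a choice exists again.

The portion optimizer rescales every meal in a day by the single factor
1 + (EI - EI_plan)/EI_plan, where EI is the user's target energy and EI_plan
the plan's energy at reference portions; nutrient totals scale by the same
factor, and the adjusted plan energy matches the target exactly up to float
rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .meals import Meal, MealDatabase, SLOTS
from .model import DietVAE
from .profiles import UserProfile, encode_profile, ensure_target_ei


@dataclass
class DailyPlan:
    meals: list            # 6 Meal records, breakfast -> supper
    portion_factor: float = 1.0

    def __post_init__(self):
        if len(self.meals) != len(SLOTS):
            raise ValueError("a daily plan needs exactly 6 meals")
        for meal, slot in zip(self.meals, SLOTS):
            if meal.slot != slot:
                raise ValueError(
                    f"slot order violated: expected {slot}, got {meal.slot}")
        if self.portion_factor <= 0:
            raise ValueError("portion_factor must be positive")

    @property
    def ei_raw(self) -> float:
        """Plan energy (kcal) at reference portions."""
        return float(sum(m.calories for m in self.meals))

    @property
    def ei_adjusted(self) -> float:
        return self.portion_factor * self.ei_raw

    @property
    def nutrients_raw(self) -> np.ndarray:
        """(protein, carbohydrate, fat, sfa) grams at reference portions."""
        return np.sum([m.macro_vector for m in self.meals], axis=0)

    @property
    def nutrients_adjusted(self) -> np.ndarray:
        return self.portion_factor * self.nutrients_raw

    @property
    def meal_ids(self) -> list[int]:
        return [m.meal_id for m in self.meals]


@dataclass
class WeeklyPlan:
    days: list                      # 7 DailyPlan
    mask_history: dict = field(default_factory=dict)  # slot -> ordered ids

    def __post_init__(self):
        if len(self.days) != 7:
            raise ValueError("a weekly plan has exactly 7 days")

    def to_dict(self) -> dict:
        return {
            "days": [
                {"portion_factor": day.portion_factor,
                 "ei_raw": day.ei_raw,
                 "ei_adjusted": day.ei_adjusted,
                 "meals": [{"slot": m.slot, "meal_id": m.meal_id,
                            "name": m.name,
                            "calories": m.calories * day.portion_factor}
                           for m in day.meals]}
                for day in self.days]}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_table(self) -> str:
        """Human-readable weekly table (meal name + scaled portion)."""
        lines = []
        for i, day in enumerate(self.days, start=1):
            lines.append(f"Day {i}  (energy {day.ei_adjusted:.0f} kcal, "
                         f"portion factor {day.portion_factor:.3f})")
            for m in day.meals:
                grams = m.base_portion * day.portion_factor
                lines.append(f"  {m.slot:<15s} {m.name}  "
                             f"(x{grams:.2f} portion, "
                             f"{m.calories * day.portion_factor:.0f} kcal)")
        return "\n".join(lines)


@dataclass(frozen=True)
class PortionAdjustment:
    """Record of one optimizer application."""
    ei_target: float
    ei_plan: float

    @property
    def diff_frac(self) -> float:
        return (self.ei_target - self.ei_plan) / self.ei_plan

    @property
    def factor(self) -> float:
        return 1.0 + self.diff_frac


class _WeeklyMask:
    """Per-slot memory of previously selected meals."""

    def __init__(self, db: MealDatabase, mask_lambda: float):
        if not 0.0 <= mask_lambda <= 1.0:
            raise ValueError("mask_lambda must be in [0, 1]")
        self.db = db
        self.mask_lambda = mask_lambda
        self.history: dict[str, list[int]] = {s: [] for s in SLOTS}

    def weights(self, slot: str) -> np.ndarray:
        """(M,) multiplicative probability weights for this slot."""
        w = np.ones(self.db.vocab_size)
        if self.mask_lambda == 1.0:
            return w
        pool = set(self.db.by_slot[slot])
        # forget least-recently-used entries while the slot pool is exhausted
        while self.history[slot] and not (pool - set(self.history[slot])):
            self.history[slot].pop(0)
        for mid in self.history[slot]:
            w[mid] = self.mask_lambda
        return w

    def record(self, slot: str, meal_id: int) -> None:
        if meal_id in self.history[slot]:
            self.history[slot].remove(meal_id)
        self.history[slot].append(meal_id)


def _select_meals(model: DietVAE, db: MealDatabase, x: np.ndarray,
                  rng: np.random.Generator,
                  mask: _WeeklyMask | None) -> list[Meal]:
    slot_masks = db.slot_masks()
    latent = model.encode(x[None, :], rng=rng)
    trace = model.decode(latent.z, slot_masks)
    probs = trace.probs[0]  # (6, M)
    chosen: list[Meal] = []
    for t, slot in enumerate(SLOTS):
        p = probs[t].copy()
        if mask is not None:
            p *= mask.weights(slot)
        if p.sum() <= 0:  # defensive: all admissible mass masked away
            p = probs[t] * slot_masks[t]
        meal_id = int(p.argmax())
        if mask is not None:
            mask.record(slot, meal_id)
        chosen.append(db[meal_id])
    return chosen


def generate_daily(profile: UserProfile, model: DietVAE, db: MealDatabase,
                   seed: int = 0, _rng: np.random.Generator | None = None,
                   _mask: _WeeklyMask | None = None) -> DailyPlan:
    """Generate one daily plan for a user (fresh latent sample per call)."""
    if model.config.vocab_size != db.vocab_size:
        raise ValueError("model vocabulary does not match the meal database")
    bounds = model.bounds
    if bounds is None:
        raise ValueError("model carries no normalization bounds")
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    x = encode_profile(profile, bounds)
    return DailyPlan(meals=_select_meals(model, db, x, rng, _mask))


def generate_weekly(profile: UserProfile, model: DietVAE, db: MealDatabase,
                    seed: int = 0, mask_lambda: float = 0.0,
                    optimize: bool = True) -> WeeklyPlan:
    """Seven daily plans from seven independent latent samples, with
    anti-repetition masking; portions optimized to the user's target energy
    unless ``optimize=False``."""
    rng = np.random.default_rng(seed)
    mask = _WeeklyMask(db, mask_lambda)
    target = ensure_target_ei(profile)
    days = []
    for _ in range(7):
        day = generate_daily(profile, model, db, _rng=rng, _mask=mask)
        if optimize:
            day = optimize_portions(day, target)
        days.append(day)
    return WeeklyPlan(days=days, mask_history=dict(mask.history))


def optimize_portions(plan: DailyPlan, ei_target: float) -> DailyPlan:
    """Scale the day's portions by 1 + (EI - EI_plan)/EI_plan so the adjusted
    plan energy equals the target exactly (float rounding aside)."""
    ei_plan = plan.ei_adjusted  # energy at the plan's current portions
    if ei_plan <= 0:
        raise ValueError("cannot optimize a plan with non-positive energy")
    adjustment = PortionAdjustment(ei_target=float(ei_target),
                                   ei_plan=ei_plan)
    return DailyPlan(meals=list(plan.meals),
                     portion_factor=plan.portion_factor * adjustment.factor)
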