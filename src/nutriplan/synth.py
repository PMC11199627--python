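"""Synthetic stand-in for the expert-curated meal-plan database.

Three generators, each a pure function of (spec, seed):

* :func:`simulate_profiles` — a virtual cohort spread over the ten population
  groups in the published proportions (85, 158, 131, 103, 92, 635, 706, 766,
  231, 93 out of 3000), sexes balanced, ages/BMIs/PALs drawn from documented
  per-group ranges, BMR from the Mifflin-St Jeor equation.
* :func:`simulate_meal_db` — a meal database whose per-slot calorie and
  macronutrient marginals match the published per-slot means and standard
  deviations. Draws come from a zero-truncated normal whose parent
  parameters are moment-matched to the target mean/std; where the target
  coefficient of variation exceeds what a zero-truncated normal can reach
  (its CV is bounded by 1), a moment-matched gamma is used instead.
* :func:`assemble_truth_plans` — ground-truth daily plans for training
  labels, built by a randomized greedy search that matches each slot's
  energy to its share of the user's target intake; this plants a learnable
  profile-to-meal signal without claiming fidelity to how the real expert
  plans were constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .meals import Meal, MealDatabase, SLOTS
from .profiles import (GROUPS, UserProfile, EnergyRule, compute_bmi,
                       derive_macro_targets, ensure_target_ei, load_guidelines)
from .planner import DailyPlan

#: published cohort composition (count per group, total 3000)
GROUP_COUNTS = {
    "Healthy adults": 85,
    "Healthy adolescents": 158,
    "Healthy older adults": 131,
    "Athletes": 103,
    "Adults who are overweight": 92,
    "Adults who are obese": 635,
    "Adults with CVD": 706,
    "Adults with T2D": 766,
    "Adults with iron deficiency": 231,
    "Adults with low fruit & veg": 93,
}

#: per-group sampling ranges (documented guesses where unpublished):
#: (age range, BMI range, PAL range)
GROUP_RANGES = {
    "Healthy adults": ((20, 64), (18.5, 25.0), (1.2, 1.6)),
    "Healthy adolescents": ((15, 19), (17.0, 25.0), (1.2, 1.6)),
    "Healthy older adults": ((65, 88), (18.5, 30.0), (1.2, 1.5)),
    "Athletes": ((18, 45), (15.0, 25.0), (1.7, 2.2)),
    "Adults who are overweight": ((20, 64), (25.0, 30.0), (1.2, 1.6)),
    "Adults who are obese": ((20, 64), (30.0, 55.0), (1.2, 1.5)),
    "Adults with CVD": ((30, 88), (20.0, 55.0), (1.2, 1.5)),
    "Adults with T2D": ((30, 88), (20.0, 50.0), (1.2, 1.5)),
    "Adults with iron deficiency": ((20, 64), (18.5, 35.0), (1.2, 1.6)),
    "Adults with low fruit & veg": ((20, 64), (18.5, 35.0), (1.2, 1.6)),
}

#: published per-slot nutrition marginals: slot -> field -> (mean, std)
SLOT_NUTRITION = {
    "breakfast": {"calories": (423.75, 157.87), "protein": (20.07, 9.45),
                  "carbohydrate": (56.95, 23.50), "fat": (14.53, 9.49),
                  "sfa": (4.24, 3.31)},
    "morning snack": {"calories": (169.16, 136.85), "protein": (7.03, 8.11),
                      "carbohydrate": (27.22, 22.11), "fat": (4.45, 5.84),
                      "sfa": (1.28, 2.20)},
    "lunch": {"calories": (543.52, 166.30), "protein": (34.85, 16.63),
              "carbohydrate": (60.88, 23.51), "fat": (18.37, 9.46),
              "sfa": (4.64, 3.77)},
    "afternoon snack": {"calories": (211.94, 144.87), "protein": (8.36, 8.22),
                        "carbohydrate": (31.67, 22.73), "fat": (6.67, 7.07),
                        "sfa": (2.07, 2.83)},
    "dinner": {"calories": (600.19, 259.45), "protein": (37.53, 19.39),
               "carbohydrate": (75.58, 49.71), "fat": (21.65, 12.38),
               "sfa": (6.38, 4.89)},
    "supper": {"calories": (189.93, 103.24), "protein": (10.70, 7.65),
               "carbohydrate": (21.21, 15.30), "fat": (7.35, 6.60),
               "sfa": (2.09, 2.07)},
}

#: published number of unique meals per slot (total 1349)
SLOT_COUNTS = {"breakfast": 286, "morning snack": 258, "lunch": 255,
               "afternoon snack": 253, "dinner": 238, "supper": 59}

WEIGHT_RANGE = (46.0, 180.0)
HEIGHT_RANGE = (1.60, 2.0)


@dataclass(frozen=True)
class CohortSpec:
    n_users: int = 3000
    proportions: dict = field(
        default_factory=lambda: {g: c / 3000 for g, c in GROUP_COUNTS.items()})
    group_ranges: dict = field(default_factory=lambda: dict(GROUP_RANGES))
    seed: int = 0

    def __post_init__(self):
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        for group, (ages, bmis, pals) in self.group_ranges.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}")
            if ages[0] > ages[1] or bmis[0] > bmis[1] or pals[0] > pals[1]:
                raise ValueError(f"inverted range for group {group!r}")


@dataclass(frozen=True)
class MealDistSpec:
    slot_nutrition: dict = field(
        default_factory=lambda: {s: dict(v) for s, v in SLOT_NUTRITION.items()})
    slot_counts: dict = field(default_factory=lambda: dict(SLOT_COUNTS))
    seed: int = 0

    def __post_init__(self):
        for slot, fields in self.slot_nutrition.items():
            if slot not in SLOTS:
                raise ValueError(f"unknown slot {slot!r}")
            for name, (mean, std) in fields.items():
                if std < 0 or mean < 0:
                    raise ValueError(f"{slot}/{name}: invalid moments")
        for slot, count in self.slot_counts.items():
            if count < 1:
                raise ValueError(f"{slot}: at least one meal required")


def _apportion(n: int, proportions: dict) -> dict:
    """Largest-remainder apportionment of n users over groups (exact at the
    reference cohort size)."""
    groups = list(proportions)
    raw = np.array([proportions[g] * n for g in groups])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(groups, counts.tolist()))


def simulate_profiles(spec: CohortSpec) -> list[UserProfile]:
    """Seed-reproducible virtual cohort; see module docstring."""
    rng = np.random.default_rng(spec.seed)
    counts = _apportion(spec.n_users, spec.proportions)
    profiles: list[UserProfile] = []
    uid = 0
    for group in GROUPS:
        n = counts.get(group, 0)
        if n == 0:
            continue
        (age_lo, age_hi), (bmi_lo, bmi_hi), (pal_lo, pal_hi) = \
            spec.group_ranges[group]
        sexes = np.array(["male", "female"])[
            rng.permutation(np.arange(n) % 2)]
        for i in range(n):
            uid += 1
            sex = str(sexes[i])
            height = rng.uniform(*HEIGHT_RANGE)
            bmi_draw = rng.uniform(bmi_lo, bmi_hi)
            weight = float(np.clip(bmi_draw * height ** 2, *WEIGHT_RANGE))
            age = float(np.round(rng.uniform(age_lo, age_hi)))
            pal = float(np.round(rng.uniform(pal_lo, pal_hi), 3))
            # Mifflin-St Jeor resting energy expenditure
            bmr = (10.0 * weight + 6.25 * height * 100 - 5.0 * age
                   + (5.0 if sex == "male" else -161.0))
            profile = UserProfile(
                user_id=str(uid), weight=round(weight, 1), height=round(height, 2),
                age=age, bmr=round(bmr, 2), pal=pal, group=group, sex=sex,
                has_cvd=group == "Adults with CVD",
                has_t2d=group == "Adults with T2D",
                has_iron_def=group == "Adults with iron deficiency")
            ensure_target_ei(profile)
            profiles.append(profile)
    return profiles


# -- moment-matched nonnegative draws -----------------------------------------

def _truncnorm_parent(mean: float, std: float) -> tuple[float, float] | None:
    """Parent (mu, sigma) of a zero-truncated normal with the given moments,
    or None when the target CV is out of reach (bounded above by 1)."""
    cv = std / mean

    def cv_of(alpha: float) -> float:
        lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)
        var_ratio = 1.0 + alpha * lam - lam ** 2
        return np.sqrt(max(var_ratio, 0.0)) / (lam - alpha)

    lo, hi = -39.0, 30.0
    if not cv_of(lo) < cv < cv_of(hi):
        return None
    alpha = optimize.brentq(lambda a: cv_of(a) - cv, lo, hi, xtol=1e-10)
    lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)
    sigma = mean / (lam - alpha)
    return -alpha * sigma, sigma


def _draw_nonnegative(mean: float, std: float, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Nonnegative draws whose mean/std match the targets."""
    if std == 0:
        return np.full(size, mean)
    if mean == 0:
        return np.zeros(size)
    parent = _truncnorm_parent(mean, std) if std / mean < 0.95 else None
    if parent is not None:
        mu, sigma = parent
        dist = stats.truncnorm(-mu / sigma, np.inf, loc=mu, scale=sigma)
        return dist.rvs(size=size, random_state=rng)
    shape = (mean / std) ** 2
    return rng.gamma(shape, std ** 2 / mean, size=size)


def simulate_meal_db(spec: MealDistSpec) -> MealDatabase:
    """Seed-reproducible synthetic meal database; see module docstring."""
    rng = np.random.default_rng(spec.seed)
    meals: list[Meal] = []
    for slot in SLOTS:
        n = spec.slot_counts[slot]
        fields = spec.slot_nutrition[slot]
        draws = {name: _draw_nonnegative(mean, std, n, rng)
                 for name, (mean, std) in fields.items()}
        sfa = np.minimum(draws["sfa"], draws["fat"])
        # plumbing nutrients not governed by the published marginals
        iron = rng.gamma(2.0, 1.2, size=n)
        vit_c = rng.gamma(1.5, 12.0, size=n)
        fibre = rng.gamma(2.0, 2.0, size=n)
        fruits = rng.poisson(0.6, size=n).astype(float)
        veg = rng.poisson(0.9, size=n).astype(float)
        for i in range(n):
            meals.append(Meal(
                meal_id=len(meals),
                name=f"{slot.title()} {i + 1:03d}",
                slot=slot,
                calories=float(draws["calories"][i]),
                protein=float(draws["protein"][i]),
                carbohydrate=float(draws["carbohydrate"][i]),
                fat=float(draws["fat"][i]),
                sfa=float(sfa[i]),
                iron=float(iron[i]), vitamin_c=float(vit_c[i]),
                fibre=float(fibre[i]), n_fruits=float(fruits[i]),
                n_vegetables=float(veg[i])))
    return MealDatabase(meals)


# -- ground-truth training plans ----------------------------------------------

@dataclass(frozen=True)
class TruthPlan:
    profile_id: str
    day: int
    plan: DailyPlan
    rel_energy_error: float
    accepted: bool


def assemble_truth_plans(profiles, db: MealDatabase, days_per_user: int = 28,
                         seed: int = 0, energy_tol: float = 0.10,
                         max_tries: int = 8, candidates_per_slot: int = 12,
                         macro_weight: float = 4.0,
                         guidelines: dict | None = None) -> list[TruthPlan]:
    """Label plans via randomized greedy slot-energy + guideline matching.

    Each slot aims at its share of the user's target energy (shares taken
    from the published slot calorie means); per slot a random candidate
    subset is scanned and the meal minimizing |calories - slot share of EI|
    plus ``macro_weight`` times the gram violation of the slot-scaled
    guideline macro ranges is picked, minus group-tailoring bonuses that
    mirror how expert plans differ across groups (iron-deficient users
    prefer iron-rich meals; the low-fruit-and-vegetables group prefers
    produce-rich meals). Because of the bonuses and the per-group guideline
    overrides, the resulting labels depend on the population group, not
    just on target energy. The best plan over ``max_tries``
    attempts is kept and flagged accepted when its relative energy error is
    within ``energy_tol``.
    """
    rng = np.random.default_rng(seed)
    guidelines = guidelines if guidelines is not None else load_guidelines()
    slot_means = np.array([SLOT_NUTRITION[s]["calories"][0] for s in SLOTS])
    shares = slot_means / slot_means.sum()
    cal = np.array([m.calories for m in db.meals])
    macros = np.array([m.macro_vector for m in db.meals])  # (M, 4)
    iron = np.array([m.iron for m in db.meals])
    produce = np.array([m.n_fruits + m.n_vegetables for m in db.meals])
    slot_ids = {s: np.array(db.by_slot[s]) for s in SLOTS}
    plans: list[TruthPlan] = []
    for profile in profiles:
        target = ensure_target_ei(profile)
        lo, hi = derive_macro_targets(profile, guidelines).as_arrays()
        # group tailoring: reward the nutrients the group's plans emphasize
        bonus = np.zeros(len(db.meals))
        if profile.has_iron_def:
            bonus += 20.0 * iron
        if profile.group == "Adults with low fruit & veg":
            bonus += 40.0 * produce
        for day in range(days_per_user):
            best_ids, best_err = None, np.inf
            for _ in range(max_tries):
                ids = []
                total = 0.0
                for t, slot in enumerate(SLOTS):
                    pool = slot_ids[slot]
                    k = min(candidates_per_slot, len(pool))
                    cand = rng.choice(pool, size=k, replace=False)
                    violation = (
                        np.maximum(0.0, macros[cand] - shares[t] * hi)
                        + np.maximum(0.0, shares[t] * lo - macros[cand])
                    ).sum(axis=1)
                    score = (np.abs(cal[cand] - shares[t] * target)
                             + macro_weight * violation - bonus[cand])
                    pick = cand[np.argmin(score)]
                    ids.append(int(pick))
                    total += cal[pick]
                err = abs(total - target) / target
                if err < best_err:
                    best_err, best_ids = err, ids
                if err <= energy_tol:
                    break
            plans.append(TruthPlan(
                profile_id=profile.user_id, day=day,
                plan=DailyPlan(meals=[db[i] for i in best_ids]),
                rel_energy_error=best_err,
                accepted=best_err <= energy_tol))
    return plans


def truth_plans_frame(plans) -> pd.DataFrame:
    """Plans as a flat table: profile_id, day, 6 meal-id columns."""
    rows = [{"profile_id": tp.profile_id, "day": tp.day,
             **{f"meal_{t}": tp.plan.meal_ids[t] for t in range(6)}}
            for tp in plans]
    return pd.DataFrame(rows)
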