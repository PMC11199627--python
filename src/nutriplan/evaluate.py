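"""Evaluation metrics for generated meal plans and the latent space.

* Caloric difference: 100 * |target - plan| / target, percent; after portion
  optimization this is identically zero.
* Macronutrient accuracy: 100 when the day's grams fall inside the guideline
  range; outside it decays linearly with the relative distance to the
  nearest bound, floored at 0. The guideline ranges are not a published
  formula, so a second, cruder metric — the fraction of days within range —
  is reported alongside to keep the numbers auditable.
* Weekly variability: 1-7 scores counting distinct daily plans (plan level)
  and distinct meals per slot across the week (slot level).
* Latent export: the posterior means per user plus a silhouette score of the
  population-group labels, with a permuted-label baseline helper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .meals import SLOTS
from .model import DietVAE
from .planner import WeeklyPlan
from .profiles import (NUTRIENTS, MacroTargets, encode_cohort)


def caloric_difference(plan_energy: float, target: float) -> float:
    """Absolute caloric deviation from the target, in percent."""
    if target <= 0:
        raise ValueError("target energy must be positive")
    return 100.0 * abs(target - plan_energy) / target


def macro_accuracy(n: np.ndarray, targets: MacroTargets) -> np.ndarray:
    """Per-nutrient accuracy in [0, 100] for a day's gram vector."""
    lo, hi = targets.as_arrays()
    n = np.asarray(n, dtype=float)
    acc = np.full(4, 100.0)
    below = n < lo
    above = n > hi
    with np.errstate(divide="ignore", invalid="ignore"):
        acc_below = 100.0 * np.maximum(0.0, 1.0 - (lo - n) / lo)
        acc_above = 100.0 * np.maximum(0.0, 1.0 - (n - hi) / hi)
    # zero bound with an outside value -> accuracy 0
    acc_below = np.where(np.isfinite(acc_below), acc_below, 0.0)
    acc_above = np.where(np.isfinite(acc_above), acc_above, 0.0)
    acc[below] = acc_below[below]
    acc[above] = acc_above[above]
    return acc


def in_range_fraction(n: np.ndarray, targets: MacroTargets) -> np.ndarray:
    """Binary per-nutrient indicator (1 inside the range else 0)."""
    lo, hi = targets.as_arrays()
    n = np.asarray(n, dtype=float)
    return ((n >= lo) & (n <= hi)).astype(float)


def weekly_variability(week: WeeklyPlan) -> dict:
    """Distinct-count variability scores on the 1-7 scale."""
    day_keys = [tuple(day.meal_ids) for day in week.days]
    per_slot = {
        slot: len({day.meal_ids[t] for day in week.days})
        for t, slot in enumerate(SLOTS)}
    return {"plan_level": len(set(day_keys)), "per_slot": per_slot,
            "slot_average": float(np.mean(list(per_slot.values())))}


@dataclass
class EvalReport:
    """Per-group and overall plan quality metrics."""
    table: pd.DataFrame   # one row per group plus "Overall"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def evaluate_weekly_plans(entries) -> EvalReport:
    """Aggregate metrics over (group, weekly_plan, ei_target, macro_targets)
    tuples: caloric difference mean±std, per-nutrient and average
    macronutrient accuracy, in-range fraction, weekly variability."""
    rows = []
    for group, week, ei_target, targets in entries:
        cal_diffs = [caloric_difference(day.ei_adjusted, ei_target)
                     for day in week.days]
        accs = np.array([macro_accuracy(day.nutrients_adjusted, targets)
                         for day in week.days])
        in_rng = np.array([in_range_fraction(day.nutrients_adjusted, targets)
                           for day in week.days])
        var = weekly_variability(week)
        rows.append({"group": group,
                     "cal_diff_mean": np.mean(cal_diffs),
                     "cal_diff_std": np.std(cal_diffs),
                     **{f"acc_{n}": accs[:, i].mean()
                        for i, n in enumerate(NUTRIENTS)},
                     "acc_average": accs.mean(),
                     "in_range_fraction": in_rng.mean(),
                     "variability_plan": var["plan_level"],
                     "variability_slot_avg": var["slot_average"]})
    frame = pd.DataFrame(rows)
    metric_cols = [c for c in frame.columns if c != "group"]
    grouped = frame.groupby("group", sort=False)[metric_cols].mean()
    grouped.loc["Overall"] = frame[metric_cols].mean()
    return EvalReport(table=grouped.reset_index())


def export_latent(profiles, model: DietVAE) -> pd.DataFrame:
    """Posterior means per user: columns user_id, group, mu_0..mu_{d-1}."""
    bounds = model.bounds
    if bounds is None:
        raise ValueError("model carries no normalization bounds")
    x = encode_cohort(profiles, bounds)
    latent = model.encode(x, eps=np.zeros((len(profiles),
                                           model.config.latent_dim)))
    mu = latent.mu.data
    frame = pd.DataFrame(mu, columns=[f"mu_{j}" for j in range(mu.shape[1])])
    frame.insert(0, "group", [p.group for p in profiles])
    frame.insert(0, "user_id", [p.user_id for p in profiles])
    return frame


def latent_silhouette(latent_frame: pd.DataFrame,
                      permute_seed: int | None = None) -> float:
    """Mean silhouette of the group labels on the latent means; with
    ``permute_seed`` set, labels are shuffled first (chance baseline)."""
    mu = latent_frame.filter(like="mu_").to_numpy()
    labels = latent_frame["group"].to_numpy()
    if permute_seed is not None:
        labels = np.random.default_rng(permute_seed).permutation(labels)
    return float(silhouette_score(mu, labels))
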