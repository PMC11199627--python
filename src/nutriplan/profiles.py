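"""User profiles, energy targets and guideline-derived macronutrient ranges.

A user is described by anthropometrics (weight, height, age, BMI), energy
physiology (BMR, PAL), disease flags (cardiovascular disease, type-2 diabetes,
iron deficiency) and a population-group label. The daily energy-intake target
follows the factorial approach — BMR x PAL — shifted by a fixed adjustment D
(default 500 kcal) for underweight (BMI <= 18.5, +D) and overweight/obese
(BMI >= 25, -D) users so the plan supports weight gain or loss.

Macronutrient targets are gram ranges per day obtained by converting
%-of-energy guideline ranges with Atwater factors (4 kcal/g for protein and
carbohydrate, 9 kcal/g for fat and saturated fat). The guideline table ships
as a versioned YAML (``data/guidelines.yaml``) with per-group overrides and
may be replaced wholesale by the user.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

NUTRIENTS = ("protein", "carbohydrate", "fat", "sfa")

GROUPS = (
    "Healthy adults",
    "Healthy adolescents",
    "Healthy older adults",
    "Athletes",
    "Adults who are overweight",
    "Adults who are obese",
    "Adults with CVD",
    "Adults with T2D",
    "Adults with iron deficiency",
    "Adults with low fruit & veg",
)

#: fields of the encoder input vector, in order (continuous then binary flags)
PROFILE_VECTOR_FIELDS = (
    "weight", "height", "bmr", "age", "bmi", "target_ei", "pal",
    "has_cvd", "has_t2d", "has_iron_def",
)

_PROFILE_CSV_COLUMNS = [
    "User ID", "Weight", "Height", "PAL", "BMI", "BMR", "Age",
    "Iron Deficiency", "T2D", "Heart disease", "Subgroup",
]


def load_guidelines(path=None) -> dict:
    """Load the guideline/normalization config (packaged default if no path)."""
    if path is None:
        ref = importlib.resources.files("nutriplan").joinpath("data/guidelines.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    config = yaml.safe_load(text)
    for key in ("atwater", "default_ranges", "normalization_bounds"):
        if key not in config:
            raise ValueError(f"guideline config missing section '{key}'")
    return config


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m^2."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return weight / height ** 2


@dataclass(frozen=True)
class EnergyRule:
    """BMI-dependent energy-target rule: BMR*PAL shifted by +/-D at the ends.

    ``d_adjust`` is the weight-management adjustment D in kcal/day.
    """

    d_adjust: float = 500.0
    bmi_low: float = 18.5
    bmi_high: float = 25.0

    def __post_init__(self):
        if self.d_adjust < 0:
            raise ValueError("d_adjust must be >= 0")
        if not self.bmi_low < self.bmi_high:
            raise ValueError("bmi_low must be < bmi_high")


@dataclass
class UserProfile:
    user_id: str
    weight: float          # kg
    height: float          # m
    age: float             # years
    bmr: float             # kcal/day
    pal: float
    group: str
    has_cvd: bool = False
    has_t2d: bool = False
    has_iron_def: bool = False
    sex: str | None = None          # {"male","female"}; optional, used by the simulator
    bmi: float = field(default=None)        # derived if not given
    target_ei: float = field(default=None)  # derived if not given

    def __post_init__(self):
        if self.weight <= 0 or self.height <= 0:
            raise ValueError(f"user {self.user_id}: non-positive weight/height")
        if self.pal < 1.0:
            raise ValueError(f"user {self.user_id}: PAL must be >= 1.0")
        if self.group not in GROUPS:
            raise ValueError(f"user {self.user_id}: unknown group {self.group!r}")
        derived = compute_bmi(self.weight, self.height)
        if self.bmi is None:
            self.bmi = derived
        elif abs(self.bmi - derived) > 0.005:
            raise ValueError(
                f"user {self.user_id}: BMI {self.bmi} inconsistent with "
                f"weight/height (expected {derived:.2f})")
        if self.group == "Adults with CVD" and not self.has_cvd:
            raise ValueError(f"user {self.user_id}: CVD group requires has_cvd")
        if self.group == "Adults with T2D" and not self.has_t2d:
            raise ValueError(f"user {self.user_id}: T2D group requires has_t2d")
        if self.group == "Adults with iron deficiency" and not self.has_iron_def:
            raise ValueError(
                f"user {self.user_id}: iron-deficiency group requires has_iron_def")


def compute_energy_target(profile: UserProfile,
                          rule: EnergyRule = EnergyRule()) -> float:
    """Daily energy-intake target in kcal (factorial approach with D shift)."""
    base = profile.bmr * profile.pal
    if profile.bmi <= rule.bmi_low:
        return base + rule.d_adjust
    if profile.bmi >= rule.bmi_high:
        return base - rule.d_adjust
    return base


def ensure_target_ei(profile: UserProfile,
                     rule: EnergyRule = EnergyRule()) -> float:
    if profile.target_ei is None:
        profile.target_ei = compute_energy_target(profile, rule)
    return profile.target_ei


@dataclass(frozen=True)
class MacroTargets:
    """Per-nutrient [min, max] gram ranges per day (protein, carbohydrate,
    fat, saturated fat)."""

    min_val: dict
    max_val: dict

    def __post_init__(self):
        for nutrient in NUTRIENTS:
            lo, hi = self.min_val[nutrient], self.max_val[nutrient]
            if not 0 <= lo <= hi:
                raise ValueError(f"invalid range for {nutrient}: [{lo}, {hi}]")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.min_val[n] for n in NUTRIENTS])
        hi = np.array([self.max_val[n] for n in NUTRIENTS])
        return lo, hi

    def scaled(self, factor: float) -> "MacroTargets":
        return MacroTargets(
            {n: v * factor for n, v in self.min_val.items()},
            {n: v * factor for n, v in self.max_val.items()})


def derive_macro_targets(profile: UserProfile, config: dict) -> MacroTargets:
    """Convert %-energy guideline ranges into gram ranges for this user."""
    ei = ensure_target_ei(profile)
    atwater = config["atwater"]
    ranges = dict(config["default_ranges"])
    overrides = config.get("group_overrides", {}).get(profile.group, {})
    ranges.update(overrides)
    lo, hi = {}, {}
    for nutrient in NUTRIENTS:
        try:
            pct_lo, pct_hi = ranges[nutrient]
            kcal_per_g = atwater[nutrient]
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed guideline entry for {nutrient}") from exc
        lo[nutrient] = pct_lo / 100.0 * ei / kcal_per_g
        hi[nutrient] = pct_hi / 100.0 * ei / kcal_per_g
    return MacroTargets(lo, hi)


def encode_profile(profile: UserProfile, bounds: dict) -> np.ndarray:
    """Length-10 network input: min-max normalized continuous fields
    (clipped to [0,1]) followed by the three 0/1 disease flags."""
    ensure_target_ei(profile)
    values = []
    for name in PROFILE_VECTOR_FIELDS:
        raw = getattr(profile, name)
        if name.startswith("has_"):
            values.append(1.0 if raw else 0.0)
            continue
        if name not in bounds:
            raise ValueError(f"normalization bounds missing field '{name}'")
        lo, hi = bounds[name]
        values.append(np.clip((raw - lo) / (hi - lo), 0.0, 1.0))
    return np.asarray(values, dtype=np.float64)


def encode_cohort(profiles, bounds: dict) -> np.ndarray:
    return np.stack([encode_profile(p, bounds) for p in profiles])


# -- CSV I/O (11-column schema: User ID, Weight, Height, PAL, BMI, BMR, Age,
#    Iron Deficiency, T2D, Heart disease, Subgroup) ---------------------------

def _flag(value) -> bool:
    return str(value).strip().lower() in {"yes", "true", "1"}


def read_profiles_csv(path) -> list[UserProfile]:
    frame = pd.read_csv(path, comment="#")
    frame.columns = [c.strip() for c in frame.columns]
    missing = [c for c in _PROFILE_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"profiles CSV missing columns: {missing}")
    profiles = []
    for idx, row in frame.iterrows():
        # Printed BMI columns are rounded (occasionally truncated) to 2
        # decimals; validate at printed precision, store the derived value.
        derived = compute_bmi(float(row["Weight"]), float(row["Height"]))
        if abs(float(row["BMI"]) - derived) > 0.01:
            raise ValueError(
                f"row {idx + 2}: BMI {row['BMI']} inconsistent with "
                f"weight/height (expected {derived:.2f})")
        profiles.append(UserProfile(
            user_id=str(row["User ID"]),
            weight=float(row["Weight"]),
            height=float(row["Height"]),
            pal=float(row["PAL"]),
            bmr=float(row["BMR"]),
            age=float(row["Age"]),
            has_iron_def=_flag(row["Iron Deficiency"]),
            has_t2d=_flag(row["T2D"]),
            has_cvd=_flag(row["Heart disease"]),
            group=str(row["Subgroup"]).strip(),
            sex=str(row["Sex"]).strip() if "Sex" in frame.columns else None,
        ))
    return profiles


def write_profiles_csv(profiles, path) -> None:
    rows = []
    for p in profiles:
        rows.append({
            "User ID": p.user_id,
            "Weight": p.weight,
            "Height": p.height,
            "PAL": p.pal,
            "BMI": round(p.bmi, 2),
            "BMR": round(p.bmr, 2),
            "Age": p.age,
            "Iron Deficiency": "Yes" if p.has_iron_def else "No",
            "T2D": "Yes" if p.has_t2d else "No",
            "Heart disease": "Yes" if p.has_cvd else "No",
            "Subgroup": p.group,
        })
    pd.DataFrame(rows, columns=_PROFILE_CSV_COLUMNS).to_csv(path, index=False)
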