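"""Typed meal records, CSV I/O and the equivalent-meal expansion interface.

A meal database holds one record per unique dish, keyed by a dense integer id
(the decoder's class vocabulary) and tagged with one of six daily slots:
breakfast, morning snack, lunch, afternoon snack, dinner, supper. Records
carry energy (kcal), the four targeted macronutrients (g), iron (mg),
vitamin C (mg), fibre (g) and fruit/vegetable counts, all for a reference
portion (``base_portion`` = 1.0 relative unit); portion scaling is strictly
multiplicative.

Database expansion with LLM-proposed "equivalent meals" (same nutrition,
different cuisine) is exposed as a provider-agnostic prompt builder plus a
tolerant CSV response parser; the repository ships only an offline mock
provider so nothing here requires network access.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SLOTS = ("breakfast", "morning snack", "lunch", "afternoon snack",
         "dinner", "supper")

CSV_HEADERS = ["Meal name", "Meal type", "Calories", "Protein",
               "Carbohydrates", "Fat", "Saturated Fat", "Iron", "Vitamin C",
               "Fibre", "Number of fruits", "Number of vegetables"]

_NUMERIC = {"Calories": "calories", "Protein": "protein",
            "Carbohydrates": "carbohydrate", "Fat": "fat",
            "Saturated Fat": "sfa", "Iron": "iron", "Vitamin C": "vitamin_c",
            "Fibre": "fibre", "Number of fruits": "n_fruits",
            "Number of vegetables": "n_vegetables"}


@dataclass(frozen=True)
class Meal:
    meal_id: int
    name: str
    slot: str
    calories: float
    protein: float
    carbohydrate: float
    fat: float
    sfa: float
    iron: float = 0.0
    vitamin_c: float = 0.0
    fibre: float = 0.0
    n_fruits: float = 0.0
    n_vegetables: float = 0.0
    base_portion: float = 1.0
    equivalent_of: int | None = None
    cuisine: str | None = None

    def __post_init__(self):
        if self.slot not in SLOTS:
            raise ValueError(f"meal {self.name!r}: unknown slot {self.slot!r}")
        for fname in ("calories", "protein", "carbohydrate", "fat", "sfa",
                      "iron", "vitamin_c", "fibre", "n_fruits", "n_vegetables"):
            if getattr(self, fname) < 0:
                raise ValueError(f"meal {self.name!r}: negative {fname}")
        if self.sfa > self.fat + 1e-9:
            raise ValueError(f"meal {self.name!r}: SFA exceeds total fat")

    @property
    def macro_vector(self) -> np.ndarray:
        """(protein, carbohydrate, fat, sfa) grams at base portion."""
        return np.array([self.protein, self.carbohydrate, self.fat, self.sfa])


class MealDatabase:
    """Dense-id meal vocabulary with a per-slot index."""

    def __init__(self, meals: list[Meal]):
        if not meals:
            raise ValueError("empty meal database")
        remapped = [replace(m, meal_id=i) if m.meal_id != i else m
                    for i, m in enumerate(meals)]
        self.meals: list[Meal] = remapped
        self.by_slot: dict[str, list[int]] = {s: [] for s in SLOTS}
        for m in self.meals:
            self.by_slot[m.slot].append(m.meal_id)
        missing = [s for s in SLOTS if not self.by_slot[s]]
        if missing:
            raise ValueError(f"no meals for slots: {missing}")

    def __len__(self) -> int:
        return len(self.meals)

    def __getitem__(self, meal_id: int) -> Meal:
        return self.meals[meal_id]

    @property
    def vocab_size(self) -> int:
        return len(self.meals)

    def slot_counts(self) -> dict[str, int]:
        return {s: len(ids) for s, ids in self.by_slot.items()}

    def slot_masks(self) -> np.ndarray:
        """(6, M) boolean: slot-admissible vocabulary subsets."""
        masks = np.zeros((len(SLOTS), len(self.meals)), dtype=bool)
        for row, slot in enumerate(SLOTS):
            masks[row, self.by_slot[slot]] = True
        return masks

    def vocabulary_hash(self) -> str:
        import hashlib
        digest = hashlib.sha256()
        for m in self.meals:
            digest.update(f"{m.meal_id}|{m.name}|{m.slot}|{m.calories:.6f}"
                          .encode())
        return digest.hexdigest()[:16]


def _normalize_header(name: str) -> str:
    return re.sub(r"\s+", " ", name).strip().lower()


def _frame_to_meals(frame: pd.DataFrame, source: str,
                    id_offset: int = 0) -> list[Meal]:
    canon = {_normalize_header(h): h for h in CSV_HEADERS}
    rename = {}
    for col in frame.columns:
        key = _normalize_header(str(col))
        if key in canon:
            rename[col] = canon[key]
    frame = frame.rename(columns=rename)
    missing = [h for h in CSV_HEADERS if h not in frame.columns]
    if missing:
        raise ValueError(f"{source}: missing headers {missing}")
    meals: list[Meal] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            kwargs = {dst: float(row[src]) for src, dst in _NUMERIC.items()}
            slot = str(row["Meal type"]).strip().lower()
            meal = Meal(meal_id=id_offset + len(meals),
                        name=str(row["Meal name"]).strip(), slot=slot,
                        equivalent_of=(int(row["equivalent_of"])
                                       if "equivalent_of" in frame.columns
                                       and pd.notna(row.get("equivalent_of"))
                                       else None),
                        cuisine=(str(row["cuisine"]).strip()
                                 if "cuisine" in frame.columns
                                 and pd.notna(row.get("cuisine")) else None),
                        **kwargs)
        except (ValueError, TypeError) as exc:
            logger.warning("%s line %d: row rejected (%s)", source, line, exc)
            continue
        meals.append(meal)
    return meals


def read_meal_csv(path) -> MealDatabase:
    """Read a meal database in the 12-column schema; invalid rows are
    skipped with line-numbered warnings."""
    frame = pd.read_csv(path, comment="#", skipinitialspace=True)
    return MealDatabase(_frame_to_meals(frame, str(path)))


def write_meal_csv(db: MealDatabase, path) -> None:
    rows = []
    extra = any(m.equivalent_of is not None or m.cuisine is not None
                for m in db.meals)
    for m in db.meals:
        row = {"Meal name": m.name, "Meal type": m.slot,
               "Calories": m.calories, "Protein": m.protein,
               "Carbohydrates": m.carbohydrate, "Fat": m.fat,
               "Saturated Fat": m.sfa, "Iron": m.iron,
               "Vitamin C": m.vitamin_c, "Fibre": m.fibre,
               "Number of fruits": m.n_fruits,
               "Number of vegetables": m.n_vegetables}
        if extra:
            row["equivalent_of"] = m.equivalent_of
            row["cuisine"] = m.cuisine
        rows.append(row)
    cols = CSV_HEADERS + (["equivalent_of", "cuisine"] if extra else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# -- equivalent-meal expansion ------------------------------------------------

ROLE_PROMPT = (
    "You are FoodAI, an AI system proficient at recommending meals and "
    "knowledgeable about many world cuisines. Your task is to propose, for a "
    "given reference meal, equivalent dishes from other cuisines that share "
    "similar ingredients, nutrition facts and calories. Reply exactly "
    "\"FoodAI is ready\" to acknowledge this task before we proceed."
)


def build_equivalence_prompt(meal: Meal, cuisines: list[str],
                             n_equivalents: int = 1) -> str:
    """Two-stage prompt: FoodAI role-setting message, then the per-meal query
    demanding CSV output with the exact 12-column header."""
    if not cuisines:
        raise ValueError("at least one cuisine is required")
    header = ", ".join(CSV_HEADERS)
    query = (
        f"Reference meal ({meal.slot}): {meal.name}.\n"
        f"Nutrition facts per portion: {meal.calories:.1f} kcal, "
        f"{meal.protein:.1f} g protein, {meal.carbohydrate:.1f} g "
        f"carbohydrates, {meal.fat:.1f} g fat, {meal.sfa:.1f} g saturated "
        f"fat, {meal.iron:.1f} mg iron, {meal.vitamin_c:.1f} mg vitamin C, "
        f"{meal.fibre:.1f} g fibre, {meal.n_fruits:.0f} fruits, "
        f"{meal.n_vegetables:.0f} vegetables.\n"
        f"Propose {n_equivalents} equivalent meal(s) from each of the "
        f"following cuisine(s): {', '.join(cuisines)}. Match the ingredients, "
        f"nutrition facts and calories as closely as possible.\n"
        f"Respond ONLY with CSV using exactly these headers: {header}"
    )
    return ROLE_PROMPT + "\n\n" + query


_FENCE = re.compile(r"```[a-zA-Z]*\n(.*?)```", re.DOTALL)


def parse_equivalents(response_text: str, expected_slot: str,
                      equivalent_of: int | None = None,
                      cuisine: str | None = None) -> list[Meal]:
    """Tolerantly parse an LLM CSV response into validated meals.

    Code fences are stripped, the slot column is coerced to ``expected_slot``
    and rows violating meal invariants are dropped with warnings. An
    unparseable response yields an empty list, never an exception.
    """
    if expected_slot not in SLOTS:
        raise ValueError(f"unknown slot {expected_slot!r}")
    text = response_text.strip()
    fenced = _FENCE.search(text)
    if fenced:
        text = fenced.group(1).strip()
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.strip().startswith("#")]
    start = next((i for i, ln in enumerate(lines)
                  if _normalize_header(ln.split(",")[0]) == "meal name"), None)
    if start is None:
        logger.warning("equivalents response: no CSV header found")
        return []
    try:
        frame = pd.read_csv(io.StringIO("\n".join(lines[start:])),
                            skipinitialspace=True)
    except Exception as exc:  # malformed CSV body
        logger.warning("equivalents response unparseable: %s", exc)
        return []
    frame["Meal type"] = expected_slot
    meals = _frame_to_meals(frame, "equivalents response")
    if equivalent_of is not None or cuisine is not None:
        meals = [replace(m, equivalent_of=equivalent_of, cuisine=cuisine)
                 for m in meals]
    return meals


#: per-field noise scales of the offline mock, chosen to emulate the
#: differences observed between LLM-proposed equivalents and their references
DEFAULT_JITTER = {"calories": 25.0, "protein": 6.70, "carbohydrate": 12.64,
                  "fat": 5.19, "sfa": 2.74}
DEFAULT_BIAS = {"calories": 0.0, "protein": -1.76, "carbohydrate": -3.56,
                "fat": 2.29, "sfa": 0.97}


def mock_equivalents(meal: Meal, jitter: dict | None = None,
                     seed: int = 0, cuisine: str = "International",
                     bias: dict | None = None) -> Meal:
    """Offline stand-in for the LLM provider: a renamed meal whose nutrition
    is the original plus Gaussian noise (truncated at 0), seed-reproducible."""
    jitter = DEFAULT_JITTER if jitter is None else jitter
    bias = ({k: 0.0 for k in DEFAULT_BIAS} if jitter is not DEFAULT_JITTER
            else DEFAULT_BIAS) if bias is None else bias
    if any(v < 0 for v in jitter.values()):
        raise ValueError("jitter stds must be >= 0")
    rng = np.random.default_rng([seed, meal.meal_id])
    fields = {}
    for key in ("calories", "protein", "carbohydrate", "fat", "sfa"):
        std = jitter.get(key, 0.0)
        shift = bias.get(key, 0.0) + (rng.normal(0.0, std) if std > 0 else 0.0)
        fields[key] = max(0.0, getattr(meal, key) + shift)
    fields["sfa"] = min(fields["sfa"], fields["fat"])
    return replace(meal, name=f"{cuisine} equivalent of {meal.name}",
                   equivalent_of=meal.meal_id, cuisine=cuisine, **fields)


@dataclass(frozen=True)
class EquivalenceReport:
    """Mean and std of (equivalent - original) per nutrient and calories,
    over matched meal pairs."""

    mean: dict
    std: dict
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "std": self.std})


def equivalence_report(original: MealDatabase,
                       equivalent: MealDatabase) -> EquivalenceReport:
    """Differences equivalent-minus-original, matched by ``equivalent_of``
    back-reference (falling back to meal_id when absent)."""
    fields = ("calories", "protein", "carbohydrate", "fat", "sfa")
    diffs = {f: [] for f in fields}
    for eq in equivalent.meals:
        ref_id = eq.equivalent_of if eq.equivalent_of is not None else eq.meal_id
        if ref_id is None or not 0 <= ref_id < len(original):
            continue
        orig = original[ref_id]
        for f in fields:
            diffs[f].append(getattr(eq, f) - getattr(orig, f))
    n = len(diffs["calories"])
    if n == 0:
        raise ValueError("no matched meal pairs between the databases")
    mean = {f: float(np.mean(diffs[f])) for f in fields}
    std = {f: float(np.std(diffs[f], ddof=1)) if n > 1 else 0.0
           for f in fields}
    return EquivalenceReport(mean=mean, std=std, n_pairs=n)
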