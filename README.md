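# nutriplan

Guideline-aligned personalized meal-plan generation with a variational
autoencoder.

`nutriplan` is a research tool for personalized nutrition informatics. Given
a user profile — weight, height, age, basal metabolic rate (BMR), physical
activity level (PAL), BMI and flags for cardiovascular disease, type-2
diabetes and iron deficiency — it generates 7-day meal plans of six daily
slots (breakfast, morning snack, lunch, afternoon snack, dinner, supper)
drawn from a typed meal database, and guarantees that each day's energy
exactly matches the user's target intake. It is aimed at researchers
building or evaluating diet-recommendation systems who need a transparent,
fully reproducible reference pipeline that runs offline end-to-end.

## The model

**Energy target.** The daily energy-intake target follows the factorial
approach with a weight-management shift *D* (default 500 kcal):

```
EI = BMR·PAL + D   if BMI ≤ 18.5
EI = BMR·PAL       if 18.5 < BMI < 25
EI = BMR·PAL − D   if BMI ≥ 25
```

**Generator.** A variational autoencoder maps the normalized length-10
profile vector through a fully connected encoder to the mean μ and
log-variance log σ² of a diagonal Gaussian latent space (d = 256 by
default); a sample z = μ + σ⊙ε seeds a stacked GRU decoder (2 × 512)
unrolled over the six meal slots. Per slot, a classifier over the meal
vocabulary (masked to the slot's meal type) picks the dish, and auxiliary
heads predict plan energy and macronutrients for the training losses.

**Training losses.** The total loss is the unweighted sum of four terms:
meal cross-entropy against ground-truth plans (L_MC), the KL divergence of
the latent posterior from N(0, I) (L_KLD), mean-squared error on plan
energy (L_EI), and a macronutrient range penalty
(1/N)·Σᵢ(|minᵢ − n̂ᵢ| + |maxᵢ − n̂ᵢ|) that is minimal exactly on the
guideline box (L_macro). Guideline ranges (%-of-energy, converted to grams
with Atwater factors) ship as an editable YAML with per-group overrides.

**Portion optimizer.** After decoding, each day's portions are rescaled by
1 + d with d = (EI − ÊI)/ÊI, so the plan's energy matches the target
exactly — the mechanism behind the 0.00 ± 0.00 caloric-difference results.

**Weekly masking.** Across the 7 days, meals already chosen for a slot have
their probability multiplied by λ (default 0, hard removal), enforcing
within-week variety while the slot pool lasts.

Because the expert-curated meal-plan database the method was designed
around is not redistributable, the package includes a first-class synthetic
stand-in: a cohort generator reproducing the study's ten population groups
and anthropometric ranges, a meal-database generator matching the published
per-slot calorie/macronutrient means and standard deviations, and a
ground-truth plan assembler that plants a learnable profile→meal signal.

## Worked example

```python
from nutriplan import (UserProfile, compute_energy_target,
                       derive_macro_targets, load_guidelines,
                       optimize_portions)
from nutriplan.model import DietVAE, ModelConfig
from nutriplan.planner import generate_daily
from nutriplan.synth import MealDistSpec, simulate_meal_db
from nutriplan.meals import SLOTS

user = UserProfile(user_id="11", weight=130, height=1.64, age=41,
                   bmr=1980.25, pal=1.195, group="Adults who are obese")
ei = compute_energy_target(user)          # 1866.40 kcal/day (BMI 48.33 ≥ 25)
g = load_guidelines()
targets = derive_macro_targets(user, g)   # e.g. carbohydrate [210.0, 280.0] g

db = simulate_meal_db(MealDistSpec(slot_counts={s: 12 for s in SLOTS}, seed=0))
model = DietVAE(ModelConfig(vocab_size=db.vocab_size, encoder_hidden=32,
                            latent_dim=16, decoder_hidden=32, seed=0),
                bounds=g["normalization_bounds"])
plan = generate_daily(user, model, db, seed=0)
print(plan.ei_raw)            # 2448.70  kcal at reference portions
plan = optimize_portions(plan, ei)
print(plan.portion_factor)    # 0.7622   every portion scaled by this factor
print(plan.ei_adjusted)       # 1866.40  kcal — matches the target exactly
```

The user's BMI (48.33) puts them in the weight-loss branch, so the target is
BMR·PAL − 500 = 1866.40 kcal. The decoded plan carries 2448.70 kcal at
reference portions; the optimizer shrinks every portion by the single factor
0.7622 and the adjusted plan hits the target to float precision.

The same pipeline is available from the shell via the `nutriplan` console
script (`simulate`, `train`, `generate`, `evaluate`, `expand-db` — see
`nutriplan --help`). The `expand-db` command builds the "FoodAI"
equivalent-meal prompts for LLM-based database expansion and ships an
offline mock provider, so no network access is ever needed.

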