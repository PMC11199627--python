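# Methods

This note documents the models, numerical choices and known limitations of
`nutriplan`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and what the bundled synthetic data can and cannot
show.

## User profiles and targets

A profile carries weight (kg), height (m), age (yr), BMR (kcal/day), PAL
(dimensionless), three disease flags and one of ten population-group
labels. BMI is derived (weight/height²) and validated against any supplied
value to 0.005; CSV columns printed at two decimals are validated at 0.01,
since printed tables mix rounding and truncation.

The energy target uses the factorial approach EI = BMR·PAL with a shift of
±D (default D = 500 kcal/day) for BMI ≤ 18.5 (gain) and BMI ≥ 25 (loss).
The boundaries are closed exactly as written: a BMI of exactly 18.5 receives
+D, exactly 25 receives −D. The three branches partition the BMI axis, so
the target is a step function with jumps of exactly ∓D at the thresholds.

Macronutrient targets are daily gram ranges obtained from %-of-energy
guideline ranges via Atwater factors (protein and carbohydrate 4 kcal/g,
fat and saturated fat 9 kcal/g). The shipped defaults (protein 10–20 %E,
carbohydrate 45–60 %E, fat 20–35 %E, SFA 0–10 %E, with a stricter SFA/fat
cap for the cardiovascular group, a narrower carbohydrate range for type-2
diabetes and a higher protein range for athletes) condense widely used
EFSA/WHO recommendations; they are policy, not code, and live in a
versioned YAML (`data/guidelines.yaml`) that users can replace wholesale.
Gram ranges are homogeneous of degree 1 in EI by construction.

The encoder input is a fixed-order length-10 vector: seven continuous
fields (weight, height, BMR, age, BMI, EI target, PAL) min–max normalized
by fixed population bounds and clipped to [0, 1], then the three 0/1 flags.
The bounds (weight 46–180 kg, height 1.60–2.0 m, BMR 800–3500, age 15–88,
BMI 15–60, EI 1000–5000, PAL 1.0–2.5) cover the study population with the
age floor lowered to include adolescents; they are stored in the same YAML
so a trained checkpoint can carry them.

## Generative model

Encoder: one fully connected ReLU layer (10 → 256 by default), then two
linear maps to μ and log σ² (d = 256). Sampling uses the
reparameterization z = μ + σ⊙ε with ε ~ N(0, I), so gradients flow through
the sample.

Decoder: a stacked GRU (2 layers × 512 units by default) unrolled for the
six meal slots. The printed recurrence feeds the latent vector at the first
step and the previous hidden state afterwards; we read this literally — the
step-1 input is a linear projection of z to the GRU input width, and for
t > 1 the top layer's previous hidden state is fed back as the next input.
Hidden states initialize to zero. Three heads share the hidden state: a
single meal classifier over the whole vocabulary whose logits are masked to
the slot's admissible meal type before the softmax (masked classes receive
probability exactly 0; implemented with a −10³⁰ sentinel so the softmax
underflows cleanly rather than producing NaNs), and linear energy/nutrient
heads whose per-slot outputs are summed into plan totals. The alternative
designs — per-slot classifiers, or sizing the GRU input equal to the latent
dimension — are not recoverable from the published description; the
single-classifier-with-masks reading matches the stated "one classifier"
architecture, and the projection is the minimal reconciliation of
dimensions.

The auxiliary heads exist for training only. At inference, plan energy and
nutrients are computed from the selected meals' database values; this is
what lets the portion optimizer zero the caloric difference exactly.

Nonlinearity (ReLU) and initialization (uniform fan-in, seeded) are fixed
in the config for reproducibility. The whole model runs on a small bundled
reverse-mode autodiff engine over float64 NumPy arrays; its analytic
gradients are validated against central finite differences at 10⁻⁴
relative tolerance in the test suite.

## Losses

With energies expressed in normalized units (kcal/1000, configurable):

* L_macro = (1/N)·Σᵢ(|minᵢ − n̂ᵢ| + |maxᵢ − n̂ᵢ|), N = 4 nutrients. Inside
  the target box this is constant (the mean range width) — the loss's
  minimum region is the guideline range itself, not a point; outside it
  grows linearly. During training it is applied to the nutrient head's
  output with the gram targets normalized by the same energy constant.
* L_EI: mean squared error between predicted and target plan energy, the
  mean taken over the batch.
* L_KLD = −½·Σⱼ(1 + log σⱼ² − μⱼ² − σⱼ²), the closed-form KL divergence of
  the diagonal Gaussian posterior from N(0, I), batch-averaged.
* L_MC = −Σₜ log p(true meal at slot t), batch-averaged; a probability
  below 10⁻¹² is clamped (with a warning) to keep the loss finite.

The total is the unweighted sum, as printed; per-term weights are exposed
but default to 1. The kcal/1000 normalization is a deliberate numerical
choice: raw squared kilocalories (~10⁶) would dominate an unweighted sum.
Whether the original work normalized energies or weighted terms is not
stated; we chose normalization because it preserves the printed equation.

## Planner and optimizer

Daily generation encodes the profile, samples z, decodes under the
slot-type masks and takes the argmax meal per slot. Weekly generation draws
seven independent latent samples. The anti-repetition mask multiplies the
probability of a slot's previously selected meals by λ; the default λ = 0
removes them outright, which guarantees seven distinct meals per slot
whenever the slot pool holds at least seven. When a pool is exhausted
mid-week the mask forgets its least-recently-used entries until a choice
exists; λ = 1 disables masking entirely. λ is exposed because the published
weekly-variability averages (≈5 of 7) imply the original masking was not
absolute; both the plan-level and per-slot distinct-count variability
metrics are implemented.

The optimizer computes d = (EI − ÊI)/ÊI from database values of the
selected meals and scales every portion by the single factor 1 + d. The
adjusted energy equals EI·(ÊI/ÊI) identically, so the percent caloric
difference after optimization is 0 to float rounding for any
positive-energy plan, and all nutrients scale by the same factor
(linearity contract: nutrient fields describe the reference portion and
scaling is strictly multiplicative). A per-meal clamp on the factor exists
but is off by default, because clamping would break the exact-zero
property. Plans with non-positive energy are rejected.

## Synthetic data

The generators are pure functions of (spec, seed) and define the package's
study conditions.

* **Cohort.** Group counts follow the published proportions
  (85/158/131/103/92/635/706/766/231/93 over 3000) through
  largest-remainder apportionment — exact at n = 3000. Sexes alternate
  within groups (balanced to ±1 per group). Heights are uniform on
  1.60–2.0 m; a BMI is drawn uniformly in the group's range and weight
  derived as BMI·h², clipped to 46–180 kg; ages and PALs are uniform in
  group-appropriate ranges (adolescents 15–19, older adults 65–88,
  athletes PAL ≥ 1.7, obese BMI ≥ 30, overweight 25–30). The published
  cohort description gives only global ranges, so the per-group ranges are
  documented guesses; the stated adult age floor (20) conflicts with the
  printed example cohort containing 15/16-year-olds, and the generator
  follows group-appropriate ages. BMR uses Mifflin–St Jeor (10W + 6.25H −
  5A + 5 for men, −161 for women) because the original BMR formula is not
  stated; printed profiles carry BMR as data, so this choice affects only
  synthetic cohorts.
* **Meal database.** Slot sizes default to the published counts
  (286/258/255/253/238/59, total 1349). For each slot, calories and the
  four macronutrients are drawn independently from a zero-truncated normal
  whose *parent* parameters are moment-matched (via a bracketed root solve
  on the coefficient of variation) so the truncated distribution has
  exactly the published mean and standard deviation. A zero-truncated
  normal cannot exceed CV = 1, and several published marginals do (e.g.
  morning-snack SFA 1.28 ± 2.20 g); those fields fall back to a
  moment-matched gamma. SFA is clipped to total fat after sampling. The
  published table gives marginals only, so no covariance structure is
  imposed; re-deriving calories from 4P + 4C + 9F is deliberately not done
  by default, to keep the calorie marginal exact. Iron, vitamin C, fibre
  and fruit/vegetable counts carry plausible ad-hoc distributions — they
  are plumbing, not emulation targets.
* **Truth plans.** Each profile-day picks one meal per slot by randomized
  greedy search: a random candidate subset per slot is scored by
  |calories − slot share of EI| (shares from the published slot calorie
  means) plus 4 kcal/g times the violation of the slot-scaled guideline
  gram ranges, minus group-tailoring bonuses (iron-rich meals for the
  iron-deficiency group, produce-rich meals for the low-fruit-and-vegetable
  group) that emulate how expert plans differ across groups. Plans within
  10% relative energy error are accepted; otherwise the best of eight
  attempts is kept and flagged. This is a stated heuristic for producing
  guideline-respecting, group-dependent training labels — not a claim about
  how the real expert plans were constructed.

What the synthetic data does *not* emulate: recipes and ingredients, meal
co-occurrence structure, nutrient covariances, seasonal or cultural
patterns, and the qualitative richness that makes real expert plans
group-specific. Passing tests on this data demonstrate the pipeline's
mechanics (losses, masking, optimization, reproducibility) and the
existence of a learnable profile→plan signal; they do not certify accuracy
on real meal databases.

## Training

Adam (lr 10⁻⁴, batch 64) on the four-term loss; the full-scale defaults
(500 epochs, 3000 users, 28 plans per user) mirror the original study. The
80/20 split is by profile, not by plan row, so no user appears on both
sides; whether the original split was by plan or profile is not stated, and
the profile split is the leakage-safe choice. There is no early stopping; a
best-validation-cross-entropy snapshot is recorded additively alongside the
final parameters. A non-finite loss aborts with the offending term named.
Fixed seeds make runs bit-reproducible (init, split, batch order and ε
draws all derive from explicit seeds).

The scaled-down study used by the test suite and the acceptance script runs
200 profiles, 10 meals per slot, one labelled week per profile and 50
epochs with reduced widths (encoder 64, latent 32, GRU 64) — small enough
to train in seconds while preserving every mechanism. One behaviour worth
noting: at this scale, prolonged training (hundreds of epochs or many more
labelled days per profile) lets the KL term collapse the latent posterior
toward the prior faster than the cross-entropy can counteract, degrading
the group structure of the latent means even as training loss falls — the
familiar posterior-collapse failure mode of VAEs. The scaled study
therefore reflects a moderate training regime; the full-scale
configuration, with ~50× more data, is the setting the architecture was
designed for.

## Evaluation

Caloric difference is 100·|EI − ÊI|/EI (%); after the optimizer it is
identically zero. The macronutrient accuracy formula was not published and
cannot be reverse-engineered from the reported percentages, so two
auditable metrics are reported side by side: (a) the default — 100 inside
the guideline range, decaying linearly with relative distance to the
nearest bound outside it, floored at 0 (a value at a zero bound's outside
scores 0); and (b) the fraction of days within range. Accuracies are
averaged per day, then pooled across days and users. Weekly variability is
a distinct count on the 1–7 scale, at plan level (distinct daily plans) and
per slot (distinct meals per slot across the week); both are invariant to
day order. The latent export writes per-user posterior means with group
labels for downstream 2-D embedding (t-SNE or similar via standard
tooling, outside the core contract) and reports the mean silhouette of
group labels on μ, with a permuted-label baseline (mean over 10 shuffles)
as the chance reference.

## Equivalent-meal expansion

Database expansion is provider-agnostic: a deterministic two-stage prompt
(role-setting "FoodAI" message expecting the acknowledgement "FoodAI is
ready", then a per-meal query embedding the nutrition facts and demanding
CSV output with the exact 12-column header) and a tolerant response parser
(code fences stripped, slot coerced, invalid rows dropped with warnings,
zero parseable rows a warning rather than an error). The repository ships
only an offline mock provider, which returns the reference meal renamed
with Gaussian nutrient jitter; its default bias and spread are set to the
observed equivalent-minus-original difference statistics (protein
−1.76 ± 6.70 g, carbohydrate −3.56 ± 12.64 g, fat +2.29 ± 5.19 g, SFA
+0.97 ± 2.74 g, calories ± 25 kcal) so offline experiments see realistic
perturbations. Matched pairs are linked by an `equivalent_of`
back-reference, one equivalent per queried meal. How many equivalents per
meal and cuisine the original work requested, and with which decoding
parameters, is unknown; both are exposed as arguments.

## Known limitations

* The published accuracy percentages for the proprietary database cannot be
  reproduced here: they depend on that database, the original trained
  weights and an unpublished accuracy formula. The acceptance script
  reports this package's own numbers under its own documented metrics.
* The optimizer targets energy only; macronutrients scale along for the
  ride, which preserves ratios but not gram targets.
* Guideline defaults are a condensed, editable policy file — they are not
  a substitute for jurisdiction-specific dietary reference values, and
  pediatric/pregnancy guidelines are out of scope.
* Micronutrients (iron, vitamin C, fibre) are carried through the data
  model but not targeted by any loss.
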