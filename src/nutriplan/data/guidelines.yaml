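# Default macronutrient guideline ranges, expressed as % of daily energy
# intake, with per-group overrides. Derived from EFSA dietary reference
# values and WHO recommendations; fully user-overridable. version: 1
version: 1
atwater:            # kcal per gram
  protein: 4.0
  carbohydrate: 4.0
  fat: 9.0
  sfa: 9.0
default_ranges:     # [min %E, max %E]
  protein: [10, 20]
  carbohydrate: [45, 60]
  fat: [20, 35]
  sfa: [0, 10]
group_overrides:
  "Adults with CVD":
    sfa: [0, 7]
    fat: [20, 30]
  "Adults with T2D":
    carbohydrate: [40, 50]
  "Athletes":
    protein: [12, 25]
normalization_bounds:   # fixed population bounds for min-max input scaling
  weight: [46, 180]     # kg
  height: [1.60, 2.0]   # m
  bmr: [800, 3500]      # kcal/day
  age: [15, 88]         # years
  bmi: [15, 60]         # kg/m^2
  target_ei: [1000, 5000]  # kcal/day
  pal: [1.0, 2.5]
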