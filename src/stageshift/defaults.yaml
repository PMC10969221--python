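# Default study configuration: an Alberta's Tomorrow Project (ATP) breast-cancer
# cohort summarized by seven modifiable lifestyle factors (N = 492 women).
# Continuous dietary intakes are truncated-normal (floor at 0); the five
# lifestyle indicators are Bernoulli.
factors:
  energy:
    kind: continuous
    label: "Total dietary energy intake (kcal/day)"
    mean: 1605
    sd: 576
    bounds: [0, null]
  protein:
    kind: continuous
    label: "Total dietary protein intake (g/day)"
    mean: 64
    sd: 25
    bounds: [0, null]
  mammogram:
    kind: binary
    label: "Have had mammogram test (yes)"
    proportion: 0.831
  pregnant:
    kind: binary
    label: "Have been pregnant (yes)"
    proportion: 0.902
  sun:
    kind: binary
    label: "Spend time in the sun 11am-4pm, June-August (>= 1 h/day)"
    proportion: 0.504
  stress:
    kind: binary
    label: "Currently experiencing stressful situation (>= 1)"
    proportion: 0.535
  birth_control:
    kind: binary
    label: "Use birth control pills (yes)"
    proportion: 0.868

# Pairwise correlations of the realized variables as (factor_a, factor_b, value)
# triples.  The source cohort's correlation values are not published, so the
# packaged default is independence — a PLACEHOLDER, not an ATP estimate.
# Supply triples here when real estimates are available.
correlation: []

# Proportional odds ratios for later stage at diagnosis (OR > 1: risk factor).
# unit_scale maps natural units to model units: energy enters per 100 kcal/day,
# protein per 1 g/day, indicators per unit presence.  CIs are metadata only.
odds_ratios:
  energy:        {or: 1.07, ci: [1.01, 1.14], unit_scale: 0.01}
  protein:       {or: 0.98, ci: [0.97, 1.00], unit_scale: 1.0}
  mammogram:     {or: 0.57, ci: [0.33, 0.97]}
  pregnant:      {or: 0.51, ci: [0.27, 0.98]}
  sun:           {or: 0.56, ci: [0.32, 0.99]}
  stress:        {or: 2.87, ci: [1.55, 5.32]}
  birth_control: {or: 1.64, ci: [0.94, 2.86]}
# Hook for cut-specific odds ratios of the non-proportional factors
# (pregnant, sun, stress); the published per-cut values are unavailable, so
# the single OR above is applied proportionally by default.  Example:
#   per_cut_odds_ratios: {stress: [2.9, 2.1]}
per_cut_odds_ratios: {}

model:
  stages: ["I", "II", "III+IV"]
  # Observed stage distribution: 51% I, 37% II, 10% III + 2% IV (merged).
  baseline_stage_distribution: [0.51, 0.37, 0.12]
  sigma: 0.0
  calibration_n: 100000

# Scenario I: one factor swept over five values, others fixed at observed.
scenario1:
  designs:
    - {id: "1", factor: energy,        grid: [1800, 1700, 1605, 1500, 1400], baseline: 1605}
    - {id: "2", factor: protein,       grid: [64, 70, 75, 80, 85],           baseline: 64}
    - {id: "3", factor: mammogram,     grid: [0.70, 0.75, 0.83, 0.90, 0.95], baseline: 0.83}
    - {id: "4", factor: pregnant,      grid: [0.75, 0.80, 0.85, 0.90, 0.95], baseline: 0.90}
    - {id: "5", factor: sun,           grid: [0.3, 0.4, 0.5, 0.6, 0.7],      baseline: 0.5}
    - {id: "6", factor: stress,        grid: [0.7, 0.6, 0.53, 0.4, 0.3],     baseline: 0.53}
    - {id: "7", factor: birth_control, grid: [0.70, 0.80, 0.87, 0.92, 0.98], baseline: 0.87}
  # Headline single shifts (applied to the observed values): -100 kcal/day,
  # protein to 70 g/day, +5 points mammogram and pregnancy, +10 points sun,
  # -10 points stress, +10 points birth-control use.
  headline_shifts:
    "1": 1505
    "2": 70
    "3": 0.881
    "4": 0.952
    "5": 0.604
    "6": 0.435
    "7": 0.968

# Scenario II: factors that singly moved stage I by >= 0.5 points, added
# sequentially; each design pins earlier factors at their optimal values.
scenario2:
  designs:
    - {id: A, factor: energy,        grid: [1605, 1500, 1400], optimal: 1400}
    - {id: B, factor: protein,       grid: [64, 70, 85],       optimal: 85}
    - {id: C, factor: mammogram,     grid: [0.83, 0.90, 0.95], optimal: 0.95}
    - {id: D, factor: pregnant,      grid: [0.90, 0.95, 0.95], optimal: 0.95}
    - {id: E, factor: birth_control, grid: [0.87, 0.80, 0.70], optimal: 0.70}

# Scenario III: policy-targetable factors at their most impactful levels,
# added cumulatively in this order.
scenario3:
  targets:
    energy: 1400
    protein: 85
    mammogram: 0.95
    sun: 0.7

run:
  n_realizations: 20
  n_per_realization: 1000
  pairing: common_random_numbers
  tail: 0.0225
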