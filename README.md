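# stageshift

Monte-Carlo simulations of **stage shifting**: how much would the distribution
of breast-cancer stage at diagnosis move if a population's modifiable
lifestyle factors changed?

`stageshift` is aimed at cancer-epidemiology and screening-program analysts
who have *summary* inputs — factor means/prevalences and published odds
ratios from an ordinal regression of stage at diagnosis — but no access to
individual-level cohort data. It builds a synthetic population that matches
those summaries, pushes it through a cumulative-logit stage model, and
reports how single or cumulative counterfactual changes in the factors move
the stage distribution, with Monte-Carlo uncertainty.

## Model

Stage at diagnosis is ordinal (I, II, III+IV; III and IV merged because stage
IV is rare). For cut *j* the exceedance probability follows a proportional
odds model

    P(Stage > j | x) = expit(α_j + xᵀβ + zᵀγ_j + ε),   ε ~ N(0, σ²),

where β holds one log odds ratio per factor shared across cuts, selected
factors may instead get cut-specific slopes γ_j (the partial-proportional
relaxation), and σ is an optional residual-heterogeneity SD (default 0;
integrated out by Gauss–Hermite quadrature when positive). OR = exp(β) > 1
marks a risk factor for later-stage diagnosis; OR < 1 is protective.

The intercepts α_j are rarely published, so they are **calibrated**: each α_j
is solved by monotone root-finding so that the population-average exceedance
over a large calibration cohort matches a target baseline stage distribution
(the packaged default is 51% / 37% / 12%).

Cohorts are drawn from a **Gaussian copula**: continuous dietary intakes are
truncated normal (floor at 0), binary lifestyle indicators are latent-normal
thresholded Bernoulli, and the latent correlation matrix is solved from the
target correlations of the realized variables (Emrich–Piedmonte root-finding
for binary pairs). Counterfactual runs shift one factor's mean or prevalence
and reuse the baseline's random streams (common random numbers), so
stage-wise percent changes are low-variance and sum to zero exactly within
each realization. Results across 20 realizations of 1000 subjects are
summarized by the median and a 95% percentile interval (2.25% tails).

## Worked example

```python
import numpy as np
from stageshift import (RunConfig, DesignSpec, calibrate_intercepts,
                        run_baseline, run_design)
from stageshift import config

cfg = config.load_config()                      # packaged cohort + model inputs
spec = config.cohort_spec_from_config(cfg)
coeffs = calibrate_intercepts(
    spec,
    config.coefficient_set_from_config(cfg),
    config.baseline_distribution(cfg),          # 51% / 37% / 12%
    n_calib=100_000,
    seed=(1, 987654321),
)
run_cfg = RunConfig(n_realizations=20, n_per_realization=1000, master_seed=1)
baseline = run_baseline(spec, coeffs, run_cfg)
print("baseline stage proportions:", np.round(baseline.proportions.mean(axis=0), 3))

design2 = DesignSpec("2", "protein", grid=(70.0,), baseline_value=64.0)
shifted = run_design(design2, spec, coeffs, run_cfg, baseline=baseline)[0]
print("protein 64 -> 70 g/day, stage-wise change (points):",
      np.round(shifted.mean_percent_change, 2))
```

Output:

```
baseline stage proportions: [0.511 0.371 0.119]
protein 64 -> 70 g/day, stage-wise change (points): [ 2.38 -1.4  -0.98]
```

The calibrated baseline reproduces the observed 51/37/12 stage split to
Monte-Carlo precision. Raising mean daily protein intake from 64 to
70 g/day (OR 0.98 per g/day) moves about 2.4% of diagnoses into stage I,
drawn from stages II (−1.4 points) and III+IV (−1.0 points).

## Command line

```bash
stageshift run --scenario 1 --seed 1 --out results/scenario1          # single-factor sweeps
stageshift run --scenario 2 --seed 1 --out results/scenario2 --figures # cumulative A–E
stageshift run --scenario 3 --seed 1 --out results/scenario3          # policy subset
```

Each run writes `summary.csv` (one row per design / grid value / stage with
median, percentile interval and average percent change), `summary.json`, a
`run_meta.json` echoing the configuration and seed, and optional
dot-and-interval figures. Identical seeds give bitwise-identical outputs.
Study definitions (factor margins, odds ratios, design grids) live in a YAML
config; `src/stageshift/defaults.yaml` documents the schema and ships the
default study.

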