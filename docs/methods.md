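# Methods

## Problem and approach

The package estimates how counterfactual changes to modifiable lifestyle
factors would shift the population distribution of breast-cancer stage at
diagnosis. Only summary inputs are required: each factor's marginal
distribution in the diagnosed population, a published odds ratio per factor
from an ordinal (proportional or partial-proportional odds) regression of
stage, and the observed baseline stage distribution. The pipeline is

1. **cohort** — draw synthetic cohorts matching the factor margins and a
   target correlation structure;
2. **model** — map each subject to stage probabilities through a
   cumulative-logit model whose slopes are the published log odds ratios and
   whose intercepts are calibrated to the baseline stage distribution;
3. **scenarios** — re-simulate under shifted factor distributions, singly or
   cumulatively, paired with the baseline by common random numbers;
4. **report** — summarize realization-level stage proportions by medians,
   percentile intervals and average percent change.

## Synthetic cohort generator

Seven factors are modelled: total dietary energy (truncated normal, mean
1605, SD 576 kcal/day), total dietary protein (truncated normal, mean 64,
SD 25 g/day), and five binary indicators — mammogram history (0.831),
ever-pregnant (0.902), summer midday sun exposure ≥ 1 h/day (0.504), current
stressful situation (0.535), birth-control pill use (0.868). These defaults
describe a diagnosed breast-cancer cohort of 492 women from a prospective
Alberta health study and are the conditions under which all packaged
scenarios run.

Sampling uses a single Gaussian copula across all seven factors. A latent
multivariate normal vector is drawn; binary coordinates become 1 when the
latent value exceeds the standard-normal quantile at 1 − prevalence;
continuous coordinates are location/scale transformed, and any row violating
a continuous bound is redrawn whole, so the continuous block follows an exact
truncated multivariate normal law. Rejection sampling (rather than transform
sampling) keeps the joint law exact; the cost is negligible because the
truncated mass is tiny for the default margins.

Design choices in the generator:

- **Truncation bounds.** Intake bounds are unspecified in the source
  summaries; the default is [0, ∞) as a physiological floor, overridable in
  the config. Because both means sit ≥ 2.5 SD above zero, truncation biases
  the realized energy mean upward by ≈ 4.8 kcal/day (0.3%) and shrinks its SD
  by ≈ 1.2%; protein analogously by ≈ +0.4 g/day. Tests and acceptance
  tolerances (3 Monte-Carlo SEs on means, 3% on SDs) absorb this.
- **Latent correlations.** Binary–binary entries are solved from the
  bivariate-normal orthant-probability equation (Emrich–Piedmonte) by Brent
  root-finding; infeasible targets (outside the Fréchet-type range implied by
  the margins) raise an error naming the pair and the attainable range.
  Continuous–binary entries use the closed-form solution of the analogous
  moment equation, ignoring the (≤ 1%) effect of continuous truncation;
  continuous–continuous entries pass through. The assembled matrix is
  projected to the nearest positive semi-definite correlation matrix if
  needed.
- **Default correlation.** The source cohort's correlation values are
  unpublished, so the packaged default is independence — explicitly a
  placeholder. Users supply known correlations as (factor, factor, value)
  triples.
- **Acceptance floor.** If the product of per-factor in-bounds probabilities
  falls below 1e−6, sampling aborts rather than loop indefinitely. The
  product is exact under the default independence and conservative in
  practice for the mild correlations this application sees.
- **Seeding.** Every random stream is a `numpy.random.SeedSequence` over a
  path of small integers `(master_seed, arm, realization, stream)`; the path
  is recorded on each sample (`seed_path`), making every artifact
  reproducible from the master seed alone.

## Stage model

With two cuts (I | II, III+IV), the exceedance probability at cut *j* is
`expit(α_j + xᵀβ + zᵀγ_j + ε)`. Slopes come from printed odds ratios:
`β = ln(OR)` per model unit, with unit scales making the energy OR (1.07)
per 100 kcal/day and the protein OR (0.98) per 1 g/day; indicator factors
enter per unit presence. A factor given per-cut odds ratios switches to
cut-specific slopes `γ_j = ln(OR_j)` (its shared slope is dropped). The
published fit treated pregnancy, sun exposure and stress as
non-proportional, but their per-cut values are unavailable, so the default
applies each factor's single printed OR proportionally; the config exposes a
`per_cut_odds_ratios` hook for when the values are known. Residual
heterogeneity σ is likewise unpublished and defaults to 0; when σ > 0 the
population-level exceedance integrates the logistic over ε with 40-node
Gauss–Hermite quadrature (cross-checked against million-draw Monte Carlo).

Category probabilities are differences of adjacent exceedances. Crossing
exceedances (possible under non-proportional γ) raise an error identifying
the subject and cut — they are never clipped silently, since that would bias
the stage distribution.

**Intercept calibration.** The α_j are solved so the population-average
exceedance over a freshly sampled calibration cohort matches the target
cumulative proportions (default target 0.51/0.37/0.12 → cumulative 0.49 and
0.12). The average exceedance is strictly increasing in α_j, so each cut is
an independent bracketed root-find on α ∈ [−30, 30] (Brent, xtol 1e−6);
unattainable targets (e.g. a degenerate stage distribution) raise rather
than clamp. Default calibration cohort size is 100,000: its Monte-Carlo
error (≈ 0.2 percentage points at 1 SE on a 51% proportion over 20,000
pooled subjects is the comparison scale) is then an order of magnitude below
the 20 × 1000 simulation noise the results are judged against. Whatever
non-modifiable covariates the original regression adjusted for are implicit
absorbed into the calibrated intercepts.

**Stage assignment.** Per-subject stages are sampled categorically (one
uniform per subject against the cumulative category probabilities) and
proportions computed from the sampled labels, matching how the study
protocol tabulates simulated stages. Population-expected (noiseless)
proportions are available by averaging `StageProbabilities.category`
directly, used in the shift-direction tests.

## Scenarios

`RunConfig` defaults to 20 realizations × 1000 subjects, the study's stated
size. Three scenario types:

- **Single-factor sweeps** (designs 1–7): one factor moves over a 5-point
  grid containing its observed value, all others fixed at observed values.
  Headline single shifts (−100 kcal/day energy; protein to 70 g/day;
  +5 points mammogram and pregnancy; +10 points sun; −10 points stress;
  +10 points birth-control use) are packaged alongside the grids; where the
  printed shift amount and the printed grid disagree (e.g. "−100 kcal/day"
  vs. a 1605 → 1500 grid step), the literal shift amount is used, except
  protein whose target value (70 g/day) is named explicitly.
- **Cumulative designs A–E**: energy, protein, mammogram, pregnancy,
  birth-control added one at a time, each new design pinning the previous
  factors at their optimal values (1400 kcal/day, 85 g/day, 0.95, 0.95,
  0.70). Design D's printed grid (0.90, 0.95, 0.95) contains a duplicate and
  is reproduced as printed.
- **Policy subset**: energy, protein, mammogram and sun exposure at their
  most impactful levels (1400, 85, 0.95, 0.7), cumulatively.

**Pairing.** By default every arm reuses the baseline's per-realization
streams (common random numbers): the same latent normals generate the
cohort (a shifted mean translates values; a shifted prevalence moves the
threshold on the same latents) and the same uniforms assign stages. This
makes the identity shift exactly zero, makes stage-wise percent changes sum
to zero within each realization, and reduces the variance of change
estimates by orders of magnitude (verified against `independent` pairing,
which is available for fidelity runs since the source tables' rows do not
sum exactly to zero, suggesting unpaired runs or rounding).

**Roster rule.** `significant_designs` implements the ≥ 0.5-point stage-I
inclusion rule for promoting single-factor designs into a cumulative
scenario. With the single printed OR applied proportionally, sun and stress
produce stage-I shifts above that cutoff, unlike in the source analysis
whose non-proportional per-cut slopes (unavailable here) evidently dampened
their stage-I effect — so the re-derived roster is a superset of the
published one. The packaged cumulative designs therefore follow the
published A–E roster verbatim rather than re-deriving it.

## Reporting

Realization-level stage proportions are summarized by the median and the
95% percentile interval between the lower and upper 2.25% of ranked values —
the tail the source tables print; `tail=0.025` gives the conventional
interval. Quantiles use linear interpolation between order statistics
(checked to 1e−12 against a brute-force sort-and-interpolate oracle); with
20 realizations the choice of quantile rule visibly affects interval width,
so it is configurable and documented rather than hidden. Percent change is
reported in percentage points of the stage distribution (a value of 0.83
means +0.0083 absolute). CSV output uses shortest round-trip float
formatting (re-read with pandas `float_precision="round_trip"` for bitwise
equality); `run_meta.json` echoes the config and master seed so any output
can be regenerated bit for bit.

## What the generator does and does not emulate

The synthetic cohort matches the real cohort's first moments, prevalences
and (when supplied) pairwise correlations, and the stage model reproduces
its marginal stage distribution and published effect sizes. It does not
capture higher-order dependence, non-normal intake shapes (skewness of
dietary data), measurement error, or the non-modifiable covariates (age,
income, comorbidity, family history) that the original regression adjusted
for — their influence is frozen inside the calibrated intercepts. Passing
tests therefore certify the simulation machinery and its calibration, not
that the counterfactual effects would materialize in a real population;
single-cohort odds ratios carry their own generalizability limits.

## Numerical choices and limitations

- Logistic and quadrature evaluations are vectorized float64; category rows
  sum to 1 within 1e−12 and are validated non-negative.
- Brent tolerances: 1e−12 on latent correlations, 1e−6 on intercepts.
- Boundary correlation targets (at the Fréchet bound) clamp the latent
  correlation to ±(1 − 1e−10) rather than failing, reproducing the boundary
  cell probabilities to ~1e−6 (the bivariate-CDF accuracy).
- With unpublished intercepts, per-cut slopes and residual SD, reproduction
  of the source study's shift magnitudes is approximate by construction; the
  packaged tests check the headline protein effect within ±0.75 percentage
  points and the sign pattern of all seven single-factor shifts, not
  table-exact values.
- Problem sizes in tests and the acceptance script follow the study protocol
  (20 × 1000 per arm; 100,000-subject calibration); oracle cross-checks use
  up to 4 × 10⁶ draws where 1e−3 cell-probability agreement is asserted.
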