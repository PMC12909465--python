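# Methods

`dietshift` simulates what happens to a population's nutrient adequacy and
environmental footprint when meat and/or dairy consumption in a two-recall
dietary survey is replaced by plant-based alternatives. This note documents
the models, the synthetic data that stand in for the restricted survey,
food-composition and life-cycle-assessment (LCA) datasets, the numerical
choices, and the limits of what the tests demonstrate.

## Replacement scenarios

The reference diet is the observed consumption: one record per eating
occasion (person, recall day, food, grams). Four replacement scenarios are
modelled, each under two strategies:

| scenario            | targeted records                      | fraction |
|---------------------|---------------------------------------|----------|
| `no_meat_and_dairy` | all meat and dairy subgroups          | 1.0      |
| `no_meat`           | all meat subgroups                    | 1.0      |
| `half_meat`         | all meat subgroups                    | 0.5      |
| `no_red_meat`       | records of red-meat foods only        | 1.0      |

For every targeted record, one replacement food is drawn uniformly (with
replacement) from the consumed subgroup's mapped list of plant-based
alternatives, using a dedicated seeded stream per scenario x strategy.
Under the *quantity* strategy the replacement carries exactly the replaced
grams; under the *energy* strategy its grams are scaled by the ratio of
energy densities so the kilocalories of the replaced grams are conserved
exactly. Design choices where the procedure was genuinely open:

* **Per-record halving.** `half_meat` halves every targeted record's grams
  rather than replacing a random half of the records; this is
  deterministic in the fraction and independent of how finely occasions
  are recorded.
* **Per-occurrence draws.** The uniform draw is per consumption record,
  not per food code or per person; with thousands of records this
  averages allocation noise down to a coefficient of variation well below
  0.01 across replicates (`replicate_allocation_cv` quantifies this).
* **Energy-density guard.** In energy mode, candidates below 0.05 kcal/g
  are excluded from the candidate list; matching calories into a
  near-zero-energy food would require physically meaningless gram
  amounts. A group whose candidates are all below the guard is an error.
* **Composition of rules.** In `half_meat` under the energy strategy the
  replaced half is energy-matched and the retained half is untouched.

## Habitual (usual) intake model

Two 24-h recalls per person allow separating day-to-day (within-person)
from between-person variation. For each nutrient and sex the package fits
a one-part model (appropriate for nutrients consumed daily by everyone):

1. **Transform.** Daily intakes are transformed by the geometric-mean
   standardized Box-Cox, z = ((y/g)^λ − 1)/λ with g the survey-weighted
   geometric mean (λ = 0 gives log(y/g)). λ is chosen on the fixed grid
   {0, 0.05, …, 1} by Gaussian profile likelihood; with the standardized
   form the Jacobian term is constant in λ, so the criterion reduces to
   the weighted residual sum of squares, and — importantly — the residual
   scale is comparable across the grid, so the estimated variance
   components do not jump if the data place λ̂ one grid step away from
   the truth. Zero intakes are handled by shifting all values by half the
   smallest positive value (logged, and undone after back-transform).
2. **Age trend.** A weighted linear regression of z on (age − 40), per
   sex, with survey weights as observation weights (weights are used both
   in the fit and in all population aggregation).
3. **Variance split.** σ_w² is the weighted mean of the within-person
   residual day variance (half the squared day difference for two days);
   σ_b² is the weighted variance of person-mean residuals minus its
   within-person share σ_w²/d, truncated at zero (truncation logged).
4. **Person-level habitual values.** Each person's transformed habitual
   value is the fitted age trend plus the person-mean residual scaled by
   σ_b/√(σ_b² + σ_w²/d). This *variance-matching* makes the
   transformed-scale variance of the habitual values exactly σ_b².
   Posterior-mean (BLUP) shrinkage by σ_b²/(σ_b²+σ_w²/d) would minimize
   per-person error but under-disperse the population distribution by the
   factor √shrink, which visibly biases tail statistics: at σ_b = 0.30,
   σ_w = 0.50 the estimated fraction below a true 5th-percentile cutoff
   would be Φ((z_q − (1−s)σ_b/2)/√s) ≈ 0.004 instead of 0.05. Because the
   whole point of the distribution is comparison against cutoff values,
   the distribution-matched estimator is used.
5. **Back-transform and population mean.** Values return to the original
   scale through the inverse transform (a negative base at λ > 0 clamps
   to zero, logged). The population mean is computed by 30-node
   Gauss-Hermite integration of the inverse transform over
   N(age trend, σ_b²), which is unbiased on the original scale; in the
   λ = 1 case it preserves the weighted grand mean of daily intakes
   exactly, and in the λ = 0 case it converges to the lognormal closed
   form exp(μ + σ_b²/2).

**Adequacy.** The cut-point method: the proportion of the habitual
distribution strictly below the Estimated Average Requirement (EAR), for
vitamin A, B12, B6, B2 and calcium, per sex. A proportion above 0.10
flags a potential public-health concern.

**Uncertainty.** Percentile bootstrap, 200 iterations by default, persons
resampled with replacement within sex strata with both recall days
travelling together. Within a bootstrap the Box-Cox power is held at the
point-estimate grid value; re-searching the grid per resample changes
nothing detectable in the intervals but dominates runtime. Scenario
differences are flagged when the 95% intervals do not overlap — a
conservative criterion, as in the underlying deterministic simulation
design no formal tests are applied.

## Environmental footprints

Three indicators per food, per kg: greenhouse-gas emission (kg CO2-eq),
land use (m²·year) and freshwater consumption (liters). Diet footprints
are linear: per person-day, Σ amount_g/1000 × factor. Population values
average within person across days first, then weight across persons
(symmetric with the intake summaries; identical when both days are
complete). Relative differences are percentages versus the reference
scenario; contribution shares are per consumed group, survey-weighted.
LCA factors are point values; no uncertainty is propagated (the same
convention as the monitoring datasets this emulates).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

* **Survey.** 600 women and 585 men by default, ages uniform on [18, 65],
  lognormal survey weights (relative SD 0.2) normalized to mean 1 per sex.
* **Food database.** 5 meat and 9 dairy consumed subgroups (8 foods
  each) plus six staple groups (bread/cereals, vegetables, fruit,
  fish/eggs, snacks, fats/sauces). Each meat/dairy subgroup maps to a
  list of pure-plant alternatives whose length is 1 + Binomial(30, 11/30)
  — mean 12, support [1, 31]. Nutrient densities are drawn per food
  around class profiles with relative SD 0.2 (≤ 0.3). Plant alternatives
  carry more fiber, less saturated fat and zero B12 (unless a
  fortification flag is set); their footprint factors are lower for GHG
  and land but higher for water than the animal foods they replace. Meat
  foods are red meat with probability 0.8 (red meat dominates meat
  consumption in the emulated population), with markedly heavier GHG/land
  factors.
* **Intake model.** Transformed daily intake = sex-level mean +
  age_slope·(age − 40) + b_i + e_ij, with b_i ~ N(0, σ_b²) and
  e_ij ~ N(0, σ_w²); defaults σ_b = 0.30, σ_w = 0.50, λ = 0 (lognormal),
  age slope −0.003/yr, identical across nutrients, with *one* shared
  standard-normal person factor and day factor across nutrients. Sharing
  the factors keeps every fixed linear combination of nutrients (e.g.
  total = plant + animal protein) exactly lognormal.
* **Exact realization.** Each person-day draws Poisson eating occasions
  per group (floored at the group minimum — staples at least daily, so
  every nutrient is consumed every day), foods uniform within group, and
  lognormal provisional amounts pinned to the group's expected grams.
  The amounts are then minimally adjusted — a non-negative least-squares
  step regularized toward the provisional menu, polished by an active-set
  equality solve, with the menu widened by extra foods in the rare case
  the target lies outside its cone — so that all 12 independent nutrient
  totals hit the latent model targets exactly (residuals ~1e-13 in
  practice; failures are counted and reported). The latent sex-level
  means are anchored at the expected totals of the realized menu, which
  keeps the reference diet at the emulated population's conditions:
  plant-protein share ≈ 0.40, meat ≈ 120 g/day and dairy ≈ 400 g/day for
  women (men scaled by 1.3), and total footprints of a few kg CO2-eq per
  day. These defaults were set by a forward analytic calculation of the
  expected menu, not by fitting to any test outcome.
* **Ground truth.** Each person's latent habitual intake per nutrient is
  the back-transformed linear predictor without the day effect; the
  analytic population habitual mean integrates the person effect (exact
  in the lognormal case) and averages over the age distribution. EARs are
  planted at a configurable survey-weighted quantile of the latent
  habitual values, so the true inadequacy fraction is known by
  construction.

**What the generator does not emulate.** Real recall data have episodic
(non-daily) foods, reporting error, digit preference, seasonal and
day-of-week structure, correlated food preferences, and amount
distributions that are not lognormal. Passing tests demonstrate that the
estimators recover the truth when the model is correctly specified and
that the scenario arithmetic is exact — not that the model is correct for
any real survey. The generative model is deliberately the model the
habitual-intake module assumes, so parameter recovery is a clean oracle.

## Numerical choices

* Box-Cox grid [0, 1] step 0.05; ties broken toward the smaller λ by
  strict-improvement comparison.
* Gauss-Hermite: 30 nodes (mean integration), 40 nodes for the
  generator's analytic truth.
* Exact-realization solver: NNLS on the target-normalized system with
  regularization 1e-4 toward the provisional menu; active-set polish;
  acceptance at max relative residual 1e-6; at most two menu-widening
  retries.
* Bootstrap redraw budget: 5% of the requested iterations; exceeding it
  raises.
* Seeds: the master seed drives three independent generator streams
  (population, food database, consumption); scenario allocation seeds and
  bootstrap seeds are derived from the master seed by CRC32 hashing of
  the scenario/strategy/sex labels, all below 2³¹.

## Problem sizes used in the checks

The acceptance-style checks run at the survey's natural scale (1185
persons) for allocation stability, n = 1000 (one sex) for parameter
recovery and cut-point fidelity, and 200 scaled-down worlds of 150 women
for bootstrap coverage — sizes chosen so each check is decisive for its
tolerance while the whole suite stays quick to run.

## Known limitations

* The one-part model is inappropriate for episodically consumed nutrients;
  a two-part model is out of scope.
* EARs are treated as single adult values per sex; age-specific
  requirements within 18-65 are not modelled.
* The equal-probability replacement draw ignores consumer preference and
  market shares.
* Survey weights enter both the likelihood and the aggregation; whether
  the emulated national tooling weights the likelihood is not documented,
  so this choice is configurable (`use_weights`).
* Water-scarcity weighting and seasonal LCA variation are not modelled;
  footprint factors are national averages.
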