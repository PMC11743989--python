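# Methods

## The estimand

The cognitive footprint of an exposure is its per-person effect on a
cognitive outcome multiplied by the number of exposed people in a target
population.  For a medication *j* with posterior coefficient draws β⁽ˢ⁾ (in
Z-scores of the outcome per exposure) and a population partitioned into
age × sex strata with counts N_c and exposure prevalence p_{j,c},

    footprint⁽ˢ⁾ = β⁽ˢ⁾ · Σ_c p_{j,c} · N_c        (person·Z-scores)

summarized by the mean and equal-tailed 2.5%/97.5% quantiles over draws.
Because the footprint is linear in β, this propagation is exact — no delta
method, and the footprint interval is the coefficient interval rescaled by
Σ p·N.  For the binary prospective-memory outcome the per-person effect is
instead the average marginal effect on the probability scale (mean over
participants of P(success | exposed) − P(success | unexposed), other
predictors held at observed values), so the footprint counts people.  The
AME is the standard counterfactual average and reduces to the plain
logistic difference σ(α + β) − σ(α) in the intercept-only case, which the
tests exploit as a closed form.

All footprints are **exploratory upper bounds**: they assume (i) the
cross-sectional association is causal and (ii) the target population's
exposure prevalence equals the cohort's, stratified by age and sex.  The
package labels every footprint table accordingly.

Interventions on continuous covariates are handled analogously without a
prevalence term: the standardized coefficient is divided by the recorded
column SD (effect per original unit), multiplied by the intervention amount
and the full population count.

## Reporting rules

A coefficient (and its footprint) is *reportable* when its 50% equal-tailed
credible interval excludes zero — i.e. at least 50% posterior credibility
for a non-zero effect.  Zero on an interval boundary counts as contained.
Because equal-tailed intervals nest, anything whose 95% interval excludes
zero is automatically reportable; a test asserts this subset relation on
every stored fit.

Per outcome and ATC level, the top-10 medications are selected by the rank
statistic: within each posterior draw, medications are ranked by descending
|β| (rank 1 strongest, ties averaged), and the statistic is the mean rank
over draws.  Ties in mean rank break by larger posterior mean |β|, then
lexicographic ATC code.  This definition is deterministic given the draws
and reduces to ranking |posterior mean| when draws are degenerate.

## The regression model

Outcomes are modeled one at a time on the complete-case sample for that
outcome, with predictors standardized and the continuous outcome re-z-scored
on the same sample (each model therefore has its own Z-scale; the
standardization constants are stored per column so effects can be expressed
per raw unit or per exposure).  The prior is the horseshoe:

    y | β, σ²  ~ N(Xβ, σ²I)
    β_j        ~ N(0, λ_j² τ² σ²)       (penalized columns)
    λ_j, τ     ~ half-Cauchy(0, 1)
    σ²         ~ Jeffreys (1/σ²)

The intercept and the age coefficient carry flat priors by default —
age is a known, strong determinant of cognition and a forced-in confounder,
not a hypothesis under selection; `HorseshoeConfig.unpenalized` makes this
a switch.  Binary outcomes drop σ² and use a logistic link.

### Sampling

* **Local scales λ_j** (and σ², and the λ auxiliaries): conjugate
  inverse-gamma updates via the inverse-gamma mixture representation of the
  half-Cauchy.  Every inverse-gamma variate is drawn as rate/Gamma(shape,1),
  which makes the linear chain exactly scale-equivariant in y under a fixed
  seed (a property test verifies the whole draw path at 1e-8).
* **Coefficient block**: one joint multivariate-normal draw per iteration
  from N(A⁻¹X'y, σ²A⁻¹), A = X'X + D⁻¹, via Cholesky factorization; X'X is
  precomputed, so iteration cost is O(p³ + np) and the n=5,000 × p=300
  contract runs comfortably on one CPU.
* **Global scale τ**: random-walk Metropolis on log τ targeting the
  conditional with β integrated out analytically,
  log f ∝ ½ b'A⁻¹b/σ² − ½ log|A| − p_pen·log τ + log C⁺(τ) + log τ,
  b = X'y.  The textbook fully-conjugate update (τ² | β, λ inverse-gamma)
  conditions on the current coefficients and creates a funnel: once τ drifts
  small, β is shrunk to the prior scale, which in turn keeps the τ rate
  small, and the chain can stall in a fully-collapsed state that annihilates
  genuine 4-5-SE signals (we confirmed this against an independent ensemble
  sampler on the collapsed posterior).  Marginalizing β removes the funnel;
  the coefficient block is redrawn immediately afterwards, making the move a
  valid partially-collapsed Gibbs step.  Proposal SD 0.8 on the log scale
  (≈30-50% acceptance across the scenarios in the test suite); acceptance
  rate is recorded in the fit diagnostics.
* **Logistic augmentation**: ω_i ~ PG(1, x_i'β) per observation, then the
  conjugate Gaussian block update with working precision X'ΩX and
  pseudo-response y − ½.  The PG(1, z) sampler uses the truncated
  infinite-convolution-of-gammas representation (64 terms) with a
  deterministic tail-mean correction, so the sampled mean is exactly
  tanh(z/2)/(2z) and the variance deficit is O(K⁻³) — negligible against
  Var PG(1,0) = 1/24.  The truncated form vectorizes over observations,
  which an exact per-element rejection sampler would not without compiled
  code; moment tests pin the mean and variance.
* **Numerical guards**: λ² and τ² are clipped to [1e-12, 1e12] (far outside
  any region with posterior mass) so D⁻¹ stays finite; log τ proposals
  outside ±30 are rejected.

Defaults: 4,000 iterations, 1,000 burn-in, thin 1 — chosen so a
desk-scale analysis (a dozen models at n ≈ 20,000, p ≈ 20) finishes in
minutes; effective sample sizes per coefficient (arviz) are reported in the
diagnostics and minimum ESS is logged per model.  Each (outcome × ATC
level) model runs one independent chain seeded by
`base_seed + crc32("outcome:Llevel")`, so runs are reproducible and models
independent.

### Summaries

Equal-tailed quantile intervals (not HPD) at 50% and 95% — reproducible
without density estimation and consistent with the symmetric bounds used in
this literature.  R² is the Bayesian draw-wise variance ratio
var(fit)/(var(fit)+var(resid)) averaged over draws (probability-scale
analogue with mean Bernoulli variance for logistic models).  Odds ratios
are exp(β) for logistic coefficients, reported to 4 decimals.

## Synthetic cohorts

The generator emulates the statistical structure of large mid-life cohort
studies rather than any dataset's exact margins:

* age uniform on 40-70 (keeps every 5-year stratum populated for the
  footprint stratification); sex Bernoulli at 54.2% female;
* medication exposures independent Bernoulli per participant at the
  specified prevalence (overall or per age×sex stratum); the default
  scenario uses 14 medications at 0.5-20% prevalence with effects of
  ±0.02-0.09 Z (±0.04-0.20 log-odds for the binary test) mirroring the
  magnitudes this kind of analysis reports, including one medication below
  the 1% inclusion threshold to exercise the filter;
* one shared standard-normal latent-cognition factor with per-outcome
  loadings of 0.5-0.8 induces the strong cross-test correlations that make
  a first principal component a meaningful summary (default battery: ~45%
  of variance on the first component);
* reaction-time-like scores are generated on their natural orientation
  (larger = worse), forcing the preprocessing sign flip;
* the binary prospective-memory test uses a logistic intercept of 1.186 ≈
  logit(0.766), matching a ~77% pass rate;
* missingness is per-outcome, completely at random (real cohorts' per-test
  availability is structured, but no mechanism is documented to emulate).

What the generator does **not** emulate: polypharmacy correlation between
exposures (hook available via stratified prevalence, but no joint
distribution is published), confounding by indication, selection into the
cohort, and measurement error in drug ascertainment ("regular use" is a
clean binary here).  Passing tests therefore demonstrate that the pipeline
recovers effects under its own assumptions — not that those assumptions
hold in any real cohort.

Analysis scripts run at n = 20,000 (and the test suite at n = 250-6,000),
a deliberate desk-scale choice: real cohorts of this kind are 20× larger,
so planted effects of 0.02-0.05 Z sit at 2-4 posterior SEs here rather
than 6-15, and only the strongest survive the horseshoe's shrinkage and the
50% reporting filter.  That is the statistically honest behaviour at this
n, and the parameter-recovery tests use effects scaled to be identifiable
(0.5 Z) instead.

## Population denominators

The published footprints' population denominators are not printed anywhere,
so `default_uk_strata` ships an openly illustrative synthetic population:
24.6 million people aged 40-70 split over six 5-year bins × two sexes with
mildly decreasing weights.  Prevalence per stratum is estimated from the
analysed cohort (`PopulationStrata.from_cohort_prevalence`), mirroring the
assumption that population prevalence equals cohort prevalence.  Any real
denominators can be supplied as a CSV.

## Design choices and degenerate inputs

* ">1% prevalence" is read strictly (exactly 1% is excluded).
* PCA uses the correlation matrix on rows complete for all battery tests;
  the component sign is fixed by positive correlation with the row-mean of
  the oriented tests; composite values are re-standardized.  Fewer complete
  rows than tests raises a rank-deficiency error.
* Zero-variance outcomes raise; constant predictor columns after
  complete-case subsetting are dropped with a logged warning.
* Categorical covariates are dummy-coded against their first (sorted)
  level.
* Quantiles use linear interpolation of order statistics (numpy default),
  cross-checked against a hand-written sort-based oracle.

## Known limitations

Cross-sectional coefficients are associations; the footprint inherits every
caveat of the underlying regression (confounding, reverse causation,
prodromal disease).  The binary-outcome footprint averages marginal effects
over the analysed sample, not the target population.  Duration-weighting of
effects over the lifespan and downstream dementia-risk projection are out
of scope.
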