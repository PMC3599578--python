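# Methods

## The generalized Poisson model

`gpcount` models the number of malnourished under-five children per
family as a generalized Poisson (GP) random variable,

    f(y; μ, α) = [μ/(1+αμ)]^y (1+αy)^(y−1)/y! · exp(−μ(1+αy)/(1+αμ)),

the mean-parametrized ("restricted") form with E(Y) = μ and
V(Y) = μ(1+αμ)². The dispersion parameter α is dimensionless: α = 0 is
exactly Poisson, α > 0 over-dispersion, α < 0 under-dispersion. The
regression layer links μ_i = exp(x_i β) and shares one α across
families.

### Support and truncation for α < 0

For α < 0 the factor (1+αy) changes sign at y = −1/α, so the density is
defined only on the finite support {0, …, y_max} with 1 + α·y_max > 0.
`gp_pmf` returns exactly 0 beyond that point, and `gp_total_mass`
reports the resulting total mass so callers can see the truncation
error. Two facts worth knowing, both verified numerically in the test
suite:

* The truncated sum is **not** bounded by 1: it can exceed it (for
  μ = 0.626, α = −0.3025 the mass is 1.000039). Within the family's
  validity region λ = αμ/(1+αμ) > −1 the error stays below about 2% and
  shrinks rapidly as the support grows (below 10⁻³ once the support has
  four or more points, which covers the study-scale parameters).
* Outside that region (λ ≤ −1, i.e. α ≤ −1/(2μ)) the function stops
  being a sub-probability altogether; parameters there are formally
  accepted (only 1+αμ > 0 is enforced, the usual convention) but
  results are not meaningful as probabilities.

`gp_sample` renormalizes the pmf over the finite support before
inversion sampling, so draws always come from a proper distribution;
the induced bias relative to the nominal (μ, μ(1+αμ)²) moments is below
10⁻³ at the study-scale parameters. All density work is done on the log
scale with `lgamma` for y!, so large counts cannot overflow.

## Dispersion diagnostics

The Consul–Jain moment estimators from a raw count vector are

    μ̂ = sqrt(ȳ³/s²),   α̂ = 1 − sqrt(ȳ/s²),

with the (n−1)-denominator sample variance. These live in the
Consul parametrization: at the population level they converge to
θ = μ/(1+αμ) and λ = αμ/(1+αμ) rather than to the regression-scale
(μ, α). The two agree in sign, and closely in magnitude for small
counts (for μ = 0.8, α = −0.3, λ = −0.316), so α̂ is a serviceable
dispersion diagnostic; the inconsistency is retained deliberately
because it is how the estimator is conventionally written. A separate
helper `alpha_from_meanvar` inverts s² = ȳ(1+αȳ)² for the
regression-scale α and is used only to initialize the ML fit.

### Asymptotic variances

The variances of (μ̂, α̂) are obtained by the delta method: both are
smooth functions of (ȳ, s²), whose joint asymptotic covariance follows
from the GP central moments (in Consul form μ₂ = θ/(1−λ)³,
μ₃ = θ(1+2λ)/(1−λ)⁵, μ₄ = 3θ²/(1−λ)⁶ + θ(1+8λ+6λ²)/(1−λ)⁷). Two
independent checks pin this down: at λ = 0 the formula collapses to the
known Poisson-limit value V(α̂) = 1/(2n) exactly, and a Monte-Carlo
experiment at n = 2000 reproduces the replicate variance of α̂ within a
few percent. `dispersion_wald_test` nevertheless takes the variance as
an argument, so a user with an externally supplied variance can use it
directly.

### The Wald Z test

Z = α̂ / sqrt(V(α̂)) is referred to the standard normal, two-sided.
Rejection with α̂ < 0 indicates under-dispersion and motivates GP over
standard Poisson regression. Type-I error is calibrated: on Poisson
data (n = 2000, 1000 replicates) the empirical rejection rate at the 5%
level is 5.5%.

## Maximum-likelihood regression

β and α are estimated jointly (the standard choice for GP regression)
by maximizing the log-likelihood with L-BFGS-B:

* **Initialization** — β from a Poisson GLM fit (statsmodels), α from
  `alpha_from_meanvar` clipped into the feasible box.
* **Feasibility** — α is box-constrained below by −1/max(y) + 10⁻⁶
  (keeping 1+αy_i > 0 for every observed count); points where some
  1+αμ_i ≤ 0 return a large finite penalty so the line search backs
  off. `gpr_loglik` itself returns −inf at infeasible points.
* **Gradient** — analytic, validated against finite differences.
* **Convergence** — relative objective change below 10⁻⁹ or gradient
  norm below 10⁻⁶, capped at 500 iterations; anything else raises
  `ConvergenceError` rather than returning a silently bad fit.
* **Standard errors** — inverse of the observed information, computed
  by central finite differences of the analytic gradient at the
  optimum (step 10⁻⁵ scaled by parameter magnitude); a singular or
  non-positive information matrix raises a named error.
* **Poisson comparison** — `fit_poisson` pins α = 0 in the same code
  path; on an intercept-only model it reproduces log(ȳ) and on
  covariate models it matches the statsmodels GLM estimates and
  standard errors.

The coefficient report applies the deterministic transforms
IRR = exp(β̂), CI = exp(β̂ ± 1.96·SE), Wald χ² = (β̂/SE)² with a 1-df
p-value; the 1.96 constant (not the exact 1.959964) matches the
symmetric-on-log-scale intervals conventional in this literature.

Under the reference conditions (n = 2000 families, the published
coefficient vector, α = −0.30), 200 simulated replicates show
per-coefficient bias indistinguishable from 0, 95% Wald CI coverage
between 0.92 and 0.98, and mean α̂ = −0.301.

## Screening and descriptives

Bivariate screening is the classical Pearson chi-square of independence
(no continuity correction, no multiplicity adjustment) with strict
p < 0.05 selection. Because the outcome is a count, it is binned
0 / 1 / 2+ before cross-tabulation; the integer predictors are binned
with caps 4+ (children ever born) and 1+ (children died). All three
binnings are reconstructions — the source analysis does not state its
binning — and are exposed as configuration knobs.

## Outcome construction

A child is malnourished iff the weight-for-height Z-score is strictly
below −2 SD (−2.00 exactly counts as well-nourished). Children without
anthropometry or outside 0–59 months are excluded before counting, with
a logged count. No biological-plausibility filter (e.g. |WHZ| > 5) is
applied by default. WHZ computation from raw height/weight is out of
scope; the survey file supplies precomputed Z-scores.

## The synthetic-data generator

The generator emulates the *statistical structure* of the survey, not
its sampling design:

* Covariate levels are drawn independently per family from the
  published marginal frequencies (renormalized to sum to 1, since the
  printed percentage columns sum to 99.8–100.1). Real covariates are
  correlated (wealth × education, notably); independence is a
  deliberate simplification — recovery experiments need known truth
  more than realism. Joint sampling would slot in at
  `generate_families` if ever needed.
* Children ever born = 1 + Poisson(1.67) with the excess capped at 9
  (mean 2.67; the cap keeps the largest attainable μ inside GP
  feasibility at α = −0.30). Children died is an independent
  Poisson(0.24); independence means a family can rarely report more
  deaths than births — accepted for the sake of exact closed-form
  intercept calibration.
* The intercept is calibrated in closed form so E[μ] equals the target
  mean count (0.626): with independent covariates E[exp(xβ)] factorizes
  into per-predictor sums and MGFs.
* Counts are GP(μ_i, −0.30) draws via renormalized inversion; any
  infeasible (μ_i, α) raises a config error naming the covariate
  pattern.
* Child emission gives each family max(count, 1 + Poisson(2.70) capped
  at 9) under-five children — mean 3.70, the value implied by the
  published aggregates 0.626/0.169, taken as-is even though it is
  demographically high — and assigns exactly `count` of them WHZ below
  −2 (truncated normal at −2.6 ± 0.45 on (−5, −2)) and the rest at or
  above −2 (truncated normal −0.3 ± 0.95 on (−2, 5)). The WHZ shapes
  are plumbing, not claims about anthropometry; the construction makes
  the outcome-builder round-trip exact and the pooled child prevalence
  ≈ 16.9%.
* Everything is driven by one integer seed (children use a derived
  stream), so datasets are bit-reproducible.

Consequently, passing tests demonstrate correctness of the estimators
and pipeline under a *known* GP data-generating process with the
published marginals and effects; they cannot validate survey-design
effects (clustering, stratification, weights), covariate correlation,
or real anthropometric noise.

## Problem sizes

Defaults were chosen to match the study scale: 1,200 families (the
published per-family mean 0.626, prevalence 16.9% and 4,460 children
imply a four-digit family count). Calibration experiments use 200
replicates of 2,000 families; consistency checks use single samples of
10⁴–10⁵ draws. These sizes give Monte-Carlo error well inside the
tolerances asserted in the tests.

## Known limitations

* The moment estimators' parametrization inconsistency (above) is
  inherited from their conventional definition and is left intact.
* No survey weights, clustering or stratification.
* No multicollinearity diagnostics; strongly correlated predictors
  (wealth, education) would inflate standard errors on real data.
* The screening step's binnings are reconstructions.
* The GP family itself cannot represent under-dispersion stronger than
  λ = −1, and its truncated density is only approximately normalized.
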