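# Methods

This note documents the statistical procedures implemented in
`cogbattery`, the assumptions behind them, the design choices that were
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Trials-to-criterion scoring

A test presents binary trials (1 = correct choice at chance probability
0.5); an individual passes at the first run of six consecutive correct
choices, and its score is the index of the final trial of that run —
so the criterion run is counted and the best possible score is 6,
matching a score range of 6–120.  Tests are stopped at 120 trials and
scored as 120 with a censoring flag.  Sessions paused and resumed in the
field are treated as one concatenated sequence; no session-boundary
model is attempted.

`chance_pass_probability` gives the exact probability that a
Bernoulli(p) chooser produces a run of r successes within n trials, by
dynamic programming over the current-run-length state.  At n = r it
reduces to `p^r`; six-in-six at chance 0.5 is 0.015625 (≈ 0.016), the
usual justification for the six-correct criterion.  The run-within-n
generalization supports criterion design (e.g. asking how often a random
chooser would pass *somewhere* within the 120-trial budget) but the
headline pipeline uses only the scores.

## GCP extraction and its permutation null

The score matrix (individuals × 3 tasks) is standardized per column
(n−1 denominator) and the correlation matrix eigen-decomposed.
Loadings are variable–component correlations (eigenvector ×
√eigenvalue); PC1 is oriented so its loading sum is non-negative, and
GCP is *minus* the projection of the standardized score row on the PC1
unit eigenvector, so higher GCP = fewer trials = better performance.
GCP values are mean-zero; their variance equals the leading eigenvalue
under the unit-eigenvector convention used here.  (The alternative
√eigenvalue scaling of coordinates changes nothing downstream because
predictors are standardized before every regression.)  Incomplete
batteries are rejected, not silently dropped: listwise deletion must be
the caller's explicit decision.

The permutation null shuffles each task's scores among individuals
independently, re-runs the PCA, orients PC1 by the same loading-sum
rule, and records the mean and s.d. (n−1) of the PC1 loadings; 95%
intervals are 2.5/97.5 percentiles with linear interpolation.  Two
design points matter:

* **Orientation.**  Without a sign rule the null mean loading is zero by
  symmetry and the null interval would be symmetric about zero; the
  loading-sum rule makes the null interval match what an analyst doing
  the same orientation on shuffled data would see.  Orienting by the
  sign of the first loading instead changes the interval little; the
  loading-sum rule is the default.
* **Verdicts.**  "Observed mean above the null 95% CI" behaves as a
  ~5%-level test (calibration over independent-column datasets sits in
  the 2–9% band).  The loading s.d. is reported against its null
  interval rather than tested: a genuinely general factor tends to show
  a *small* loading s.d. (uniform loadings), at the lower end of the
  null.

The implementation batches the shuffles (vectorized correlation
matrices and 3×3 eigen-decompositions); each iteration is mathematically
identical to shuffling the columns and calling the extraction routine.

## Repeatability

R = σ²_between / (σ²_between + σ²_within) from a one-way
random-intercept decomposition.  For balanced layouts the ANOVA
estimator is used directly (for balanced one-way designs it coincides
with REML, with negative between-group estimates truncated at zero);
unbalanced layouts fall back to a REML mixed-model fit.  Uncertainty is
by parametric bootstrap (resimulate from the fitted normal components,
re-estimate; default 1000 draws) and the p-value by permutation of
individual labels (one-sided, default 1000).  With ~18 individuals ×
2 replicates the bootstrap CI is approximate — nominal 95% intervals
cover the truth slightly below nominal — which is why the estimator, not
the interval, is the validated quantity.

## Mixed models and AICc selection

* **Gaussian (GCP determinants).**  One random intercept (social group).
  The fit profiles the variance ratio θ = σ²_group/σ²_resid: at fixed θ
  the GLS coefficients and residual variance are closed form (the
  marginal precision is block diagonal, I − θ/(1+θn_g)·11′ per group),
  leaving a 1-D bounded optimization.  This handles boundary fits
  (θ → 0) exactly — at θ = 0 the coefficients are identical to OLS —
  which matters because many candidates in a 42-model AICc set land on
  the boundary.  Estimates agree with lme4/statsmodels to numerical
  precision on interior fits.
* **ML, not REML, for ranked fits.**  AICc comparisons across different
  fixed-effect structures require likelihoods on a common scale, which
  REML does not provide; a `reml` switch (CLI `--criterion-fit`) exists
  for variance reporting.
* **Poisson (reproduction).**  Crossed random intercepts (year,
  individual).  The marginal likelihood is Laplace-approximated: for
  fixed (β, σ) the conditional mode of the random effects is found by
  damped Newton iterations on the penalized Poisson log-likelihood, and
  the outer optimization (L-BFGS-B) runs over β and log σ with the log
  s.d. bounded in [−10, 4]; at the lower bound the fit coincides with a
  Poisson GLM to < 1e-4 in log-likelihood.  Wald covariance for β is the
  Schur complement of the joint (β, b) Hessian.  Fits were
  cross-checked against lme4::glmer (Laplace) and agree to ~1e-3 on
  coefficients, standard errors and log-likelihood.
* **Parameter count.**  k = fixed coefficients + one variance component
  per random intercept (+ residual variance for gaussian); n = number of
  observations.  Wald 95% CIs are estimate ± 1.96·se.  Categorical
  terms use treatment coding with the alphabetically first level as
  reference (so `sex` is reported as the male contrast against a female
  reference).
* **Candidate sets.**  Null model + one model per single term + all
  pairwise additive models over a designated pool + all pairwise
  interactions (with both main effects) over an interaction pool.
* **Top model set.**  ΔAICc ≤ 2 *and* all interpreted coefficients'
  95% CIs exclude zero.  Main effects that are marginal to an included
  interaction are exempt from the CI screen: in the presence of an
  interaction they are conditional effects at the reference level and
  are not interpreted on their own (an age × sex model with a credible
  interaction belongs in the top set even when the sex main effect's CI
  spans zero).  AICc ties break toward fewer parameters.  Candidate
  models that are inestimable for a particular dataset (rank-deficient
  designs from empty factor cells) are skipped and logged, not silently
  dropped.

## Reproduction measures and fitness models

Breeding attempts are attributed to the dominant pair at attempt time;
attempts by non-dominants are an attribution error.  Within a breeding
season (September–August, the random "year" key) counts cumulate;
dominant-tenure years without success are explicit zero rows.  Missing
recruitment outcomes stay missing and drop the row from the recruitment
model set only — listwise per measure, never imputed.  The fitness
candidate set is {null, GCP, age, sex, group size, drought, GCP × sex}
per measure, Poisson with crossed year and individual intercepts.
Group identity is not a random term here (few groups with repeated
dominants produce singular fits); passing `random_terms` swaps it in as
a robustness check.  The age/sex trend in average yearly fledglings
since age 2 (the earliest breeding age) is checked with a gaussian
age × sex model on per-individual means — an approximation, flagged as
such, since per-individual averaging discards within-individual
year-to-year structure.

## Power

Power for a fixed-effect test with u numerator and v denominator df is
P(F′(u, v, λ) > F_crit(1−α; u, v)) with λ = f²(u+v+1) — the Cohen/pwr
convention; λ = f²·v is available behind a flag since textbooks differ.
The minimum detectable f² inverts this by bracketed root-finding to
1e-6.  At u = 1, v = 30 (one tested coefficient, N = 32), α = 0.05 and
power 0.80 the minimum detectable effect is f² ≈ 0.26, a moderate
effect.  Interaction-term power depends on the df convention chosen for
the interaction test and is reported for whatever (u, v) the caller
supplies rather than hard-coded.

## The synthetic-data generator

The generator emulates the *structure* of a wild cooperative-breeder
cognition study: groups of 2–7 adults each holding exactly one dominant
pair (dominants at least 2 years old), a 50:50 sex ratio, ages 1–13,
motivation-proxy covariates, and a latent general factor g ~ N(0, g_sd²)
shifted for females by `female_age_slope` (−0.77 by default) per s.d. of
age — males have no age trend.

**Learning curves.**  Per trial, the probability of a correct choice is
p_t = 0.5 + 0.49·(1 − exp(−(r·t)^shape)): chance at the start, an
asymptote of 0.99 (never 1, so 120-trial censoring has positive
probability), and a rate r with log r = base + gain·loading·g + noise.
The shape exponent (default 4) gives an S-shaped acquisition curve with
an onset lag near 1/r.  This choice is deliberate: with a memoryless
exponential rise (shape 1), the run-to-criterion statistic is dominated
by early-trial Bernoulli noise — measured across the plausible parameter
range, the correlation between extracted GCP and true g then plateaus
near 0.83 and the first component cannot reach the shared-variance level
seen in real batteries at realistic score means.  The lag-shaped curve
keeps monotone single-rate learning while letting the residual
dispersion parameter genuinely control cross-task correlation.  None of
this is a claim about avian learning mechanisms; the family is a
generative stand-in.

**Calibration.**  Defaults (base rates −3.33/−4.01/−3.22, link gain 1.2,
noise s.d. 0.25 at reference loadings of 0.8) were set once so that the
synthetic battery reproduces the statistical regime of the real study —
PC1 near 60% of score variance, score means in the mid-30s to ~50 with
single-digit-percent censoring, a score floor at 6 — while the latent
factor remains recoverable (corr(GCP, g) ≈ 0.84, PC1 > 55% in ~98% of
200-individual cohorts).  The reversal task is hardest, as in the field
data, but its mean (~47 trials) sits below the published ~63: pushing
the mean to 63 raises censoring to ~15%, which clips the g→score mapping
enough to destroy latent recovery.  Structure and recoverability were
prioritized over matching that one moment.

**Breeding.**  Dominants only.  Fledglings are Poisson with log mean
β₀ + β_gcp·z(GCP) + u_year + u_individual (β_gcp = −0.18 per s.d. by
default, σ_year = σ_id = 0.3); independence is a binomial thinning with
a logit drought penalty (drought itself a yearly Bernoulli flag — the
rainfall threshold that defines a drought season is metadata, not
simulated weather); recruitment a further binomial thinning.  The
marginal fledgling mean is exp(β₀ + (σ²_year+σ²_id)/2), which the
generator reproduces within Monte-Carlo error.  Because independents are
a thinning of fledglings, a GCP effect on fledglings propagates to the
independence measure; in validation scenarios that want a
drought-dominated independence set, the drought contrast must be strong
(the tests use a −2.5 logit penalty).

**What the generator does not emulate:** overdispersion beyond the
log-normal random intercepts, tenure turnover and dispersal, helper
effects on provisioning, year-to-year carryover in condition, unknown
sexes, unbalanced replicate designs, and any weather process.  Passing
recovery tests therefore demonstrates that the estimators recover the
truth under this clean data-generating process, not that field data meet
these assumptions.

## Validation scale

The recovery checks run at deliberately modest sizes so the whole suite
completes in well under a minute of simulation time: 100 replicates of
200-individual cohorts for factor recovery, 100 simulated studies of 20
dominants × 10 years for the fitness effect, 200 datasets of 18 × 2 for
repeatability, 500 datasets × 1000 shuffles for the permutation-null
calibration.  Empirical Wald-CI coverage for the Poisson mixed model at
20 dominants × 10 years is 87–91% at 95% nominal — the familiar
small-cluster Wald effect, present identically in lme4 on the same
data — and the recovery test asserts coverage within that stochastic
band rather than pretending to exact nominal coverage.

## Known limitations

* Wald intervals throughout; no profile-likelihood or bootstrap CIs for
  mixed-model coefficients.
* The Laplace approximation is not corrected for small counts (no AGQ);
  adequate here because counts are small but clusters are not tiny.
* One interaction per candidate model; no random slopes, model
  averaging, zero-inflation or overdispersion corrections.
* The repeatability engine assumes gaussian components; trial-level
  binomial noise enters only through the scores.
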