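# Methods

## Closed forms

Two analytic predictions of the c-statistic of a univariate logistic model
are implemented. With group-wise covariate moments (μ_A, σ_A) in affected
and (μ_U, σ_U) in unaffected subjects and the binormality assumption (X
normal within each group),

- general form: c = Φ((μ_A − μ_U)/√(σ_A² + σ_U²)) = Φ(d/√2), with
  d the standardized difference using the quadratic-mean pooled SD
  √((σ_A² + σ_U²)/2) — not the sample-size-weighted Cohen pooling; the
  algebra of the rewriting requires the quadratic mean.
- equal-variance form: c = Φ(σβ/√2), obtained from the general form via
  the discriminant-analysis identity β = (μ_A − μ_U)/σ² for a common SD σ.

Φ is evaluated with `scipy.stats.norm.cdf`; no approximation of our own.
Because Φ saturates to exactly 0.0/1.0 in double precision for |z| ≳ 8.3,
outputs are nudged one representable value into (0, 1) so the open-interval
contract holds for all finite parameters; the perturbation is one ulp and
invisible at any statistical scale.

Signs are kept literal: a negative β (or mean difference) predicts c < 0.5.
Direction-free discrimination is `max(c, 1 − c)`, left to the caller.

### Linear predictors

For a multivariable model the covariate is replaced by the model's linear
predictor, whose slope is 1 by construction when the outcome is regressed
on it alone. `auc_from_linear_predictor_moments` applies the general form
directly, or the equal-variance form with β = 1. The equal-variance path
needs a single combined-population SD; when only group moments are
available it is reconstructed by the law of total variance with caller-
supplied group weights (default equal). That moments-only reconstruction is
an extrapolation of the protocol — which pools *raw* covariate values when
data are at hand — and matters only when the supplied group SDs differ.

## Subject-level estimation

- **Logistic fit**: Newton–Raphson (equivalently IRLS) on internally
  standardized x — an exact reparameterization of the MLE that keeps the
  Hessian well conditioned under extreme covariate scales (log-normal
  covariates here span orders of magnitude). Convergence when every score
  component is below 1e−8, at most 50 iterations, starting from the
  intercept-only fit. Steps are halved only when the log-likelihood drops
  by more than 1e−10·(|ℓ|+1); demanding any improvement at all turned out
  to reject the final Newton steps once the true improvement fell below
  float rounding, stalling the score just above tolerance. Separation is
  flagged (never raised) when a standardized coefficient exceeds 20 or the
  fit fails to converge; estimates are then the last iterate and are
  treated as diverging.
- **Empirical c**: the fitted probabilities are scored with the
  Wilcoxon/Mann–Whitney rank-sum identity using midranks, which credits
  tied pairs exactly 0.5 — identical to exhaustive pair enumeration (a
  property the tests check exactly for n ≤ 50) and invariant under strictly
  increasing score transforms. Scores are the fitted probabilities, not raw
  x, so a negative fitted slope flips the direction — deliberately, since
  that is what evaluating "the c-statistic of the fitted model" means.
- **Moments**: variances use the n−1 denominator. Skewness defaults to the
  moment estimator b1 = g1·((n−1)/n)^{3/2} (g1 = m3/m2^{3/2} is available
  as an option), matching the default convention of the common statistical
  skewness helpers. Moments undefined at the group size (variance < 2,
  skewness < 3 subjects) are NaN, never silently 0.
- **Prediction from data**: formula 1 plugs the estimated group moments
  into the general form; formula 2 multiplies the fitted slope by the SD of
  x in the *combined* sample (both outcome groups pooled). These coincide
  only to first order in the mean separation: the combined variance exceeds
  the within-group variance by the between-group term w(1−w)(μ_A − μ_U)²,
  so formula 2 sits slightly above formula 1 at large effects.

## The simulation studies

Each replicate draws x_i for 1,000 subjects, sets
logit(p_i) = β0 + β1·x_i, draws y_i ~ Bernoulli(p_i), refits the univariate
logistic model, and records the empirical c alongside both predictions and
the within-group skewnesses; scenario cells average 500 such replicates
(both counts overridable). Factorial designs:

| study     | covariate                      | β0 levels        | exp(β1) levels       | family parameter        | cells |
|-----------|--------------------------------|------------------|----------------------|-------------------------|-------|
| normal    | N(0, σ)                        | −2, −1, 0, 1, 2  | 1 to 4 step 0.2      | σ: 0.2 to 4 step 0.2    | 1,600 |
| gamma     | shape k, scale 1               | −1, 0, 1         | 1 to 4 step 0.25     | k: 0.25 to 4 step 0.25  | 624   |
| lognormal | log-mean 0, log-SD s           | −1, 0, 1         | 1 to 4 step 0.25     | s: 0.1 to 2 step 0.1    | 780   |
| uniform   | U(−a, a)                       | −2, −1, 0, 1, 2  | 1 to 4 step 0.2      | a: 0.2 to 4 step 0.2    | 1,600 |

Grids are specified on the odds-ratio scale and converted to log-odds once
at construction; levels are generated by integer index (0.2·k), never by
repeated addition, so grid sizes cannot drift.

These generator settings *are* the study conditions; they emulate a single
continuous risk factor measured in a cohort whose outcome follows the
logistic law exactly. What they deliberately do not emulate: measurement
error in x, model misspecification of the link, confounding, or multiple
covariates — so passing validation here says the closed forms track the
c-statistic when the only violation in play is the shape of the covariate
distribution, nothing stronger about real cohorts.

### Randomness and reproducibility

One master seed; each scenario's seed derives from
SeedSequence(master, index-in-the-full-grid), and each replicate from
SeedSequence(scenario seed, replicate index). Results are therefore
bit-for-bit reproducible, independent of execution order, and a thinned
grid reproduces exactly the corresponding cells of the full grid.
`run_study` can append finished cells to a checkpoint CSV and resume an
interrupted run past them.

### Degenerate replicates

A replicate is recorded invalid — excluded from cell means, counted in
`n_failed` — when an outcome group has fewer than 3 subjects (its variance
or skewness would be undefined) or when the fit separates or fails to
converge. Resampling instead would bias the conditional distribution of the
retained replicates; exclusion plus a reported failure count is
transparent. In extreme cells (|β0| = 2 with a weak covariate, or heavy
log-normal tails) this policy can shift cell means at the third decimal
relative to any alternative handling.

### Desk-scale defaults

Tests and the acceptance script run thinned studies — every 4th level of
each factor, 100 replicates, 1,000 subjects — which finish in seconds to a
couple of minutes on one CPU while preserving the qualitative patterns: the
full grids remain the package defaults.

## Reporting choices

The scatter tables pair each cell's mean predicted c with its mean
empirical c; the skewness tables emit one row per cell per outcome group
(per-group rather than group-averaged skewness, since the two groups can be
skewed very differently under asymmetric covariates). Accuracy bands
default to predicted c in (0.5, 0.8], (0.8, 0.9], (0.9, 1.0), the ranges in
which prediction accuracy visibly changes regime. Figures themselves are
not rendered; every figure-equivalent is a CSV table.

## Known limitations

- Both closed forms are exact only under binormality. When the covariate is
  normal in the *combined* sample, the within-group distributions are
  exponentially tilted normals, and the predictions acquire a small
  systematic offset that grows with the effect size (≈0.02 at σβ = 1) and
  with predicted c above ~0.8; under strongly skewed covariates
  (log-normal) the offset grows with the within-group skewness. This is the
  phenomenon the validation studies quantify, not an implementation error.
- At a null effect the empirical c of a *fitted* model is biased upward
  (the fit picks the favorable direction of its noise slope), by about
  0.5·E|AUC noise| ≈ 0.02 at n = 1,000 with 12% prevalence. The closed
  forms predict 0.5 there; the gap is a property of in-sample evaluation.
- Confidence intervals for predicted c are not provided; only point
  predictions.
- Multivariable fitting is out of scope: reduce a model to its linear
  predictor externally and feed that as x.
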