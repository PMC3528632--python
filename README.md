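# cstat

Predicting the concordance (c) statistic of a univariate logistic regression
model from the distribution of its covariate — before fitting any model —
and validating those predictions by Monte Carlo simulation.

## Who this is for

Biostatisticians and epidemiologists designing or interpreting risk models
with binary outcomes. The c-statistic (equivalently, the area under the ROC
curve) is the standard measure of a logistic model's discrimination. A
recurring puzzle is that the same covariate, with the same odds ratio, can
discriminate well in one population and poorly in another. This package
implements the closed forms that explain why: discrimination depends jointly
on the effect size *and* on the heterogeneity of the population.

## The model

Let X be a continuous covariate with mean μ_A and SD σ_A in subjects with
the outcome, and μ_U, σ_U in subjects without it. If X is normally
distributed within each group (the *binormality* assumption), the
c-statistic of the univariate logistic model is

    c = Φ( (μ_A − μ_U) / √(σ_A² + σ_U²) ) = Φ( d / √2 )

where Φ is the standard normal CDF and d = (μ_A − μ_U)/√((σ_A²+σ_U²)/2) is
the standardized difference (Cohen's effect size). When the two groups share
a common SD σ, the discriminant-analysis identity β = (μ_A − μ_U)/σ² reduces
this to

    c = Φ( σ·β / √2 )

with β the log-odds ratio per unit of X. So a covariate's discrimination is
the product of its effect (β) and the population's heterogeneity (σ): a
transportable odds ratio yields a *lower* c-statistic in a more homogeneous
population. Somers' rank correlation follows as D_xy = 2(c − 0.5). The same
formulas apply to a multivariable model through its linear predictor, whose
own regression coefficient is 1 by construction.

The package provides:

- `cstat.analytic` — the closed forms above (`auc_binormal`,
  `auc_equal_variance`, `standardized_difference`, `somers_d_from_c`,
  `auc_from_linear_predictor_moments`);
- `cstat.empirical` — subject-level estimation: Newton–Raphson logistic ML
  fitting with separation detection, the empirical c via the midrank
  Wilcoxon identity, group moments/skewness, and the two moment-based
  predictions from data;
- `cstat.simulation` — full-factorial Monte Carlo studies under normal,
  gamma, log-normal and uniform covariates (1,600 / 624 / 780 / 1,600
  scenarios; 500 replicates of 1,000 subjects each by default), fully
  seeded and resumable;
- `cstat.reporting` — per-scenario predicted-vs-empirical tables,
  skewness-vs-error tables, and banded accuracy summaries.

## Worked example

What c-statistic should a covariate with odds ratio 2 (β = ln 2 ≈ 0.693)
achieve in a population where it has SD 1?

```sh
$ cstat predict --sigma 1 --beta 0.6931
predicted c-statistic (equal_variance): 0.687967
standardized difference d:        0.693100
Somers' Dxy:                      0.375934
```

No model, by itself, can do better than c ≈ 0.69 with this covariate in
this population — even though its odds ratio is "significant". Doubling the
population SD would raise the ceiling to Φ(2·ln2/√2) ≈ 0.84.

Checking against data (1,000 subjects simulated under exactly that model):

```sh
$ cstat evaluate --input example.csv
n: 1000
n_affected: 494
c_empirical: 0.665044
c_formula1: 0.665054
c_formula2: 0.672292
d: 0.602873
skew_affected: -0.003436
skew_unaffected: -0.121958
```

The fitted model's empirical c (0.665) is matched by the moment-based
prediction `c_formula1` to four decimals, and by the slope-based
`c_formula2` to within 0.01; the realized standardized difference in this
sample (d = 0.603) is smaller than the design value, which is why both sit
slightly below the 0.688 planning figure.

A whole validation study, desk scale:

```sh
cstat simulate --study normal --thin 4 --reps 100 --seed 1 --out normal.csv
cstat report --results normal.csv --formula 2 --out normal
```

writes `normal_fig1.csv` (predicted vs empirical c per scenario),
`normal_fig2.csv` (skewness vs prediction error) and `normal_accuracy.csv`
(mean errors in the predicted-c bands (0.5, 0.8], (0.8, 0.9], (0.9, 1.0)).

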