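# Methods

This note documents the statistical model behind `nordicdiet`, the choices
made where the underlying design was open, and what the synthetic cohort
does and does not emulate.

## Diet-score construction

The healthy Nordic diet score is a within-cohort quartile index: the same
participant can receive different points depending on the roster they are
scored with. Two conventions had to be fixed because "quartiles" alone does
not determine an algorithm:

* **Percentile estimator.** Cut-points are the empirical 25th/50th/75th
  percentiles by the median-unbiased (type-8) quantile estimator.
  Assignment is half-open: value < Q1 → quartile 1, [Q1, Q2) → 2,
  [Q2, Q3) → 3, ≥ Q3 → 4. Tied values always share a quartile, which is
  what produces unequal quartile sizes on the narrow integer range of the
  total score — a feature of the design, not an artefact.
* **Degenerate component.** If every participant has the identical intake,
  all land in quartile 4 under the ≥ Q3 rule (3 points for a positive
  component, 0 for a negative one). This is deterministic and exercised in
  the tests; any constant component contributes a constant offset and no
  between-person variance.

Units: food groups in g/d, total fat as a percentage of energy (E%), the
fat-quality ratio PUFA/(SFA+TFA) from gram intakes, ethanol in g/d with
the 0/1 alcohol point switching at 20 g/d. Averaging the 4 diary days
happens upstream; the scorer consumes 4-day means only.

## HPL scale

Items arrive already dichotomized (1 = answer indicating a depressive
symptom); the total is their count and the clinical flag is total ≥ 5. Any
missing item makes the whole outcome missing — participants with missing
depressive-symptom data are excluded rather than prorated, the
conservative convention for a screening scale without published
psychometrics.

## Quade's rank ANCOVA

Procedure: (1) rank the outcome across all participants, mid-ranks for
ties; (2) rank each covariate column the same way (categorical covariates
enter as 0/1 indicators and are then ranked — a binary column's mid-ranks
are an affine transform of the column, so nothing is lost); (3) ordinary
least squares of outcome ranks on covariate ranks with intercept, pooling
all groups; (4) one-way ANOVA F on the residuals across groups, p from
F(k−1, N−k). The test is invariant to any strictly monotone transform of
the outcome, which is the point of using it on a skewed count.

Three presentation decisions, made here because the analysis convention
pairs them without stating formulas:

* **Adjusted means.** Point estimates and 95% CIs for quartile means come
  from the parallel parametric ANCOVA (OLS of the raw outcome on quartile
  indicators plus covariates, predictions at covariate sample means), while
  hypothesis tests are rank-based. The extreme-quartile contrast
  (lowest-adherence minus highest) carries a normal-theory CI and two-sided
  t p-value from the contrast standard error.
* **Trend test.** The outcome ranks are residualised on the covariate
  ranks, then regressed on the integer quartile index 1–4; the two-sided t
  p of the linear coefficient is reported as P for trend.
* **Reference levels.** Smoking enters as two indicators with "never" as
  reference; marital status as one indicator with "couple" as reference.
  Energy is carried in kJ/d throughout; since ranking is scale-invariant
  the rank tests are unaffected by the kJ/kcal choice.

Covariate imputation is the stated single-value rule: missing leisure-time
physical activity ← cohort mean of observed values; missing marital status
← modal category; any other covariate gap raises rather than being guessed
at. Complete-case sensitivity repeats the final model on rows that needed
no imputation.

## Quantile regression

`statsmodels` QuantReg (iteratively reweighted least squares on the check
loss, convergence tolerance 1e-6, max 5000 iterations) fits the
conditional 0.33 and 0.66 quantiles — exactly those levels, not 1/3 and
2/3. With a discrete outcome the IRLS weights can cycle within tolerance
of the optimum; the returned solution is accepted (a test verifies it
beats 1000 random coefficient perturbations on the check loss). CIs are
participant-resampling (pairs) bootstrap, percentile method, B = 1000 by
default and seeded; the slope p-value is a normal approximation on the
bootstrap SE. Bootstrap was chosen because no CI method is mandated by the
analysis convention this mirrors; numeric CI agreement with other software
is therefore not expected even on identical data.

A caution specific to count outcomes: conditional quantiles of an
integer-valued score move in steps, so fitted slopes at a given tau can
sit near zero for some samples even when the mean-based contrast is
clearly negative. The monotonicity of fitted quantiles (0.66 above 0.33 at
the covariate mean) is checked and crossings are treated as a warning
sign in diagnostics, not an error.

## Synthetic cohort

What it emulates: a baseline examination of n = 2603 men aged 42/48/54/60
(weights 0.10/0.26/0.36/0.28, mean ≈ 53 y), examinations 1984–1989;
log-normal 4-day mean component intakes correlated through one latent
diet-quality factor (loading 0.30 on the food groups and on total fat and
meat with reversed sign, 0.225 on the fat-quality inputs, −0.25 on
ethanol); a logit-normal total-fat E% so the percentage stays in [0, 100];
covariates with confounder structure (smoking, SES and marital status
correlated with the diet factor and contributing to the depression
liability); and 18 HPL items as conditionally independent Bernoulli draws
given a logistic liability.

Calibration: the ethanol location is set analytically so P(ethanol < 20
g/d) = 0.80, which pins the HNDS mean at 12.8 by construction (the eight
quartile components contribute 1.5 points each on average for continuous
intakes). The factor loadings, item intercept (−2.75 shared, plus fixed
per-item offsets spanning ±1.15), liability noise SD (1.10) and the
diet-factor loading on liability (−0.16) were fitted once by simulation to
the reference marginals (HNDS SD 4.0; HPL mean 1.9, SD 2.1; prevalence
10.9%; a fully adjusted extreme-quartile difference around a third of a
point) and then frozen. Randomness is organised as named substreams of a
single seed (seed × CRC32 of the stream name), so adding a variable never
perturbs another variable's draws and a given cohort is bit-reproducible.

What it does not emulate — and therefore what passing tests do not show
about real data: no individual diary days, foods or nutrient-database
conversion (only 4-day mean components); no abstainer point-mass in the
ethanol distribution; conditional independence of HPL items given a
one-dimensional liability (real symptom data have residual item
structure); missingness injected completely at random, whereas real
missingness is plausibly informative; and confounding limited to the three
modelled paths. Agreement of the pipeline's output with the calibration
targets validates the machinery and the direction/magnitude plausibility
of the analysis, not any substantive claim about diet and depression.

Missingness defaults mirror the reference bookkeeping: diet/HPL block
missingness at rate 79/2682 (exclusion path), LTPA at 8/2603 (mean
imputation), marital at 2/2603 (mode imputation).

## Descriptive tests

Per-quartile descriptives use linear regression on the quartile index for
continuous variables and, for categorical variables, the chi-squared test
plus a Mantel–Haenszel linear-by-linear association test (M² = (N−1)r²
with integer row/column scores, 1 df). Smoking rows are scored in the
ordinal order never < previous < current.

## Problem sizes and numerical tolerances in the test suite

Simulation-based checks run at sizes chosen to resolve their acceptance
bands comfortably on a single CPU: type-I error of the Quade test at 1000
replicates × n = 400 (band 0.05 ± 0.02); trend-test null at the same size;
quantile-slope recovery at n = 10 000 with B = 200 (within 3 bootstrap
SEs); bootstrap-CI coverage at 150 replicates × n = 300 × B = 100 (band
[0.90, 0.98], binomial MC error ≈ 1.8 points); marginal calibration at the
reference n = 2603. Exact checks (Quade vs ANOVA-on-ranks without
covariates, the 16-observation brute-force oracle, score conservation)
assert to machine precision (relative 1e-12). α = 0.05 two-sided is the
decision threshold throughout, with no multiple-testing correction,
matching the analysis convention.

## Known limitations

* The trend test and adjusted-mean CIs are asymptotic; no exact or
  permutation inference is provided.
* Quantile-regression output on integer outcomes is step-like (see above);
  bootstrap CIs can collapse onto the estimate on one side.
* The generator's confounder effects are linear on the liability logit;
  interactions and non-linear confounding are out of scope.
* BMI, CVD history and mental-illness history are generated and described
  in the quartile tables but deliberately not offered as adjustment
  covariates in Models 1–2.
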