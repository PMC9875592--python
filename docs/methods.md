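# Methods

## The scientific question

Retinopathy has a chronic-inflammatory component, and diet modulates
systemic inflammation. The dietary inflammatory index (DII) condenses a
24-hour recall into a single signed score: positive values indicate a
pro-inflammatory diet, negative values an anti-inflammatory one. This
package implements the full analysis chain linking the energy-adjusted
index (E-DII) to retinopathy prevalence in a cross-sectional cohort with
three glycemic strata (normal glucose, prediabetes, diabetes), and a
synthetic-cohort generator so every stage is testable without external
data.

## The index

For each food parameter *i* with intake *x\_i*, global reference mean
*μ\_i*, reference SD *σ\_i* and inflammatory effect weight *w\_i*:

    z_i   = (x_i − μ_i) / σ_i
    p_i   = 2·Φ(z_i) − 1                (centered percentile, in (−1, 1))
    DII   = Σ_i  p_i · w_i

Φ is the standard normal CDF; this is the percentile construction of the
index's source methodology, and it is swappable (`percentile="empirical"`
uses within-sample mid-ranks instead). The centered-percentile bound gives
|DII| ≤ Σ|w\_i| for any intakes — an exact invariant the tests assert.

**E-DII.** All intakes are first expressed per 1,000 kcal of total energy
(`energy_adjust`), then scored against a reference table whose means/SDs
are themselves densities (`mode="per_1000_kcal"`). Scaling a whole diet
proportionally (same composition, more calories) leaves E-DII unchanged.
Tables carry their mode and the engine refuses to mix modes. In density
mode the energy component is excluded by default (energy per 1,000 kcal is
the constant 1,000 and carries no information); `keep_energy=True`
retains it.

**Reference constants are data, not code.** Every scoring call takes the
table explicitly. A transcription of the published 28-parameter constants
is bundled for convenience (`load_default_table()`), but all tests run on
synthetic tables, so correctness never rests on the transcription.
Missing components are skipped and counted (`n_missing`) rather than
failing the participant — the index is routinely computed on a subset of
its 45 parameters. Zero intakes (e.g. alcohol = 0) are values, not
missing.

## Cohort definitions

Glycemic status is a disjunction with inclusive cutoffs, diabetes checked
first:

| status | criteria (any one) |
|---|---|
| diabetes | self-reported diagnosis; fasting glucose ≥ 126 mg/dL; HbA1c ≥ 6.5 %; OGTT ≥ 200 mg/dL |
| prediabetes | self-reported diagnosis; fasting ≥ 100; HbA1c ≥ 5.7; OGTT ≥ 140 |
| normal | no self-report, fasting glucose **and** HbA1c measured and below the prediabetes cutoffs |

Missing labs are "criterion not met", never disqualifying. A record with
no labs cannot be called normal and is *indeterminate*; the exclusion
cascade drops records in a fixed order (missing diet → missing outcome →
indeterminate status → pregnancy), tallying one reason per record.

Covariates: aged = age ≥ 65; overweight = BMI ≥ 25; income bands PIR < 1,
1–3, > 3 (both boundaries fall in the middle band, matching the strict
inequalities that define the outer bands); marital collapses
divorced/widowed/separated into "live separated". Missing values of
categorical covariates become an explicit `"Missing"` level so adjusted
models keep the full sample instead of dropping rows.

## Statistical battery

* **Descriptives** by outcome status: mean ± SD with pooled-variance
  t-tests; counts and column percentages with Pearson chi-square *without*
  continuity correction (this reproduces the published p = 0.034 for the
  sex row recomputed from printed counts; with correction it would be
  0.040). "Missing" rows are displayed but excluded from the test.
* **Logistic fits** are maximum likelihood (Newton, score-norm
  convergence; L-BFGS fallback on a singular Hessian step), 95% CIs from
  the normal approximation on the log-odds scale. Perfect separation and
  genuine non-convergence raise; a *quasi-separated nuisance cell* (a
  zero-event "Missing" level whose coefficient drifts to −∞ while the
  likelihood converges — the score norm still vanishes) is accepted and
  logged, because dropping those fits would silently change the model the
  analysis claims to run. Fits used only inside likelihood-ratio tests may
  skip the standard-error identifiability check (`require_se=False`).
* **Subgroups**: crude per-stratum E-DII fits; heterogeneity tested by a
  likelihood-ratio comparison of pooled models with and without all
  exposure × stratum product terms jointly (df = levels − 1 — a 3-level
  grouping gets one joint df = 2 test, not pairwise tests). Strata with
  < 10 events are flagged unstable but reported.
* **Tertiles** are cut at the 1/3 and 2/3 quantiles of the *total*
  analyzed sample; subgroup ladders reuse those cuts. Ties at a cut go to
  the lower tertile. The trend test is a Wald test on the ordinal tertile
  index (1/2/3), not on tertile medians; this is a documented, switchable
  choice.
* **Adjustment ladder**: Unadjusted → Model I (age, sex, race; age dropped
  when the subset is age-defined) → Model II (+ education, marital,
  income band, smoking, BMI band) → Model III (+ hypertension, high
  cholesterol). BMI enters as the banded covariate so its Missing level is
  retained.

## Threshold analysis

The two-piecewise logistic model replaces the single slope with hinge
terms `min(x−k, 0)` and `max(x−k, 0)`. The knot *k* is profiled over a
grid of candidate values — all unique exposure values between the 5th and
95th percentiles, thinned to at most 200 equally spaced points — and the
profile-likelihood maximiser is selected (ties go to the smallest knot;
boundary selections are flagged).

The piecewise-vs-linear likelihood-ratio p-value uses a chi-square
reference with **df = 2**: the alternative spends two extra parameters, the
second slope *and* the estimated changepoint. The naive df = 1 reference
(counting only the slope) ignores the maximisation over candidate knots
and is badly anti-conservative — measured type-I error ≈ 19–21% at the
study's stratum size versus 5.6% for df = 2; it remains available via
`lrt_df=1`. Even df = 2 is an approximation (the statistic's exact null
law is that of a supremum over correlated one-df statistics, so the
p-value distribution is not exactly uniform even when the 5% level
calibrates); `bootstrap=B` adds a parametric-bootstrap p-value simulated
under the fitted one-line model for exact calibration when it matters.

The smooth-curve diagnostic fits an unpenalised cubic B-spline logistic
GLM (default 4 df) of the outcome on the exposure plus covariates and
tabulates the partial-dependence log-odds (covariate columns held at their
sample means) with a delta-method band. It is a visual check on where the
slope changes, not an estimator of the knot. A constant outcome returns a
flat curve at the Haldane-corrected logit of the event rate.

## The synthetic world

The generator's defaults are the study's stated conditions: n = 2,403;
stratum mix 1089/823/491; within-stratum retinopathy prevalence 82/1089,
69/823, 154/491; per-unit E-DII odds ratio 1.14 in diabetes and 1.0
elsewhere. Lab values are drawn on the correct side of every cutoff, so
planted stratum labels are recovered *exactly* by the classifier — a
generator/classifier consistency invariant the tests assert.

Nutrient densities are lognormal with median at the reference mean
(positive support, right skew typical of diet data; dispersion σ = 0.5),
with 30% of their latent variance from a common diet-pattern factor that
loads positively on pro-inflammatory and negatively on anti-inflammatory
components. The correlation matters: with independent components the
cohort E-DII spread collapses to a fraction of what real diets show,
because component contributions cancel. The default world's E-DII SD is
≈ 1.7 with 5th–95th percentiles ≈ ±2.8, matching the scale the study
reports. `intake_distribution="normal"` instead draws intakes from the
normal reference distribution the z-score standardises against; only under
that option is the expected E-DII exactly zero (under the lognormal world
the mean is ≈ −0.1 to −0.3 because the percentile transform of a skewed
standardised intake has negative mean — real cohorts are likewise not
centred at zero).

Because densities are drawn per 1,000 kcal and multiplied by an
independent lognormal energy, the engine's energy adjustment recovers the
drawn densities exactly; the outcome is then Bernoulli from a logistic (or
two-segment hinge) model in the true E-DII. Every latent quantity —
stratum, true score, event probability — is returned in a ground-truth log.

What the generator does *not* emulate: survey weights and multistage
sampling, realistic joint demographics (age/BMI/income are independent
parametric draws), measurement error in recalls, and correlation between
diet and demographics. A green test therefore establishes the statistical
machinery (estimators, tests, calibration) on data with the study's
structure and scale — it does not reproduce the study's specific
covariate confounding.

`make_worked_fixture()` is a 48-row deterministic cohort built without a
RNG (scores follow a planted z-grid; one row sits exactly at the reference
means and scores 0; tertiles split 16/16/16; every stratum and every
Missing level appears), used for hand-checkable golden tests.

## Numerical contracts and edge cases

* Scores are reproducible to 1e-9 across platforms; the engine agrees with
  a brute-force erf-based oracle to 1e-12.
* Logistic coefficients agree with an independent Newton oracle to 1e-6;
  a saturated 2×2 fit equals the cross-product odds ratio.
* LRT statistics are clamped at 0 (nesting guarantees nonnegativity up to
  optimizer noise); nested log-likelihoods are monotone in the term set.
* Strict monotonicity of the percentile transform holds in float64 only
  for |z| ≲ 6; beyond that Φ saturates.
* `fit_piecewise` requires ≥ 50 observations and ≥ 10 events; degenerate
  exposures (no distinct values in the 5–95% window) raise.

## Known limitations

* The profiled-knot LRT p-value is approximate under any fixed-df
  chi-square reference; use the bootstrap option for inference that must
  be exactly calibrated.
* The bundled reference-constant transcription is approximate and
  illustrative; analyses intended for publication should supply their own
  vetted table file.
* Tertile cut points use the default linear-interpolation sample quantile;
  other quantile conventions shift cuts by at most one order statistic.
* The smooth curve is unpenalised with fixed df; it is a diagnostic, and
  its band does not account for df selection.
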