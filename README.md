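# dii-retinopathy

Dietary-inflammation scoring and retinopathy association analysis for
NHANES-like cross-sectional cohorts.

Diets modulate systemic inflammation, and retinopathy — diabetic
retinopathy in particular — is in part an inflammatory disease. The
dietary inflammatory index (DII) turns a 24-hour dietary recall into one
signed score; its energy-adjusted form (E-DII) scores nutrient densities
per 1,000 kcal so that total consumption does not confound the comparison.
This package provides, as a tested library plus narrative analysis
scripts:

* the DII/E-DII engine: `z = (x − μ)/σ`, centered percentile
  `2·Φ(z) − 1`, weighted sum over food parameters — with reference
  constants supplied as data (JSON/YAML tables carrying means, SDs,
  effect scores and a raw vs per-1,000 kcal mode flag);
* glycemic-status classification (normal / prediabetes / diabetes from
  self-report, fasting glucose, HbA1c, OGTT with inclusive cutoffs),
  exclusion cascade, and covariate encoding with explicit "Missing"
  levels;
* the association battery: descriptive tables with t/chi-square tests,
  crude subgroup logistic fits with joint product-term interaction LRTs,
  total-sample tertiles with Wald trend tests under a four-model
  adjustment ladder;
* threshold-effect analysis: two-piecewise logistic regression with a
  profile-likelihood inflection-point search, piecewise-vs-linear LRT,
  and a B-spline smooth-curve diagnostic;
* a synthetic-cohort generator with planted ground truth (stratum labels,
  true scores, true effect sizes) emulating the study design: n = 2,403,
  strata 1089/823/491, retinopathy prevalence 7.5%/8.4%/31.4% by stratum,
  and a per-unit E-DII odds ratio of 1.14 confined to the diabetes
  stratum.

It is aimed at nutritional-epidemiology analysts who want this analysis
chain reproducible end to end, and at methodologists who want the
machinery (tertile trends, interaction LRTs, segmented logistic models)
with honest calibration properties. See `docs/methods.md` for the models,
assumptions and design choices.

## Worked example

```python
from dii_retinopathy.simulate import SimulationConfig, simulate_cohort, study_scale_table
from dii_retinopathy.cohort import apply_exclusions, encode_covariates
from dii_retinopathy.association import subgroup_analysis, model_ladder

table = study_scale_table()                      # density-mode reference table
cohort, truth = simulate_cohort(SimulationConfig(n=2403, seed=1), table)
kept, tally = apply_exclusions(cohort)
enc = encode_covariates(kept)

sub = subgroup_analysis(enc, ["glycemic_status", "age_group"])
dm = sub.rows.query("stratum == 'diabetes'").iloc[0]
print(f"diabetes: OR {dm.OR:.3f} ({dm.ci_low:.3f}, {dm.ci_high:.3f}), "
      f"interaction p {sub.interaction_p['glycemic_status']:.4f}")

lad = model_ladder(enc, subset=enc.glycemic_status == "diabetes")
print(lad.frame()[["per_unit_OR", "T3_OR", "p_trend"]].round(3))
```

Output:

```
diabetes: OR 1.160 (1.039, 1.295), interaction p 0.0009
            per_unit_OR  T3_OR  p_trend
model
unadjusted        1.160  1.975    0.008
model_i           1.162  1.992    0.008
model_ii          1.175  1.993    0.010
model_iii         1.169  1.949    0.013
```

The per-unit odds ratio in the diabetes stratum recovers the planted 1.14
(within sampling noise at n = 2,403), the diabetic-status interaction test
rejects — the effect is confined to that stratum — and the highest tertile
carries roughly twice the odds of the lowest, with a significant trend
that survives adjustment.

## Analysis scripts

Numbered drivers under `analysis/` run the pipeline as a narrative, each
writing its tables under `results/`:

```bash
python analysis/01_simulate_cohort.py      # cohort CSV + ground-truth JSON
python analysis/02_descriptives.py         # baseline table with tests
python analysis/03_subgroup_analysis.py    # per-stratum ORs + interaction p
python analysis/04_tertile_models.py       # tertile/continuous adjustment ladder
python analysis/05_threshold_effect.py     # inflection search + smooth curve
python analysis/06_piecewise_recovery.py   # validates knot recovery on planted data
```

The default world is linear in E-DII, so `05` correctly finds no
threshold; `06` plants an inflection at −0.9 with a steep lower and flat
upper segment and shows the profile search recovering it (knot −0.77,
segment ORs 3.22 vs planted 3.32 and 0.94 vs 1.00 at n = 8,000).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at the given seed — simulation,
scoring, classification, descriptives, subgroup interaction models, the
tertile ladder for the diabetes and aged subsets, the threshold search and
the smooth curve — writing each stage's table under `results/` and the
target-value JSON to `--out`.

## Real data

The cohort readers accept CSV or SAS transport (XPT) files
(`cohort.read_nhanes_xpt` merges on the participant id); batch scoring
reads a wide nutrient CSV and writes DII/E-DII per participant
(`scoring.score_csv`). The bundled reference-constant transcription is
illustrative — supply a vetted table for substantive analyses.
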