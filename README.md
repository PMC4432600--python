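# circannual

Detection and classification of annual (seasonal) rhythms in molecular
measurements: log2 expression matrices from longitudinal cohorts and
full-blood-count tables.

The package fits per-feature **cosinor models** — linear (mixed) models with
`sin(2πt)` and `cos(2πt)` terms for a one-year period, where `t` is the
calendar day of sampling divided by the number of days in that year — and
provides:

- **`circannual.cosinor`** — per-feature seasonal and null fits (OLS, or
  maximum-likelihood random-intercept models via a fast profiled-likelihood
  fitter cross-checked against `statsmodels`), the season test
  (chi-square(2) LRT for mixed models, exact F test otherwise), and
  alternative models driven by weekly-mean temperature/sunlight exposures.
- **`circannual.classify`** — Bonferroni gating, winter/summer calls (the
  fitted seasonal curve must be strictly positive on every day of
  December–February and strictly negative on every day of June–August of a
  365-day calendar, or vice versa), and the 15 Jan vs 15 Jul fold change.
- **`circannual.crosscohort`** — replication across cohorts via per-cohort
  BIC preference of the seasonal model, union candidate gates, intersection
  across cohort groups, Fisher's combined p-values, and hemisphere-aware
  phase-concordance flags.
- **`circannual.fbc`** — blood-count seasonality: a month-based cosinor
  F-test and a Fourier-harmonics model with sex and an age spline.
- **`circannual.auxiliary`** — PCA-based sex inference from Y-linked marker
  genes and the infection-effect ANOVA on PC1 scores.
- **`circannual.simulate`** — synthetic cohorts, climate series, and
  blood-count tables with planted seasonal structure and truth tables, so
  the whole pipeline is testable without any external data.
- **`circannual.pipeline` / CLI** — simulate/load → fit → classify →
  cross-cohort orchestration from a single YAML config and seed.

## CLI

Every subcommand is under the `circannual` entry point:

```bash
circannual simulate --seed 1 --out data/ --name demo
circannual fit --matrix data/demo.expression.tsv --samples data/demo.samples.csv \
    --covariates age,sex --random-intercepts subject_id --out demo.results.tsv
circannual classify --results demo.results.tsv --out demo.classified.tsv
circannual common --results a a.results.tsv --results b b.results.tsv --out common.tsv
circannual fbc --table fbc.csv --model month_cosinor --out fbc.tsv
circannual sexcall --matrix markers.tsv --out calls.csv
circannual run --config pipeline.yaml --seed 1
circannual report --run-dir circannual_out/
```

`circannual run` takes a YAML config like:

```yaml
seed: 1
output_dir: out
gates: {alpha: 0.05, mean_expr_min: 6}
pairing: {groups: [[north, south]], gate_m: 33297}
cohorts:
  - name: north
    model: {fixed_covariates: [age, sex], random_intercepts: [subject_id]}
    simulate: {n_subjects: 100, visits_per_subject: 3, n_features: 500,
               frac_seasonal: 0.3, acrophase_mode: winter}
  - name: south
    hemisphere: south
    model: {fixed_covariates: [age, sex], random_intercepts: [subject_id]}
    simulate: {n_subjects: 100, visits_per_subject: 3, n_features: 500,
               frac_seasonal: 0.3, acrophase_mode: winter}
```

Exit codes: 0 success, 1 validation/config error, 2 numerical failure.

## File formats

Expression matrices are TSV (first column `feature_id`, one column per
sample); sample metadata, climate series and blood-count tables are CSV with
ISO 8601 dates; per-feature results are TSV with columns
`feature_id, b_hat, c_hat, loglik_s, loglik_0, bic_s, bic_0, statistic, df,
p_season, mean_expr, n_obs, converged` (plus gating/label columns after
classification).

## Notes

- Mixed models are always fitted by maximum likelihood (not REML) so that
  likelihood-ratio comparisons of the fixed seasonal terms and BIC are
  coherent.
- BIC is `k·ln(n_obs) − 2·loglik` with `k` counting fixed coefficients and
  all variance parameters.
- The weekly exposure window is the 7 days strictly before the bleed date.
- The winter/summer day windows use a fixed 365-day calendar (February = 28
  days); a fitted value of exactly zero on any window day leaves a feature
  unclassified.
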