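# Methods

## Causal model and estimands

The package estimates the effect of an exposure X (a health risk factor or
genetic liability to a health condition) on an outcome Y using a polygenic
risk score Z as a single instrumental variable, under an additive
structural mean model. For a continuous outcome the estimand is a mean
difference per unit of exposure; for a binary outcome both the IV fit and
the ordinary comparator are linear probability models, so the estimand is a
risk difference (an absolute change in proportion). Linear probability
fitting deliberately accepts predictions outside [0, 1]: it is the price of
having the instrumented and ordinary estimates on the same additive scale,
and effect estimates for rare binary exposures can be large on that scale.

Identification requires the three IV assumptions: the score predicts the
exposure (checked by the first-stage F), is independent of
exposure–outcome confounders (plausible by mendelian inheritance, violated
by population structure — hence principal-component adjustment), and
affects the outcome only through the exposure (no horizontal pleiotropy —
probed by the sensitivity suite, never guaranteed).

## Two-stage least squares (`mrsoc.onesample`)

Covariates (age, sex, centre indicators, principal components) enter both
stages as exogenous regressors — the standard 2SLS formulation. The
estimator is computed by explicit projection: the exposure is regressed on
[1, C, Z], and the outcome on [1, C, X̂]. The sandwich covariance uses the
fitted-exposure design as bread and residuals formed with the **observed**
exposure as meat — the correct IV residual, since using X̂-residuals would
understate the error variance. Small-sample scaling is HC1 (n/(n−k)),
matching common econometric defaults; asymptotically irrelevant.
Confidence intervals use the normal 97.5% quantile: analysed n is large by
design, so t refinements would change nothing visible.

The weak-instrument diagnostic is the robust Wald F of the instrument's
first-stage coefficient; with one instrument this equals the
Kleibergen–Paap rk Wald F. The endogeneity test is the control-function
Durbin–Wu–Hausman form: the first-stage residual is added to an OLS of Y on
[1, C, X], and its coefficient gets a robust Wald test (χ², 1 df). When X
lies in the span of the instruments and covariates (e.g. X ≡ Z) the
residual is identically zero and the test is reported as undefined by an
explicit error rather than a spurious statistic.

Collinear covariate columns are dropped (QR with column pivoting) with a
warning rather than an error, since centre indicator blocks easily produce
exact collinearity. Missing data are handled complete-case per
exposure–outcome pair; the reported n always counts the rows actually
used.

## Summary-statistic estimators (`mrsoc.summarymr`)

The GWAS stage regresses each variant's dosage effect on the trait with
covariates, computed by Frisch–Waugh residualization so thousands of
variants vectorize; classical (homoskedastic) SEs with df = n − p − 1, the
convention of standard GWAS pipelines. Binary traits use the same linear
model, keeping per-allele effects on the risk-difference scale.

The estimator suite uses the standard published forms, selected as
follows where the literature offers variants:

* **Wald ratios**: ratio = β_out/β_exp, SE = |se_out/β_exp| — first-order
  delta method ignoring exposure-side uncertainty (the NOME
  approximation), standard for instruments selected at genome-wide
  significance.
* **IVW**: weighted regression through the origin with weights 1/se_out²;
  fixed-effect SE (1/√Σw·β_exp²), normal p. Cochran's Q is the weighted
  residual sum of squares with k−1 df.
* **MR-Egger**: the same weighted regression with an intercept, after
  re-orienting variants so every β_exp ≥ 0 (required for the intercept to
  mean average directional pleiotropy; exact zeros excluded). SEs are
  scaled by max(1, σ̂) — inflated under overdispersion, never deflated —
  and inference uses t with k−2 df. This is the convention of the widely
  used summary-MR implementations.
* **Weighted median**: ratios ordered, inverse-variance weights
  standardized and cumulated, linear interpolation at the 50% point.
* **Modes**: the mode of a normal-kernel density over the ratios, with
  bandwidth = bandwidth_factor × 0.9·min(SD, MAD_normal)·k^(−1/5)
  (bandwidth_factor default 1.0, the common choice in mode-based
  estimation); the weighted variant weights each ratio by inverse
  variance. The grid argmax is refined by bounded scalar minimisation. If
  every ratio is identical the common value is returned directly.

Median and mode SEs come from a seeded parametric bootstrap (default 1000
resamples of both association vectors from their normal sampling
distributions; the seed is a required argument so confidence intervals are
reproducible). All suite estimators require ≥3 variants (IVW ≥2), and an
exactly-zero bootstrap SE is floored at 1e-12 so downstream containers can
still carry the estimate.

## Split-sample design (`mrsoc.splitsample`)

The cohort is partitioned by individual id — ids sorted, then shuffled with
a seeded generator — so the split is reproducible and independent of row
order. Each half's covariate-adjusted GWAS of the exposure selects variants
at the genome-wide threshold (default 5 × 10⁻⁸); the selected effect sizes
become score weights for the *other* half, guaranteeing no individual
contributes to both weight discovery and estimation. Winner's-curse
inflation of the discovery betas does not bias the 2SLS estimate — weights
only shape the instrument; instrument strength is re-estimated in the
evaluation half. The two half-estimates are combined by fixed-effect
inverse-variance meta-analysis; a half with no selected variants is
reported "not estimable" and no combined estimate is produced when both
halves are empty (the expected behaviour for traits with no detectable
common-variant signal). The per-half GWAS is plain linear regression, not
a mixed model: simulated individuals are unrelated. On real data,
relatedness and LD clumping would both need handling upstream.

## Synthetic cohorts (`mrsoc.simulate`)

What the generator emulates: independent biallelic SNPs in Hardy–Weinberg
proportions with allele frequencies uniform on a configurable range
(default 0.05–0.5); a shared standard-normal confounder loading on both
exposure and outcome; exposures and outcomes that are linear in genotypes,
confounder and Gaussian noise, optionally dichotomized; nuisance covariates
(age uniform on 39–72, sex at a 0.46 male fraction, a handful of centres,
standard-normal PCs) with small nonzero effects so covariate adjustment is
exercised. Per-SNP exposure effects are drawn N(0, snp_effect_scale²)
(default scale 0.1), giving a GWAS-like spread of instrument strengths; no
external PRS R² is targeted, since instrument effect-size distributions
are exposure-specific and unknown here. Horizontal pleiotropy is injected
either balanced (zero-mean direct SNP→outcome effects) or directional (a
constant shift on every SNP).

What it does not emulate: linkage disequilibrium (instruments in real
analyses are clumped, so independence is the intended regime), population
structure, assortative mating, dynastic effects, genotyping error or
imputation noise, and selection into the cohort. Passing recovery tests
therefore validate the estimators under the model's own assumptions; they
say nothing about robustness to these real-data features.

Binary traits are thresholded at the *empirical* (1 − prevalence) quantile
of the liability, so realized prevalence is controlled exactly up to ties;
with a binary outcome the coefficient recovered on the liability scale is
attenuated relative to the latent effect, and the honest comparison target
is a brute-force risk difference simulated under both exposure states
rather than the liability coefficient. All draws come from one PCG64
stream in a fixed documented order, so a config is byte-identical across
runs; the generator algorithm name is carried in the config metadata.

A second, lighter generator (`simulate_summary_stats`) draws per-variant
summary statistics directly (true exposure betas uniform, Gaussian
estimation noise at stated SEs). It is used to calibrate the summary-level
estimators — Egger type-I error and intercept recovery — where cohort-level
simulation would conflate one-sample biases with the property under test.

## Phenotype coding (`mrsoc.phenocode`)

Weekly alcohol units use the fixed nominal per-drink lookup (red wine and
white wine/champagne 1.75; beer/cider 2; spirits 1; fortified wine 1.2;
other 1); the printed nominal values are authoritative even where a
volume × ABV calculation would give slightly different numbers (a pint at
3.5% is 1.99 units; 2 is shipped). Exclusions: former drinkers, >200
units/week, and non-never-drinkers with no intake answers. Banded income
maps to band mid-points (15 000, 24 500, 41 500, 76 000, 150 000 for the
open top band). Dichotomization rules are registered by name, always map
missing to missing, and include: income ≥ 52 000; most-deprived third of
the deprivation index (empirical tertile of the supplied vector);
weekly-or-more frequency; "extremely/very/moderately happy" versus not;
degree versus lower qualifications. Custom rules can be registered.

A deprivation effect is expressed as a percentage of "one decile" of the
index. Decile width is a declared convention — the mean gap between
adjacent empirical decile boundaries D1..D9, i.e. (P90 − P10)/8 — because
no standard definition exists; the percentile bounds are configurable in
`decile_width`.

## Reporting (`mrsoc.report`)

The multiple-testing threshold is Bonferroni across outcomes only
(alpha/n_outcomes; 0.05/19 ≈ 0.0026), with strict `<` comparison. Grid
cells are starred iff p is strictly below the threshold and signed by the
effect direction; an exactly-zero effect gets sign "0", is never starred,
and is flagged for review. Risk differences are displayed ×100 as absolute
percentage changes. Exact numbers always live in the TSV outputs; plots
are presentation only.

## Problem sizes in the test suite

The simulation studies use n = 20 000 individuals × 30 SNPs (recovery and
split-sample, 100–200 replicates), n = 5 000 × 30 (endogeneity
calibration, 500 replicates) and 30-variant summary panels (Egger
calibration, 200–500 replicates) — large enough for asymptotic behaviour
to hold while keeping the full suite to a couple of minutes on one core.
The acceptance script reruns the pipeline once at the main-analysis size
plus a 100-replicate coverage study.

## Known limitations

* Single-instrument 2SLS only; no multi-instrument or LIML/GMM variants,
  no clustered SEs, no logistic/probit IV.
* The sensitivity suite assumes two-sample-style independence between the
  numerator and denominator errors that one-sample in-sample GWAS does not
  exactly satisfy; at the simulated instrument strengths the discrepancy
  is negligible (tested), but the suite should not be trusted for weak
  instruments in one sample.
* No LD, relatedness, or population-structure handling anywhere; real-data
  use requires upstream QC, clumping and ancestry control.
* The fixed-effect meta-analysis assumes both halves estimate the same
  parameter; heterogeneity between halves is not tested.
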