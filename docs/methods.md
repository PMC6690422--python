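# Methods

## The problem

Questionnaire-based breast cancer risk models (Tyrer-Cuzick and its
relatives) summarize hormonal, reproductive and family-history factors into
an absolute 10-year risk, but omit mammographic density, one of the
strongest population-level risk factors. Density cannot simply be appended
to such a model because percent density falls with age and BMI, both of
which the model already uses. `densrisk` implements the standard remedy:
reduce density to the part not explained by age and BMI (the *density
residual*), estimate its effect in a case-control logistic model, and fold
the resulting relative risk into the absolute 10-year risk.

The package works with two density measures used in clinical practice:
automated volumetric percent density (VPD, analysed as its natural log) and
the four-grade clinical reading (fatty / scattered / heterogeneous / dense,
analysed as the integers 1–4), plus absolute fibroglandular and fat volumes
(log scale) as secondary measures.

## Density residualization

Expected density is an additive spline surface fitted on controls only:

    E[t(density)] = beta_0 + f_age(age) + f_bmi(bmi)

where `t` is log for volumetric measures and identity for the integer
grade, and `f_age`, `f_bmi` are cubic B-spline expansions. Each covariate
contributes `df = 4` basis columns (one interior knot at the training
median; `df` configurable, degree `min(3, df)`); the first basis column is
dropped so the explicit intercept leaves the spanned space — which contains
all linear functions — unchanged. The fit is ordinary least squares; a
ridge penalty on the non-constant coefficients with the weight chosen by
generalized cross-validation is available (`SplineSpec(penalty="gcv")`) but
off by default at these sample sizes. This is a deliberately plain
stand-in for a penalized GAM: with two smooth one-dimensional effects and
thousands of controls, the fitted surfaces are indistinguishable for this
purpose.

The residual is `t(observed) − fitted(age, bmi)`. Predictions outside the
training age/BMI range clamp to the boundary (spline extrapolation is not
meaningful) with a warning; integer-grade predictions clamp to [1, 4].
Control residual quartiles are stored with the model using linear
interpolation of order statistics (the "type 7" convention) for exact
reproducibility.

## Case-control modelling

Case status is modelled by maximum-likelihood logistic regression (Newton
iterations, tolerance 1e-10; non-convergence, rank deficiency and
separation raise errors naming the offending term). The standing
adjustment set is: 5-year age-group indicators, region, insurance,
financial screening, education, ethnicity (categoricals as drop-first
dummies with missing values as an explicit `Unknown` level), BMI, and the
natural log of the baseline 10-year risk.

The effect size reported is the **interquartile odds ratio**
`IQ-OR = exp(coef · (q75 − q25))` with a Wald CI on the log-odds scale,
where the quartiles are the stored control residual quartiles. Added
predictive information is the 1-df likelihood-ratio chi-square of the
residual term. Supporting analyses:

* **Quantile-group ORs** — controls are split into `k` groups of
  equal-as-possible size (boundaries at `round(i·n/k)` in the sorted
  control residuals, cut values at midpoints of adjacent order statistics;
  2,243 controls in quintiles yield 449/448/449/448/449) and indicator
  coded against the least-dense group.
* **Interaction tests** — LR test of a residual x modifier product term
  (modifier main effect always present).
* **Nonlinearity check** — LR test of a df-4 spline in the residual versus
  the linear term (3 extra df).
* **Bootstrap comparison of two measures** — the statistic is the
  difference in LR chi-square; participants are resampled within case and
  control strata; the two-sided p compares the observed difference to the
  bootstrap distribution centred at it. The bootstrap construction is this
  package's definition (the underlying study describes only "a
  nonparametric bootstrap test").
* **Calibration coefficient** — slope of case status on log baseline risk,
  x100: 100% means the model's relative risks are fully expressed in the
  case-control contrast. Implemented as the standard case-control
  relative-risk calibration; other readings of "regression of predicted on
  observed risk" are possible.

**Matched concordance (mC).** The predictor is first residualized on the
adjustment factors by OLS; mC is then the probability that a case outranks
a control within the same 5-year age group (all within-stratum
case-control pairs; ties count 1/2; computed via midrank sums). The CI is
a stratified nonparametric bootstrap over participants (1,000 replicates,
seeded). The all-pairs-within-stratum pairing is this package's stated
choice.

## Agreement statistics

Weighted kappa uses disagreement weights `|i−j|/(k−1)` (linear, default)
or squared (quadratic), expectation from margin products, CI by seeded
multinomial bootstrap. Linear weighting is the default because it
reproduces the published overall kappa (0.64) on the shipped grade
cross-tabulation; quadratic gives 0.78 there. Crude odds ratios use
`ad/bc` with the Woolf CI; a zero cell triggers the 0.5 continuity
correction with a warning.

## Risk combination

The fitted residual coefficient gives each woman a relative risk
`rr = exp(beta · residual) / normalizer`, with the normalizer the control
mean of `exp(beta · residual)` so that the mean rr over controls is one
and adding density leaves the population-average risk essentially
unchanged. Combination is on the hazard scale,
`combined = 1 − (1 − p)^rr`, a valid probability for any rr and within a
fraction of a percent of `p · rr` in the screening risk range. Strata use
the clinical thresholds: lower risk `< 2%`, increased risk `>= 8%` 10-year
risk (the boundary at exactly 8% counts as increased, at exactly 2% as
average, keeping strata exhaustive). Risks are percentages everywhere in
files and tables; only the combination arithmetic converts to fractions.

## The synthetic-data generator

No participant data are distributed with the study this pipeline models,
so the generator reproduces the *statistical structure* the analysis
relies on, with defaults frozen to the study-scale conditions:

| quantity | default | rationale |
|---|---|---|
| n controls / cases | 2,243 / 474 | study sample sizes |
| age | truncated normal (58, 9.5) on 40–79 | control median 59, IQR 53–66 |
| BMI | log-normal, median 25.6, log-SD 0.21 | control median 25.6, IQR 22.6–29.9 |
| baseline 10-year risk | log-normal, median 3.17%, log-SD from IQR 2.35–4.56 | control distribution |
| log VPD | intercept ln 6.5 at (58 y, 27 kg/m²); slopes −0.0335/y, −0.118 per kg/m²; SD 0.85 | Spearman ϱ(vpd, age) ≈ −0.25, ϱ(vpd, BMI) ≈ −0.56 |
| clinical grade | latent log VPD + reader noise (SD 0.65) cut at ln(4.6, 7.6, 15.4) | linear-weighted kappa ≈ 0.64–0.65 vs volumetric grades |
| density effect | beta_vpd = ln 1.40 / (1.349 · 0.85) | VPD IQ-OR 1.40 |
| demographic effects | independent multiplicative odds (ORs 1.90, 1.78/2.05, 3.16, 1.93, 2.00) at control prevalences | published crude ORs |
| baseline-risk effect | slope 1.0 on log risk | calibration ≈ 100% |

Mechanics: a large pool (~case target / 5% prevalence) is drawn from the
control-population distributions; each member's case probability follows
the logistic model above (intercept solved by bisection for 5% pool
prevalence); cases are sampled from the pool's cases and controls from its
non-cases within 5-year age bins matching the case age distribution
(largest-remainder allocation), emulating frequency matching. Fat and
fibroglandular volumes are derived from a BMI-linked total breast volume so
`vpd = 100·fibro/(fibro+fat)` holds exactly. One master seed feeds named
substreams per variable (keyed by a hash of the name), so adding a variable
does not perturb existing streams and identical seeds give byte-identical
tables.

Two emulation compromises are deliberate. First, the published control
residual IQR (−0.7, 0.7 on the log scale) and the published volumetric
grade margins are mutually inconsistent under any single-population model
(the first implies more residual spread than the marginal spread the second
allows); the generator prioritizes the residual spread (SD 0.85, IQR width
≈ 1.15), so its grade margins are flatter than the published ones. Second,
covariates act as independent odds factors and the baseline risk is drawn
independently of age and the questionnaire factors; real data have
confounding among these, so passing recovery tests here shows correctness
of the estimators under the assumed structure, not robustness to
misspecification. The generator also makes no attempt at DICOM-level
realism: density is a scalar per woman.

## Problem sizes and numerical conventions

Parameter-recovery runs use 16,000 controls / 4,000 cases; null-calibration
runs use 200 replicates of the study-scale 2,717; bootstrap defaults are
1,000 (mC), 2,000 (kappa) and 199–499 (model comparison) replicates —
chosen so every number in the reports is reproduced by the shipped scripts
in a few minutes on a laptop. Convergence tolerances: logistic Newton
tol 1e-10; OLS via LAPACK least squares; quantiles type 7; bootstrap p as
`(1 + #{extreme}) / (B + 1)`.

## Known limitations

* The expected-density surface is unpenalized at default settings; with
  very small control sets (n below ~10x the basis dimension) it warns and
  may overfit — use the GCV ridge there.
* The bootstrap comparison and the calibration coefficient are
  package-stated definitions of under-described procedures; alternative
  constructions could shift p-values.
* mC's bootstrap CI resamples within (stratum, status) cells and is
  percentile-based; no BCa correction.
* The generator's grade margins and the secondary-volume correlations are
  emergent, not calibrated targets; only the quantities in the table above
  are calibrated.
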