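# densrisk

Adding mammographic density to questionnaire-based breast cancer risk
assessment: a tested, reusable implementation of the case-control analysis
chain, exercised end-to-end on a synthetic data generator.

Questionnaire models such as Tyrer-Cuzick give a woman an absolute 10-year
breast cancer risk from classical factors, but leave out mammographic
density — which is itself strongly driven by age and BMI, two inputs the
model already uses. The analysis implemented here:

1. **residualizes** density on age and BMI among controls, fitting an
   additive spline surface to log volumetric percent density (VPD) or to
   the integer-coded clinical grade (1 = fatty ... 4 = dense), so the
   density *residual* r = t(observed) − E[t | age, BMI] carries only the
   information the questionnaire model does not;
2. estimates the residual's effect by adjusted logistic regression and
   reports the **interquartile odds ratio**, IQ-OR = exp(β(q₇₅ − q₂₅)),
   for a move across the control residual interquartile range, with its
   likelihood-ratio χ², quantile-group ORs, interaction and linearity
   checks, a bootstrap comparison of two density measures, a matched
   concordance index (mC), and the calibration slope of the baseline risk;
3. quantifies **agreement** between the clinical and volumetric four-grade
   readings (linear-weighted kappa) and crude demography odds ratios with
   Woolf CIs;
4. **combines** the fitted density relative risk
   rr = exp(β·r)/E_controls[exp(β·r)] with the baseline 10-year risk p on
   the hazard scale, combined = 1 − (1 − p)^rr, and tabulates the clinical
   strata (lower risk < 2%, increased risk ≥ 8%).

Because no participant-level data are public, `densrisk` ships a
synthetic case-control generator whose defaults reproduce the study-scale
conditions (2,243 controls / 474 cases, control 10-year risk median 3.17%,
density-age/BMI Spearman correlations ≈ −0.25/−0.56, grade agreement
κ ≈ 0.64, VPD IQ-OR 1.40), plus the published grade cross-tabulation and
demography 2x2 counts as packaged reference tables. See `docs/methods.md`
for the model and generator details.

## Worked example

```python
import densrisk as dr

pop = dr.generate_population(dr.GeneratorConfig(), seed=20)
ctrl = pop[pop.status == "control"]

model = dr.fit_expected_density(ctrl, "vpd_log")   # spline surface on controls
pop["r"] = dr.residualize_table(model, pop)        # density residuals
q25, q75 = dr.residual_iqr(model)                  # (-0.58, +0.56)

fit = dr.fit_adjusted_logistic(pop, "r")           # adjusted logistic model
res = dr.iq_or(fit, q25, q75)
chi2, df, p = dr.lr_test(fit, dr.fit_adjusted_logistic(pop, None))
print(f"IQ-OR {res.odds_ratio:.2f} ({res.ci[0]:.2f}-{res.ci[1]:.2f}), "
      f"LR-chi2 {chi2:.1f}")
```

prints

```
IQ-OR 1.50 (1.29-1.74), LR-chi2 28.4
```

— the generated density effect (true IQ-OR 1.40) recovered on one
study-scale draw: a woman at the 75th percentile of age/BMI-adjusted
density has about 1.5 times the odds of breast cancer of a woman at the
25th percentile, after adjusting for age group, demographics, BMI and the
log baseline risk; the residual adds 28.4 likelihood-ratio χ² (1 df) of
information.

The numbered scripts under `analysis/` run the full narrative in order —
`01` simulate, `02` grade agreement + crude ORs from the packaged counts,
`03` residual surfaces, `04` risk models (IQ-ORs, mC, calibration,
sensitivity tests), `05` risk combination and strata — each printing what
it found and writing tables under `results/`.

The same chain is scriptable from the shell:

```
densrisk simulate --seed 7 --out pop.csv
densrisk fit-expected --in pop.csv --measure vpd_log --out model.json
densrisk assess --in pop.csv --model model.json --concordance --out report.json
densrisk combine --in pop.csv --model model.json --beta-from report.json --out risks.csv
densrisk pipeline --seed 7 --out-dir results
```

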