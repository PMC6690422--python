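"""Adjusted logistic models of case status on the density residuals.

For each density measure: the continuous interquartile odds ratio with its
likelihood-ratio chi-square, quintile-group odds ratios, matched
concordance, and sensitivity checks (linearity of the residual effect,
interactions with BMI and log baseline risk), plus the calibration slope
of the baseline 10-year risk and a bootstrap comparison of the two primary
density measures.
"""

import json
import sys
from pathlib import Path

import pandas as pd

import densrisk as dr

RESULTS = Path(__file__).resolve().parents[1] / "results"
MEASURES = ("vpd_log", "birads_integer", "fibro_log", "fat_log")


def main() -> None:
    path = RESULTS / "population_with_residuals.csv"
    if not path.exists():
        print("run 03_fit_density_residuals.py first", file=sys.stderr)
        return 1
    pop = pd.read_csv(path)
    out = {}
    for measure in MEASURES:
        col = f"{measure}_residual"
        model = dr.ExpectedDensityModel.from_json(
            (RESULTS / f"expected_density_{measure}.json").read_text())
        q25, q75 = dr.residual_iqr(model)
        fit = dr.fit_adjusted_logistic(pop, col)
        null = dr.fit_adjusted_logistic(pop, None)
        chi2, dof, p = dr.lr_test(fit, null)
        res = dr.iq_or(fit, q25, q75)
        quant = dr.quantile_group_ors(pop, col, 5)
        quant.to_csv(RESULTS / f"quantile_ors_{measure}.tsv", sep="\t",
                     index=False)
        pop[f"{col}_adj"] = dr.adjust_predictor(pop, col,
                                                dr.DEFAULT_ADJUSTMENTS)
        mc = dr.matched_concordance(pop, f"{col}_adj", n_boot=1000, seed=2)
        nl = dr.nonlinearity_check(pop, col)
        ints = {m: dr.interaction_test(pop, col, m)[2]
                for m in ("bmi", "log_tc10")}
        out[measure] = {
            "iq_or": res.odds_ratio, "iq_or_ci": res.ci,
            "lr_chi2": chi2, "lr_p": p,
            "mc": mc.mc, "mc_ci": mc.ci,
            "nonlinearity_p": nl[2], "interaction_p": ints,
            "quantile_ors": quant.to_dict(orient="records")}
        print(f"{measure}: IQ-OR {res.odds_ratio:.2f} "
              f"({res.ci[0]:.2f}-{res.ci[1]:.2f}), LR-chi2 {chi2:.1f} "
              f"(P={p:.2g}), mC {mc.mc:.3f} ({mc.ci[0]:.3f}-{mc.ci[1]:.3f}); "
              f"linearity P={nl[2]:.2f}, interaction with BMI "
              f"P={ints['bmi']:.2f}, with log risk P={ints['log_tc10']:.2f}")

    slope, ci = dr.calibration_coefficient(pop, "tc10")
    out["calibration_coefficient_pct"] = {"slope": slope, "ci": ci}
    print(f"baseline-risk calibration slope {slope:.0f}% "
          f"({ci[0]:.0f}%-{ci[1]:.0f}%)")

    comp = dr.bootstrap_compare(pop, "vpd_log_residual",
                                "birads_integer_residual", n_boot=199,
                                seed=3)
    out["bootstrap_compare_vpd_vs_birads"] = comp
    print(f"predictive-ability difference (VPD vs clinical grade): "
          f"delta LR-chi2 {comp['delta_lr_chi2']:.1f}, P={comp['p']:.2f}")

    with open(RESULTS / "risk_models.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"wrote {RESULTS / 'risk_models.json'}")


if __name__ == "__main__":
    sys.exit(main())
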