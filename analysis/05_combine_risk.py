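"""Combine the density relative risk with the baseline 10-year risk.

Normalizes the per-woman relative risk from each fitted density
coefficient so its control mean is one, combines it with the baseline
10-year risk on the hazard scale, and tabulates the clinically used
strata (< 2% lower risk, >= 8% increased risk) among controls before and
after adding density.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import densrisk as dr

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = RESULTS / "population_with_residuals.csv"
    if not path.exists():
        print("run 03 and 04 first", file=sys.stderr)
        return 1
    pop = pd.read_csv(path)
    is_ctrl = (pop.status == "control").to_numpy()
    tc = pop.tc10.to_numpy()

    out = {}
    base = dr.risk_strata_proportions(tc[is_ctrl])
    out["baseline"] = base._asdict()
    print(f"baseline (controls): {100 * base.low:.1f}% lower-risk, "
          f"{100 * base.high:.1f}% increased-risk")

    for measure in ("vpd_log", "birads_integer"):
        col = f"{measure}_residual"
        resid = pop[col].to_numpy()
        fit = dr.fit_adjusted_logistic(pop, col)
        beta = float(fit.params[col])
        rr = dr.density_relative_risk(
            resid, beta, dr.control_normalizer(resid[is_ctrl], beta))
        combined = dr.combine_risk(tc, rr)
        pop[f"combined10_{measure}"] = combined
        strata = dr.risk_strata_proportions(combined[is_ctrl])
        edges, counts = dr.risk_histogram(combined[is_ctrl], 0.5)
        out[measure] = {"beta": beta, "strata": strata._asdict(),
                        "histogram": {"edges": edges.tolist(),
                                      "counts": counts.tolist()}}
        print(f"with {measure}: {100 * strata.low:.1f}% lower-risk, "
              f"{100 * strata.high:.1f}% increased-risk "
              f"(mean control rr {rr[is_ctrl].mean():.3f})")

    keep = ["id", "status", "tc10", "combined10_vpd_log",
            "combined10_birads_integer"]
    pop[keep].to_csv(RESULTS / "combined_risks.csv", index=False)
    with open(RESULTS / "risk_combination.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"wrote {RESULTS / 'combined_risks.csv'} and risk_combination.json")


if __name__ == "__main__":
    sys.exit(main())
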