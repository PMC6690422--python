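"""Agreement between clinical and volumetric density grades.

Recomputes the published statistics from the shipped count tables (the
linear-weighted kappa of the 4x4 grade cross-tabulation and the six crude
demography odds ratios) and the same kappa on the simulated population.
"""

import json
import sys
from pathlib import Path

import numpy as np

import densrisk as dr

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = {}
    tab = dr.load_reference_crosstab("combined").to_numpy()
    kappa, ci = dr.weighted_kappa(tab, "linear", n_boot=2000, seed=0)
    out["published_counts"] = {
        "weighted_kappa_linear": kappa, "kappa_bootstrap_ci": ci,
        "n": int(tab.sum())}
    print(f"published counts (n={int(tab.sum())}): linear-weighted kappa "
          f"{kappa:.3f} (bootstrap 95% CI {ci[0]:.3f}-{ci[1]:.3f})")

    out["crude_odds_ratios"] = {}
    for name, entry in dr.load_reference_two_by_twos().items():
        or_, (lo, hi) = dr.crude_odds_ratio(entry["table"])
        out["crude_odds_ratios"][name] = {
            "contrast": entry["contrast"], "or": or_, "ci": [lo, hi],
            "reported_or": entry["reported_or"]}
        print(f"  {entry['contrast']}: OR {or_:.2f} ({lo:.2f}-{hi:.2f}) "
              f"[reported {entry['reported_or']:.2f}]")

    pop_path = RESULTS / "population.csv"
    if pop_path.exists():
        pop = dr.read_participants(pop_path)
        grade = np.digitize(np.log(pop.vpd.to_numpy()),
                            np.log([4.6, 7.6, 15.4])) + 1
        sim = np.zeros((4, 4))
        np.add.at(sim, (pop.birads.to_numpy() - 1, grade - 1), 1)
        k_sim, ci_sim = dr.weighted_kappa(sim, "linear", n_boot=2000, seed=1)
        out["simulated_population"] = {
            "weighted_kappa_linear": k_sim, "kappa_bootstrap_ci": ci_sim,
            "crosstab": sim.astype(int).tolist()}
        print(f"simulated population: linear-weighted kappa {k_sim:.3f} "
              f"({ci_sim[0]:.3f}-{ci_sim[1]:.3f})")
    else:
        print("note: run 01_simulate_population.py first for the simulated "
              "kappa")

    with open(RESULTS / "agreement.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"wrote {RESULTS / 'agreement.json'}")


if __name__ == "__main__":
    sys.exit(main())
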