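"""Fit the expected-density surfaces and compute residuals.

Models log volumetric percent density and the integer clinical grade as
additive spline functions of age and BMI on controls, then writes the
serialized models and a residual-augmented participant table.
"""

import sys
from pathlib import Path

import densrisk as dr

RESULTS = Path(__file__).resolve().parents[1] / "results"
MEASURES = ("vpd_log", "birads_integer", "fibro_log", "fat_log")


def main() -> None:
    pop_path = RESULTS / "population.csv"
    if not pop_path.exists():
        print("run 01_simulate_population.py first", file=sys.stderr)
        return 1
    pop = dr.read_participants(pop_path)
    controls = pop[pop.status == "control"]

    for measure in MEASURES:
        model = dr.fit_expected_density(controls, measure)
        (RESULTS / f"expected_density_{measure}.json").write_text(
            model.to_json())
        pop[f"{measure}_residual"] = dr.residualize_table(model, pop)
        q25, q75 = dr.residual_iqr(model)
        med = model.control_residual_quartiles[1]
        print(f"{measure}: fitted on {model.training_n} controls; "
              f"control residual median {med:+.2f}, "
              f"IQR ({q25:+.2f}, {q75:+.2f})")

    pop.to_csv(RESULTS / "population_with_residuals.csv", index=False)
    print(f"wrote {RESULTS / 'population_with_residuals.csv'} and "
          f"one expected_density_*.json per measure")


if __name__ == "__main__":
    sys.exit(main())
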