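"""Logistic modelling: oracle equivalences, IQ-OR arithmetic, LR and
interaction tests, quantile bookkeeping, calibration recovery."""

import numpy as np
import pandas as pd
import pytest

from densrisk import (bootstrap_compare, calibration_coefficient,
                      fit_adjusted_logistic, interaction_test, iq_or,
                      lr_test, nonlinearity_check, quantile_group_ors)
from densrisk.errors import DomainError, InputError
from densrisk.risk_models import quantile_group_assign


def binary_table(a, b, c, d, seed=0):
    """Case-control table with binary exposure: a/b exposed/unexposed cases,
    c/d exposed/unexposed controls."""
    rows = ([{"status": "case", "x": 1.0}] * a
            + [{"status": "case", "x": 0.0}] * b
            + [{"status": "control", "x": 1.0}] * c
            + [{"status": "control", "x": 0.0}] * d)
    return pd.DataFrame(rows).sample(frac=1.0, random_state=seed)


def simple_population(n=4000, beta=0.0, seed=0):
    """Minimal table: one continuous predictor with configurable log-OR."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    z = rng.normal(0, 1, n)  # an adjustment covariate, no effect
    p = 1 / (1 + np.exp(-(-1.0 + beta * x)))
    status = np.where(rng.uniform(size=n) < p, "case", "control")
    return pd.DataFrame({"status": status, "x": x, "z": z})


class TestFitAdjustedLogistic:
    def test_binary_predictor_matches_crude_or_oracle(self):
        a, b, c, d = 73, 401, 122, 2121
        tab = binary_table(a, b, c, d)
        fit = fit_adjusted_logistic(tab, "x", adjustments=())
        crude = (a * d) / (b * c)
        assert np.exp(fit.params["x"]) == pytest.approx(crude, abs=1e-8)

    def test_null_predictor_coefficient_near_zero(self):
        tab = simple_population(n=8000, beta=0.0, seed=1)
        fit = fit_adjusted_logistic(tab, "x", adjustments=("z",))
        z = fit.params["x"] / fit.bse["x"]
        assert abs(z) < 3

    def test_covariance_symmetric_psd_and_llf_negative(self):
        tab = simple_population(n=2000, beta=0.4, seed=2)
        fit = fit_adjusted_logistic(tab, "x", adjustments=("z",))
        cov = fit.cov.to_numpy()
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-10
        assert fit.llf < 0
        assert fit.converged

    def test_all_control_input_rejected(self):
        tab = simple_population(n=100, seed=3)
        tab["status"] = "control"
        with pytest.raises(InputError, match="degenerate"):
            fit_adjusted_logistic(tab, "x", adjustments=())

    def test_separation_reported(self):
        tab = pd.DataFrame({
            "status": ["case"] * 30 + ["control"] * 30,
            "x": np.r_[np.ones(30), np.zeros(30)]})
        from densrisk.errors import FitError
        with pytest.raises(FitError):
            fit_adjusted_logistic(tab, "x", adjustments=())


class TestIqOr:
    def test_zero_coefficient_gives_unit_or(self):
        tab = simple_population(n=4000, beta=0.0, seed=4)
        fit = fit_adjusted_logistic(tab, "x", adjustments=())
        res = iq_or(fit, -0.5, 0.5)
        assert res.ci[0] < 1.0 < res.ci[1]

    def test_analytic_or_two(self):
        tab = simple_population(n=500, beta=0.5, seed=5)
        fit = fit_adjusted_logistic(tab, "x", adjustments=())
        fit.params["x"] = np.log(2.0)
        res = iq_or(fit, 0.0, 1.0)
        assert res.odds_ratio == pytest.approx(2.0, abs=1e-12)

    def test_analytic_inversion_recovers_target(self):
        tab = simple_population(n=500, beta=0.5, seed=6)
        fit = fit_adjusted_logistic(tab, "x", adjustments=())
        fit.params["x"] = np.log(1.55) / 1.5
        res = iq_or(fit, -0.75, 0.75)
        assert res.odds_ratio == pytest.approx(1.55, abs=1e-12)

    def test_scaling_invariance(self):
        """IQ-OR is unchanged when the predictor is rescaled by a constant."""
        tab = simple_population(n=4000, beta=0.4, seed=7)
        fit1 = fit_adjusted_logistic(tab, "x", adjustments=("z",))
        q25, q75 = np.quantile(tab.x[tab.status == "control"], [0.25, 0.75])
        scaled = tab.assign(x=tab.x * 3.0)
        fit2 = fit_adjusted_logistic(scaled, "x", adjustments=("z",))
        r1 = iq_or(fit1, q25, q75)
        r2 = iq_or(fit2, 3 * q25, 3 * q75)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-6)

    def test_bad_quartiles_rejected(self):
        tab = simple_population(n=500, beta=0.5, seed=8)
        fit = fit_adjusted_logistic(tab, "x", adjustments=())
        with pytest.raises(DomainError):
            iq_or(fit, 0.5, 0.5)


class TestLrTest:
    def test_identical_models_give_zero(self):
        tab = simple_population(n=1000, beta=0.3, seed=9)
        fit = fit_adjusted_logistic(tab, "x", adjustments=())
        chi2, df, p = lr_test(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_chi2_quantile_anchor(self):
        from scipy.stats import chi2 as chi2_dist
        assert chi2_dist.sf(3.841458820694124, 1) == pytest.approx(0.05,
                                                                   abs=1e-9)

    def test_non_nested_rejected(self):
        tab = simple_population(n=1000, beta=0.3, seed=10)
        fit_x = fit_adjusted_logistic(tab, "x", adjustments=())
        fit_z = fit_adjusted_logistic(tab, "z", adjustments=())
        with pytest.raises(InputError):
            lr_test(fit_x, fit_z)

    def test_invariant_to_row_reordering(self):
        tab = simple_population(n=1500, beta=0.3, seed=11)
        perm = tab.sample(frac=1.0, random_state=2)
        def stat(t):
            full = fit_adjusted_logistic(t, "x", adjustments=("z",))
            null = fit_adjusted_logistic(t, None, adjustments=("z",))
            return lr_test(full, null)[0]
        assert stat(tab) == pytest.approx(stat(perm), abs=1e-6)


class TestInteraction:
    def test_strong_product_term_detected(self):
        rng = np.random.default_rng(12)
        n = 5000
        x = rng.normal(0, 1, n)
        m = rng.normal(0, 1, n)
        eta = -1.0 + 0.2 * x + np.log(2) * x * m
        status = np.where(rng.uniform(size=n) < 1 / (1 + np.exp(-eta)),
                          "case", "control")
        tab = pd.DataFrame({"status": status, "x": x, "m": m})
        chi2, df, p = interaction_test(tab, "x", "m", adjustments=())
        assert df == 1 and p < 0.05

    def test_constant_modifier_rejected(self):
        tab = simple_population(n=500, beta=0.3, seed=13)
        tab["m"] = 1.0
        with pytest.raises(InputError, match="constant"):
            interaction_test(tab, "x", "m", adjustments=())


class TestQuantileGroups:
    def test_control_quintile_sizes_for_2243(self):
        """2,243 controls split into residual quintiles must produce the
        equal-as-possible sizes 449/448/449/448/449."""
        rng = np.random.default_rng(14)
        vals = rng.normal(0, 1, 2243)
        groups, _ = quantile_group_assign(vals, vals, 5)
        assert np.bincount(groups).tolist() == [449, 448, 449, 448, 449]

    def test_null_residual_gives_flat_ors(self):
        tab = simple_population(n=6000, beta=0.0, seed=15)
        out = quantile_group_ors(tab, "x", 5, adjustments=("z",))
        assert out.odds_ratio.iloc[0] == 1.0
        assert ((out.odds_ratio[1:] > 0.7) & (out.odds_ratio[1:] < 1.4)).all()

    def test_monotone_effect_gives_increasing_trend(self):
        tab = simple_population(n=8000, beta=0.8, seed=16)
        out = quantile_group_ors(tab, "x", 5, adjustments=("z",))
        assert out.odds_ratio.iloc[-1] > out.odds_ratio.iloc[1]
        assert out.odds_ratio.iloc[-1] > 1.5

    def test_too_few_controls_rejected(self):
        tab = simple_population(n=60, beta=0.0, seed=17)
        with pytest.raises(InputError):
            quantile_group_ors(tab, "x", 5, adjustments=())


class TestCalibration:
    def test_unit_slope_recovered(self):
        rng = np.random.default_rng(18)
        n = 20000
        risk = np.exp(rng.normal(np.log(3.0), 0.5, n))
        eta = -3.0 + 1.0 * np.log(risk)
        status = np.where(rng.uniform(size=n) < 1 / (1 + np.exp(-eta)),
                          "case", "control")
        tab = pd.DataFrame({"status": status, "tc10": risk})
        slope, ci = calibration_coefficient(tab)
        assert slope == pytest.approx(100.0, abs=10.0)
        assert ci[0] < slope < ci[1]

    def test_shuffled_risk_gives_zero_slope(self):
        rng = np.random.default_rng(19)
        n = 10000
        risk = np.exp(rng.normal(np.log(3.0), 0.5, n))
        status = np.where(rng.uniform(size=n) < 0.2, "case", "control")
        tab = pd.DataFrame({"status": status, "tc10": risk})
        slope, ci = calibration_coefficient(tab)
        assert abs(slope) < 15.0

    def test_doubled_exponent_gives_double_slope(self):
        rng = np.random.default_rng(20)
        n = 20000
        risk = np.exp(rng.normal(np.log(3.0), 0.5, n))
        eta = -3.5 + 2.0 * np.log(risk)
        status = np.where(rng.uniform(size=n) < 1 / (1 + np.exp(-eta)),
                          "case", "control")
        tab = pd.DataFrame({"status": status, "tc10": risk})
        slope, _ = calibration_coefficient(tab)
        assert slope == pytest.approx(200.0, abs=20.0)

    def test_constant_risk_rejected(self):
        tab = pd.DataFrame({"status": ["case"] * 5 + ["control"] * 5,
                            "tc10": 3.0})
        with pytest.raises(InputError):
            calibration_coefficient(tab)


class TestBootstrapCompare:
    def test_identical_predictors_give_zero_delta_large_p(self):
        tab = simple_population(n=1200, beta=0.5, seed=21)
        tab["x2"] = tab["x"]
        out = bootstrap_compare(tab, "x", "x2", adjustments=(),
                                n_boot=199, seed=0)
        assert out["delta_lr_chi2"] == pytest.approx(0.0, abs=1e-8)
        assert out["p"] > 0.5

    def test_informative_vs_noise_detected(self):
        tab = simple_population(n=5000, beta=0.5, seed=22)
        rng = np.random.default_rng(23)
        tab["noise"] = rng.normal(0, 1, len(tab))
        out = bootstrap_compare(tab, "x", "noise", adjustments=(),
                                n_boot=199, seed=0)
        assert out["delta_lr_chi2"] > 0
        assert out["p"] < 0.05

    def test_seed_reproducible(self):
        tab = simple_population(n=800, beta=0.4, seed=24)
        tab["x2"] = tab["x"] + np.random.default_rng(25).normal(
            0, 0.5, len(tab))
        a = bootstrap_compare(tab, "x", "x2", adjustments=(), n_boot=199,
                              seed=7)
        b = bootstrap_compare(tab, "x", "x2", adjustments=(), n_boot=199,
                              seed=7)
        assert a == b


class TestNonlinearity:
    def test_linear_truth_not_rejected_usually(self):
        tab = simple_population(n=4000, beta=0.5, seed=26)
        chi2, df, p = nonlinearity_check(tab, "x", adjustments=("z",))
        assert df == 3
        assert p > 0.01

    def test_strong_quadratic_detected(self):
        rng = np.random.default_rng(27)
        n = 5000
        x = rng.normal(0, 1, n)
        eta = -1.5 + 0.8 * x ** 2
        status = np.where(rng.uniform(size=n) < 1 / (1 + np.exp(-eta)),
                          "case", "control")
        tab = pd.DataFrame({"status": status, "x": x})
        chi2, df, p = nonlinearity_check(tab, "x", adjustments=())
        assert p < 1e-4

    def test_constant_residual_rejected(self):
        tab = simple_population(n=200, seed=28)
        tab["x"] = 0.0
        with pytest.raises(InputError):
            nonlinearity_check(tab, "x", adjustments=())
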