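"""Adjusted case-control logistic modelling of a density signal.

The central effect measure is the interquartile odds ratio (IQ-OR): the
odds ratio for moving from the 25th to the 75th percentile of the control
residual distribution.  It is scale-free, so effects of density measures on
different scales (log percent density, integer clinical grade, log volumes)
are directly comparable.

Model fits go through statsmodels' Newton maximum likelihood; this module
owns the design construction (5-year age-group indicators, categorical
dummies, log baseline risk), the IQ-OR/CI arithmetic, likelihood-ratio,
interaction and nonlinearity tests, the bootstrap comparison of two
predictors, quantile-group odds ratios, and the calibration slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, FitError, InputError
from .residual_model import basis_for_training

__all__ = [
    "DEFAULT_ADJUSTMENTS", "LogisticFit", "IqOrResult",
    "build_design", "fit_adjusted_logistic", "iq_or", "lr_test",
    "interaction_test", "bootstrap_compare", "quantile_group_ors",
    "calibration_coefficient", "nonlinearity_check", "quantile_group_assign",
]

#: Adjustment set used throughout: study-design factors plus BMI and the
#: log questionnaire-model 10-year risk.
DEFAULT_ADJUSTMENTS = ("age_group", "region", "insurance", "financial_screen",
                       "education", "ethnicity", "bmi", "log_tc10")

_Z = float(stats.norm.ppf(0.975))


@dataclass
class LogisticFit:
    """A converged maximum-likelihood logistic fit."""

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n_cases: int
    n_controls: int
    converged: bool
    predictor_term: str | None
    design_terms: tuple[str, ...]

    @property
    def nobs(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())),
                         index=self.params.index)


@dataclass
class IqOrResult:
    """Odds ratio for a 25th-to-75th percentile change of the predictor."""

    odds_ratio: float
    ci: tuple[float, float]
    iqr_width: float
    coefficient: float
    se: float


def _missing_category(s: pd.Series) -> pd.Series:
    # missing categorical levels are modelled as an explicit category
    return s.astype(object).where(s.notna(), "Unknown")


def build_design(table: pd.DataFrame, terms) -> pd.DataFrame:
    """Expand model terms into a numeric design matrix (no constant).

    * ``log_tc10`` means the natural log of the ``tc10`` column;
    * non-numeric columns become indicator dummies against the first level
      in sorted order (missing values form an ``Unknown`` level);
    * numeric columns enter linearly; rows with missing numeric values must
      be excluded by the caller beforehand.
    """
    cols: list[pd.Series] = []
    for term in terms:
        if term == "log_tc10":
            tc = table["tc10"].to_numpy(dtype=float)
            if np.any(tc <= 0):
                raise DomainError("tc10 must be > 0 to take its log")
            cols.append(pd.Series(np.log(tc), index=table.index,
                                  name="log_tc10"))
            continue
        if term not in table.columns:
            raise InputError(f"missing model column {term!r}")
        s = table[term]
        if pd.api.types.is_numeric_dtype(s) and term != "age_group":
            if s.isna().any():
                raise InputError(
                    f"column {term!r} has missing numeric values; "
                    "exclude those rows before fitting")
            cols.append(s.astype(float))
        else:
            s = _missing_category(s)
            levels = sorted(map(str, s.unique()))
            for lev in levels[1:]:
                cols.append(pd.Series(
                    (s.astype(str) == lev).astype(float),
                    index=table.index, name=f"{term}[{lev}]"))
    if not cols:
        return pd.DataFrame(index=table.index)
    return pd.concat(cols, axis=1)


def _status_vector(table: pd.DataFrame) -> np.ndarray:
    y = (table["status"].astype(str) == "case").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise InputError("degenerate outcome: all rows are "
                         + ("cases" if y.sum() else "controls"))
    return y


def _fit_mle(y: np.ndarray, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, float, bool]:
    Xc = sm.add_constant(X, has_constant="add")
    arr = Xc.to_numpy(dtype=float)
    # drop-first dummy coding should leave a full-rank design; if not, fail
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise FitError("design matrix is rank deficient (collinear terms)")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.filterwarnings("error", message=".*[Ss]eparation.*")
        try:
            res = sm.Logit(y, Xc).fit(method="newton", tol=1e-10,
                                      maxiter=200, disp=0)
        except Exception as exc:  # separation, overflow, no convergence
            raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 30:
        worst = Xc.columns[int(np.argmax(np.abs(res.params)))]
        raise FitError(f"separation suspected: term {worst!r} diverged")
    return (np.asarray(res.params), np.asarray(res.cov_params()),
            float(res.llf), True)


def fit_adjusted_logistic(table: pd.DataFrame, predictor: str | None,
                          adjustments=DEFAULT_ADJUSTMENTS) -> LogisticFit:
    """ML logistic fit of case status on a predictor plus adjustments.

    ``predictor`` is a numeric column (typically a density residual); pass
    ``None`` for the adjustments-only null model.
    """
    y = _status_vector(table)
    terms = ([predictor] if predictor else []) + list(adjustments)
    X = build_design(table, terms)
    params, cov, llf, conv = _fit_mle(y, X)
    names = ["const"] + list(X.columns)
    return LogisticFit(
        params=pd.Series(params, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        llf=llf,
        n_cases=int(y.sum()), n_controls=int(len(y) - y.sum()),
        converged=conv, predictor_term=predictor,
        design_terms=tuple(names))


def iq_or(fit: LogisticFit, q25: float, q75: float,
          term: str | None = None) -> IqOrResult:
    """Interquartile odds ratio with a Wald CI on the log-odds scale."""
    if q75 <= q25:
        raise DomainError("q75 must exceed q25")
    term = term or fit.predictor_term
    if term is None or term not in fit.params.index:
        raise InputError("fit does not contain the requested predictor term")
    w = q75 - q25
    coef = float(fit.params[term])
    se = float(fit.bse[term])
    return IqOrResult(
        odds_ratio=float(np.exp(coef * w)),
        ci=(float(np.exp((coef - _Z * se) * w)),
            float(np.exp((coef + _Z * se) * w))),
        iqr_width=w, coefficient=coef, se=se)


def lr_test(fit_full: LogisticFit, fit_null: LogisticFit
            ) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square of nested logistic fits."""
    if not set(fit_null.design_terms) <= set(fit_full.design_terms):
        raise InputError("models are not nested (null terms not a subset)")
    if fit_full.nobs != fit_null.nobs:
        raise InputError("models were fitted on different row counts")
    df = len(fit_full.design_terms) - len(fit_null.design_terms)
    chi2 = max(0.0, 2.0 * (fit_full.llf - fit_null.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return (chi2, df, p)


def interaction_test(table: pd.DataFrame, predictor: str, modifier: str,
                     adjustments=DEFAULT_ADJUSTMENTS
                     ) -> tuple[float, int, float]:
    """LR test for effect modification: predictor x modifier product term.

    The modifier must be numeric (continuous or 0/1) and non-constant; its
    main effect is included in both models (via the adjustment set if
    already there, else appended).
    """
    if modifier == "log_tc10":
        mod = np.log(table["tc10"].to_numpy(dtype=float))
    else:
        mod = table[modifier].to_numpy(dtype=float)
    if np.ptp(mod) == 0:
        raise InputError(f"modifier {modifier!r} is constant (collinear)")
    work = table.copy()
    pname = f"{predictor}:x:{modifier}"
    work[pname] = work[predictor].to_numpy(dtype=float) * mod
    adj = list(adjustments)
    if modifier not in adj:
        adj.append(modifier)
    full = fit_adjusted_logistic(work, pname, adjustments=[predictor] + adj)
    null = fit_adjusted_logistic(work, predictor, adjustments=adj)
    return lr_test(full, null)


def _lr_chi2_for(table: pd.DataFrame, predictor: str, adjustments) -> float:
    full = fit_adjusted_logistic(table, predictor, adjustments)
    null = fit_adjusted_logistic(table, None, adjustments)
    return lr_test(full, null)[0]


def bootstrap_compare(table: pd.DataFrame, predictor_a: str, predictor_b: str,
                      adjustments=DEFAULT_ADJUSTMENTS, n_boot: int = 499,
                      seed: int = 0) -> dict:
    """Bootstrap test for a difference in predictive ability.

    The statistic is the difference in likelihood-ratio chi-square added
    over the adjustment set by predictor A versus predictor B on the
    observed data.  Participants are resampled with replacement within
    case and control strata; the two-sided p-value compares the observed
    difference with the bootstrap distribution centred at the observed
    value.  Replicates whose fits fail are dropped and counted; more than
    5% dropped flags a warning in the result.
    """
    if n_boot < 199:
        raise InputError("n_boot must be >= 199")
    delta_obs = (_lr_chi2_for(table, predictor_a, adjustments)
                 - _lr_chi2_for(table, predictor_b, adjustments))
    rng = np.random.default_rng(seed)
    cases = table[table["status"] == "case"]
    ctrls = table[table["status"] == "control"]
    deltas = []
    dropped = 0
    for _ in range(n_boot):
        rep = pd.concat([
            cases.iloc[rng.integers(0, len(cases), len(cases))],
            ctrls.iloc[rng.integers(0, len(ctrls), len(ctrls))],
        ]).reset_index(drop=True)
        try:
            deltas.append(_lr_chi2_for(rep, predictor_a, adjustments)
                          - _lr_chi2_for(rep, predictor_b, adjustments))
        except (FitError, InputError):
            dropped += 1
    deltas = np.asarray(deltas)
    centred = deltas - deltas.mean() if len(deltas) else deltas
    p = float((1 + np.sum(np.abs(centred) >= abs(delta_obs)))
              / (len(deltas) + 1))
    result = {"delta_lr_chi2": float(delta_obs), "p": p,
              "n_boot_used": int(len(deltas)), "n_dropped": int(dropped),
              "warning": None}
    if dropped > 0.05 * n_boot:
        result["warning"] = f"{dropped}/{n_boot} bootstrap replicates dropped"
        warnings.warn(result["warning"], RuntimeWarning, stacklevel=2)
    return result


def quantile_group_assign(values: np.ndarray, control_values: np.ndarray,
                          n_groups: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-group index (0-based) with boundaries from controls.

    Controls are split into groups as equal as possible (sizes differ by at
    most one): the sorted control values are cut at positions
    ``round(i * n / k)`` and the cut values are midpoints of the adjacent
    order statistics, so ties at a boundary cannot straddle it for
    continuous data.  Returns ``(group_index, cut_values)``.
    """
    control_values = np.sort(np.asarray(control_values, dtype=float))
    n = len(control_values)
    if n < n_groups:
        raise InputError("fewer controls than groups")
    bounds = [int(round(i * n / n_groups)) for i in range(1, n_groups)]
    cuts = np.array([(control_values[b - 1] + control_values[b]) / 2.0
                     for b in bounds])
    return np.searchsorted(cuts, np.asarray(values, dtype=float),
                           side="right"), cuts


def quantile_group_ors(table: pd.DataFrame, residual_col: str,
                       n_groups: int = 5, adjustments=DEFAULT_ADJUSTMENTS
                       ) -> pd.DataFrame:
    """Per-group odds ratios against the bottom (least dense) group."""
    if n_groups < 2:
        raise InputError("n_groups must be >= 2")
    ctrl_vals = table.loc[table["status"] == "control",
                          residual_col].to_numpy(dtype=float)
    groups, _ = quantile_group_assign(
        table[residual_col].to_numpy(dtype=float), ctrl_vals, n_groups)
    ctrl_counts = np.bincount(groups[(table["status"] == "control").to_numpy()],
                              minlength=n_groups)
    if ctrl_counts.min() < 10:
        raise InputError("fewer than 10 controls in a quantile group")
    work = table.copy()
    labels = [f"Q{g + 1}" for g in range(n_groups)]
    work["_density_group"] = pd.Series(groups, index=table.index).map(
        dict(enumerate(labels)))
    fit = fit_adjusted_logistic(work, None,
                                adjustments=["_density_group"] + list(adjustments))
    case_counts = np.bincount(groups[(table["status"] == "case").to_numpy()],
                              minlength=n_groups)
    rows = []
    for g, lab in enumerate(labels):
        if g == 0:
            or_, lo, hi = 1.0, np.nan, np.nan
        else:
            term = f"_density_group[{lab}]"
            coef = float(fit.params[term])
            se = float(fit.bse[term])
            or_ = float(np.exp(coef))
            lo, hi = float(np.exp(coef - _Z * se)), float(np.exp(coef + _Z * se))
        rows.append({"group": lab, "n_controls": int(ctrl_counts[g]),
                     "n_cases": int(case_counts[g]), "odds_ratio": or_,
                     "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def calibration_coefficient(table: pd.DataFrame, risk_col: str = "tc10"
                            ) -> tuple[float, tuple[float, float]]:
    """Calibration slope of case status on log predicted risk, as percent.

    100% means the predicted relative risks are fully expressed in the
    case-control contrast; below 100% they are overdispersed relative to
    the observed gradient.
    """
    risk = table[risk_col].to_numpy(dtype=float)
    if np.any(risk <= 0):
        raise DomainError(f"{risk_col} must be > 0")
    if np.ptp(risk) == 0:
        raise InputError(f"{risk_col} has zero variance")
    y = _status_vector(table)
    X = pd.DataFrame({"log_risk": np.log(risk)}, index=table.index)
    params, cov, _, _ = _fit_mle(y, X)
    slope, se = params[1], float(np.sqrt(cov[1, 1]))
    return (float(100 * slope),
            (float(100 * (slope - _Z * se)), float(100 * (slope + _Z * se))))


def nonlinearity_check(table: pd.DataFrame, residual_col: str,
                       adjustments=DEFAULT_ADJUSTMENTS, df: int = 4
                       ) -> tuple[float, int, float]:
    """LR test of a spline-in-residual model against the linear model.

    The spline basis (with intercept absorbed by the fit) contains the
    linear function, so the models are nested with ``df - 1`` extra
    parameters.
    """
    x = table[residual_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise InputError(f"{residual_col} is constant")
    basis, _, _ = basis_for_training(x, df)
    work = table.copy()
    spline_names = []
    for j in range(basis.shape[1]):
        name = f"{residual_col}__s{j}"
        work[name] = basis[:, j]
        spline_names.append(name)
    full = fit_adjusted_logistic(work, None,
                                 adjustments=spline_names + list(adjustments))
    null = fit_adjusted_logistic(work, residual_col, adjustments=adjustments)
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    dof = basis.shape[1] - 1
    return (chi2, dof, float(stats.chi2.sf(chi2, dof)))
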