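"""Expected density given age and BMI, and the density residual.

Percent density falls with both age and BMI, so raw density partly restates
information a questionnaire-based risk model already uses.  The density
signal added to such a model is therefore the *residual*: observed minus
expected (transformed) density, where the expectation is an additive spline
surface in age and BMI fitted on controls only.

Volumetric measures (percent density, fibroglandular volume, fat volume)
are modelled on the natural-log scale; the four-grade clinical reading is
treated as the integers 1-4 on the identity scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .errors import (DomainError, InputError, StateError,
                     UnderdeterminedFitError)

__all__ = [
    "SplineSpec", "ExpectedDensityModel", "DensityResidual",
    "fit_expected_density", "residualize", "residual_iqr",
    "bspline_basis", "MEASURES",
]

#: measure name -> (source column, log transform?)
MEASURES = {
    "vpd_log": ("vpd", True),
    "birads_integer": ("birads", False),
    "fibro_log": ("fibro_volume", True),
    "fat_log": ("fat_volume", True),
}


@dataclass(frozen=True)
class SplineSpec:
    """Cubic B-spline basis dimensions for the additive surface.

    ``df`` counts columns per covariate after the constant is removed, so
    the additive model has ``1 + df_age + df_bmi`` coefficients.  The basis
    degree is ``min(3, df)``; interior knots sit at equally spaced quantiles
    of the training covariate.  ``penalty='gcv'`` adds a ridge penalty on
    the non-constant coefficients with the penalty weight chosen by
    generalized cross-validation.
    """

    df_age: int = 4
    df_bmi: int = 4
    penalty: str | None = None

    def validate(self) -> None:
        if self.df_age < 2 or self.df_bmi < 2:
            raise InputError("spline df must be >= 2 per covariate")
        if self.penalty not in (None, "gcv"):
            raise InputError("penalty must be None or 'gcv'")


def _knots(x: np.ndarray, df: int, degree: int) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    n_interior = df - degree
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def bspline_basis(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    """B-spline design matrix with the first column dropped.

    The full basis sums to one, so together with an explicit intercept the
    dropped-first parameterization spans the same function space (including
    all linear functions) without collinearity.  Inputs are clamped to the
    knot range.
    """
    x = np.clip(np.asarray(x, dtype=float), knots[degree], knots[-degree - 1])
    dm = BSpline.design_matrix(x, knots, degree).toarray()
    return dm[:, 1:]


def basis_for_training(x: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray, int]:
    degree = min(3, int(df))
    t = _knots(x, df, degree)
    return bspline_basis(x, t, degree), t, degree


@dataclass
class DensityResidual:
    """Observed minus expected density on the model's transformed scale."""

    value: float | np.ndarray
    measure: str


@dataclass
class ExpectedDensityModel:
    """Fitted additive-spline expectation of (transformed) density.

    Prediction outside the training age/BMI ranges clamps to the range
    boundary (spline extrapolation is not meaningful) and emits a warning;
    for the integer clinical grade, predictions are additionally clamped to
    the observed [1, 4] scale.
    """

    measure: str
    spline_spec: SplineSpec
    coefficients: np.ndarray
    knots_age: np.ndarray
    knots_bmi: np.ndarray
    degree_age: int
    degree_bmi: int
    training_n: int
    training_ranges: dict[str, tuple[float, float]]
    control_residual_quartiles: tuple[float, float, float] | None = None
    ridge_lambda: float = 0.0
    _fitted: bool = field(default=True, repr=False)

    # -- prediction ---------------------------------------------------------

    def _check_range(self, age, bmi) -> None:
        (alo, ahi) = self.training_ranges["age"]
        (blo, bhi) = self.training_ranges["bmi"]
        if np.any(age < alo) or np.any(age > ahi) or \
           np.any(bmi < blo) or np.any(bmi > bhi):
            warnings.warn(
                "prediction input outside training range; clamped to boundary",
                RuntimeWarning, stacklevel=3)

    def predict(self, age, bmi):
        """Expected transformed density at (age, bmi)."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        bmi = np.atleast_1d(np.asarray(bmi, dtype=float))
        age, bmi = np.broadcast_arrays(age, bmi)
        self._check_range(age, bmi)
        ba = bspline_basis(age, self.knots_age, self.degree_age)
        bb = bspline_basis(bmi, self.knots_bmi, self.degree_bmi)
        X = np.column_stack([np.ones(len(age)), ba, bb])
        pred = X @ self.coefficients
        if self.measure == "birads_integer":
            pred = np.clip(pred, 1.0, 4.0)
        return pred if pred.size > 1 else float(pred[0])

    def transform(self, observed):
        """Raw measurement -> model scale (log for volumetric measures)."""
        observed = np.asarray(observed, dtype=float)
        _, use_log = MEASURES[self.measure]
        if use_log:
            if np.any(observed <= 0):
                raise DomainError(
                    f"{self.measure}: observed values must be > 0 for a log measure")
            return np.log(observed)
        if self.measure == "birads_integer" and (
                np.any(observed < 1) or np.any(observed > 4)):
            raise DomainError("birads must be in 1..4")
        return observed

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "measure": self.measure,
            "spline_spec": {"df_age": self.spline_spec.df_age,
                            "df_bmi": self.spline_spec.df_bmi,
                            "penalty": self.spline_spec.penalty},
            "coefficients": self.coefficients.tolist(),
            "knots_age": self.knots_age.tolist(),
            "knots_bmi": self.knots_bmi.tolist(),
            "degree_age": self.degree_age,
            "degree_bmi": self.degree_bmi,
            "training_n": self.training_n,
            "training_ranges": {k: list(v)
                                for k, v in self.training_ranges.items()},
            "control_residual_quartiles": list(self.control_residual_quartiles)
            if self.control_residual_quartiles is not None else None,
            "ridge_lambda": self.ridge_lambda,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExpectedDensityModel":
        d = json.loads(text)
        return cls(
            measure=d["measure"],
            spline_spec=SplineSpec(**d["spline_spec"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            knots_age=np.asarray(d["knots_age"], dtype=float),
            knots_bmi=np.asarray(d["knots_bmi"], dtype=float),
            degree_age=int(d["degree_age"]),
            degree_bmi=int(d["degree_bmi"]),
            training_n=int(d["training_n"]),
            training_ranges={k: (float(v[0]), float(v[1]))
                             for k, v in d["training_ranges"].items()},
            control_residual_quartiles=tuple(d["control_residual_quartiles"])
            if d["control_residual_quartiles"] is not None else None,
            ridge_lambda=float(d.get("ridge_lambda", 0.0)),
        )


def _gcv_ridge(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Ridge fit (intercept unpenalized) with GCV-selected penalty weight."""
    n, p = X.shape
    pen = np.ones(p)
    pen[0] = 0.0  # never shrink the intercept
    best = (None, np.inf, 0.0)
    for lam in np.concatenate([[0.0], np.logspace(-6, 4, 21)]):
        A = X.T @ X + lam * np.diag(pen)
        try:
            coef = np.linalg.solve(A, X.T @ y)
            # effective dof = trace of the hat matrix
            edf = float(np.trace(np.linalg.solve(A, X.T @ X)))
        except np.linalg.LinAlgError:
            continue
        resid = y - X @ coef
        denom = (1.0 - edf / n) ** 2
        if denom <= 0:
            continue
        gcv = float(resid @ resid / n / denom)
        if gcv < best[1]:
            best = (coef, gcv, lam)
    if best[0] is None:
        raise UnderdeterminedFitError("ridge/GCV fit failed for every penalty")
    return best[0], best[2]


def fit_expected_density(controls: pd.DataFrame, measure: str,
                         spline_spec: SplineSpec | None = None
                         ) -> ExpectedDensityModel:
    """Fit the additive age+BMI spline surface on controls.

    ``controls`` must contain only control rows (a ``status`` column, if
    present, is checked).  Residuals on the training controls average zero
    by construction of the least-squares fit with intercept; their
    quartiles (linear interpolation of order statistics, the "type 7"
    convention) are stored on the model for interquartile effect scaling.
    """
    if measure not in MEASURES:
        raise InputError(f"unknown measure {measure!r}; one of {sorted(MEASURES)}")
    if spline_spec is None:
        spline_spec = SplineSpec()
    spline_spec.validate()
    if "status" in controls.columns and (controls["status"] != "control").any():
        raise InputError("fit_expected_density expects control rows only")
    if len(controls) == 0:
        raise InputError("fit_expected_density: empty training table")

    col, use_log = MEASURES[measure]
    for needed in (col, "age_mammogram", "bmi"):
        if needed not in controls.columns:
            raise InputError(f"missing column {needed!r}")

    age = controls["age_mammogram"].to_numpy(dtype=float)
    bmi = controls["bmi"].to_numpy(dtype=float)
    raw = controls[col].to_numpy(dtype=float)
    if use_log:
        if np.any(raw <= 0):
            raise DomainError(f"{col} must be > 0 for measure {measure}")
        y = np.log(raw)
    else:
        if measure == "birads_integer" and (np.any(raw < 1) or np.any(raw > 4)):
            raise DomainError("birads must be in 1..4")
        y = raw

    ba, t_age, d_age = basis_for_training(age, spline_spec.df_age)
    bb, t_bmi, d_bmi = basis_for_training(bmi, spline_spec.df_bmi)
    X = np.column_stack([np.ones(len(y)), ba, bb])
    n, p = X.shape
    if n < p:
        raise UnderdeterminedFitError(
            f"{n} rows for a {p}-dimensional basis")
    if n < 10 * p:
        warnings.warn(f"only {n} rows for a {p}-dimensional basis; "
                      "the fitted surface may be unstable",
                      RuntimeWarning, stacklevel=2)

    lam = 0.0
    if spline_spec.penalty == "gcv":
        coef, lam = _gcv_ridge(X, y)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)

    model = ExpectedDensityModel(
        measure=measure, spline_spec=spline_spec, coefficients=coef,
        knots_age=t_age, knots_bmi=t_bmi, degree_age=d_age, degree_bmi=d_bmi,
        training_n=n,
        training_ranges={"age": (float(age.min()), float(age.max())),
                         "bmi": (float(bmi.min()), float(bmi.max()))},
        ridge_lambda=lam)
    resid = y - np.asarray(model.predict(age, bmi))
    q25, q50, q75 = np.quantile(resid, [0.25, 0.5, 0.75])  # type-7 default
    model.control_residual_quartiles = (float(q25), float(q50), float(q75))
    return model


def residualize(model: ExpectedDensityModel, age, bmi, observed
                ) -> DensityResidual:
    """Observed minus expected density on the model's transformed scale.

    Accepts scalars or arrays; inputs outside the training age/BMI range are
    clamped (with a warning) before prediction.
    """
    obs_t = model.transform(observed)
    pred = model.predict(age, bmi)
    value = obs_t - pred
    if np.ndim(value) == 0 or np.size(value) == 1:
        value = float(np.asarray(value).reshape(-1)[0])
    return DensityResidual(value=value, measure=model.measure)


def residualize_table(model: ExpectedDensityModel, table: pd.DataFrame
                      ) -> np.ndarray:
    """Vector of residuals for every row of a participant table."""
    col, _ = MEASURES[model.measure]
    r = residualize(model, table["age_mammogram"].to_numpy(),
                    table["bmi"].to_numpy(), table[col].to_numpy())
    return np.atleast_1d(np.asarray(r.value, dtype=float))


def residual_iqr(model: ExpectedDensityModel) -> tuple[float, float]:
    """(q25, q75) of the training-control residuals."""
    if model.control_residual_quartiles is None:
        raise StateError("model has no stored control residual quartiles")
    q25, _, q75 = model.control_residual_quartiles
    return (q25, q75)
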