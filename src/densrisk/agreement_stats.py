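"""Contingency-table statistics for density gradings and 2x2 risk factors.

Covers the pieces of the study's descriptive tables that are computable
from printed counts alone: weighted kappa between the clinical and
volumetric four-grade density readings, crude odds ratios with Woolf
confidence intervals for binary demographic contrasts, and Spearman rank
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import DomainError, InputError

__all__ = [
    "TwoByTwo", "weighted_kappa", "kappa_point", "crude_odds_ratio",
    "spearman_rho", "load_reference_crosstab", "load_reference_two_by_twos",
]

_Z = 1.959963984540054


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-status counts for a crude odds ratio."""

    case_exposed: float
    case_unexposed: float
    control_exposed: float
    control_unexposed: float

    def validate(self) -> None:
        cells = (self.case_exposed, self.case_unexposed,
                 self.control_exposed, self.control_unexposed)
        if any(c < 0 for c in cells):
            raise DomainError("2x2 counts must be non-negative")
        if sum(cells) == 0:
            raise DomainError("2x2 table is empty")


def _disagreement_weights(k: int, weighting: str) -> np.ndarray:
    i, j = np.indices((k, k))
    if weighting == "linear":
        return np.abs(i - j) / (k - 1)
    if weighting == "quadratic":
        return (i - j) ** 2 / (k - 1) ** 2
    raise InputError("weighting must be 'linear' or 'quadratic'")


def kappa_point(tab, weighting: str = "linear") -> float:
    """Weighted kappa point estimate of a k x k agreement table.

    kappa = 1 - sum(w * p_obs) / sum(w * p_exp), with disagreement weights
    ``|i-j|/(k-1)`` (linear) or ``(i-j)^2/(k-1)^2`` (quadratic) and expected
    proportions from the margin products.
    """
    tab = np.asarray(tab, dtype=float)
    if tab.ndim != 2 or tab.shape[0] != tab.shape[1] or tab.shape[0] < 2:
        raise InputError("agreement table must be square with k >= 2")
    if np.any(tab < 0):
        raise DomainError("counts must be non-negative")
    n = tab.sum()
    if n == 0:
        raise DomainError("agreement table is empty")
    p = tab / n
    w = _disagreement_weights(tab.shape[0], weighting)
    e = np.outer(p.sum(axis=1), p.sum(axis=0))
    return float(1.0 - (w * p).sum() / (w * e).sum())


def weighted_kappa(tab, weighting: str = "linear", n_boot: int = 2000,
                   seed: int = 0, ci_level: float = 0.95
                   ) -> tuple[float, tuple[float, float]]:
    """Weighted kappa with a multinomial-bootstrap percentile CI."""
    tab = np.asarray(tab, dtype=float)
    point = kappa_point(tab, weighting)
    n = int(tab.sum())
    p = (tab / n).ravel()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, p, size=n_boot).reshape(n_boot, *tab.shape)
    reps = np.array([kappa_point(d, weighting) for d in draws])
    a = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(reps, [a, 1.0 - a])
    return point, (float(lo), float(hi))


def crude_odds_ratio(t: TwoByTwo) -> tuple[float, tuple[float, float]]:
    """Crude odds ratio with the Woolf (log-normal) confidence interval.

    A zero cell triggers the 0.5 continuity correction with a warning; a
    zero margin even after correction is an error.
    """
    t.validate()
    a, b = float(t.case_exposed), float(t.case_unexposed)
    c, d = float(t.control_exposed), float(t.control_unexposed)
    if min(a, b, c, d) == 0:
        warnings.warn("zero cell in 2x2 table; applying 0.5 continuity "
                      "correction", RuntimeWarning, stacklevel=2)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a + b, c + d, a + c, b + d) == 0:
        raise DomainError("odds ratio undefined: zero margin")
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (float(or_),
            (float(or_ * np.exp(-_Z * se)), float(or_ * np.exp(_Z * se))))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (midranks for ties); NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("spearman_rho needs equal-length inputs of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("spearman correlation undefined for constant input",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(spearmanr(x, y).statistic)


# -- shipped reference counts ----------------------------------------------

def _read_data(name: str) -> pd.DataFrame:
    with resources.files("densrisk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_crosstab(which: str = "combined") -> pd.DataFrame:
    """Published clinical-vs-volumetric density grade cross-tabulation.

    ``which`` is ``'controls'``, ``'cases'`` or ``'combined'``; rows are the
    clinical grades 1-4, columns the volumetric grades 1-4.
    """
    if which not in ("controls", "cases", "combined"):
        raise InputError("which must be 'controls', 'cases' or 'combined'")
    ctrl = _read_data("density_grade_crosstab_controls.csv").set_index("birads")
    case = _read_data("density_grade_crosstab_cases.csv").set_index("birads")
    if which == "controls":
        return ctrl
    if which == "cases":
        return case
    return ctrl + case


def load_reference_two_by_twos() -> dict[str, dict]:
    """Published demographic 2x2 counts with the reported crude ORs."""
    df = _read_data("demography_two_by_two.csv")
    out = {}
    for _, row in df.iterrows():
        out[row["factor"]] = {
            "contrast": row["contrast"],
            "table": TwoByTwo(row["case_exposed"], row["case_unexposed"],
                              row["control_exposed"], row["control_unexposed"]),
            "reported_or": float(row["reported_or"]),
            "reported_ci": (float(row["reported_lo"]),
                            float(row["reported_hi"])),
        }
    return out
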