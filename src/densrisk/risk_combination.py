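"""Combine a density relative risk with an absolute 10-year risk.

The density residual carries risk information beyond the questionnaire
model, summarized as a per-woman relative risk ``exp(beta * residual)``
normalized so its mean over controls is one (adding density then leaves the
population-average risk essentially unchanged).  The combined 10-year risk
is formed on the hazard scale, ``1 - (1 - p)^rr``, which stays a valid
probability for any relative risk and is numerically close to ``p * rr``
for the small risks typical of screening populations.

Risks are percentages throughout this package's tables (3.17 means a 3.17%
10-year risk); only the hazard-scale arithmetic here converts to fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DomainError, EmptyInputError

__all__ = [
    "RiskAssessment", "StrataProportions", "control_normalizer",
    "density_relative_risk", "combine_risk", "risk_category",
    "risk_strata_proportions", "risk_histogram",
]

#: clinical action thresholds on the 10-year risk scale, percent
DEFAULT_THRESHOLDS = (2.0, 8.0)


class StrataProportions(NamedTuple):
    low: float
    average: float
    high: float


@dataclass
class RiskAssessment:
    """Baseline and density-combined 10-year risk for one woman."""

    tc10: float
    rr_density: float
    combined10: float
    category: str


def control_normalizer(control_residuals, beta: float) -> float:
    """Mean of exp(beta * residual) over the control set."""
    r = np.asarray(control_residuals, dtype=float)
    if r.size == 0:
        raise EmptyInputError("control residual set is empty")
    if not np.all(np.isfinite(r)):
        raise DomainError("control residuals must be finite")
    return float(np.mean(np.exp(beta * r)))


def density_relative_risk(residual, beta: float, normalizer: float):
    """Normalized relative risk exp(beta * residual) / normalizer.

    With ``normalizer = control_normalizer(controls, beta)`` the mean
    relative risk over the controls equals one by construction.
    """
    if normalizer <= 0:
        raise DomainError("normalizer must be > 0")
    r = np.asarray(residual, dtype=float)
    if not np.all(np.isfinite(r)):
        raise DomainError("residual must be finite")
    rr = np.exp(beta * r) / normalizer
    return float(rr) if rr.ndim == 0 else rr


def combine_risk(tc10, rr_density):
    """Combined 10-year risk (percent) on the hazard scale.

    combined = 100 * (1 - (1 - tc10/100)**rr); equal to the baseline when
    rr = 1 and strictly below 100 for any finite rr.
    """
    tc10 = np.asarray(tc10, dtype=float)
    rr = np.asarray(rr_density, dtype=float)
    if np.any((tc10 <= 0) | (tc10 >= 100)):
        raise DomainError("tc10 must be in (0, 100) percent")
    if np.any(rr <= 0):
        raise DomainError("rr_density must be > 0")
    combined = 100.0 * (1.0 - np.power(1.0 - tc10 / 100.0, rr))
    return float(combined) if combined.ndim == 0 else combined


def risk_category(combined10, thresholds=DEFAULT_THRESHOLDS):
    """'low' (< lower), 'average', or 'high' (>= upper).

    The strata must be exhaustive, so the boundary convention places a risk
    exactly at the upper threshold in the high stratum and one exactly at
    the lower threshold in the average stratum.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise DomainError("thresholds must be increasing")
    c = np.asarray(combined10, dtype=float)
    cat = np.where(c < lo, "low", np.where(c >= hi, "high", "average"))
    return str(cat) if cat.ndim == 0 else cat


def risk_strata_proportions(risks, thresholds=DEFAULT_THRESHOLDS
                            ) -> StrataProportions:
    """Fractions of women below, between, and at/above the thresholds."""
    r = np.asarray(risks, dtype=float)
    if r.size == 0:
        raise EmptyInputError("risk_strata_proportions: empty input")
    lo, hi = thresholds
    if not lo < hi:
        raise DomainError("thresholds must be increasing")
    n = r.size
    low = float(np.sum(r < lo) / n)
    high = float(np.sum(r >= hi) / n)
    return StrataProportions(low=low, average=float(1.0 - low - high),
                             high=high)


def risk_histogram(risks, bin_width: float = 0.5
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(bin_edges, counts) for a report histogram; counts conserve n."""
    r = np.asarray(risks, dtype=float)
    if r.size == 0:
        raise EmptyInputError("risk_histogram: empty input")
    if bin_width <= 0:
        raise DomainError("bin_width must be > 0")
    top = np.ceil(r.max() / bin_width) * bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    counts, edges = np.histogram(r, bins=edges)
    return edges, counts
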