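"""Sigmoidal growth-curve families and the Gaussian observation model.

Four classical three-parameter growth functions for body weight Y(t) as a
function of age t (days):

========================  =============================================
Logistic                  Y = A / (1 + exp(K (B - t)))
Gompertz                  Y = A * exp(-exp(K (B - t)))
von Bertalanffy           Y = A * (1 - (1/3) exp(K (B - t)))**3
Brody                     Y = A * (1 - B exp(-K t))
========================  =============================================

``A`` is the asymptotic (mature) weight in grams; ``B`` is the abscissa of
the inflection point in days (for Brody, a dimensionless shape constant in
(0, 1] with no inflection interpretation); ``K`` is the relative growth-rate
constant per day.  In the von Bertalanffy parameterization used here the
inflection occurs at t = B with weight (2/3)**3 * A ~= 0.296 A, and for the
Gompertz at t = B with weight A/e ~= 0.368 A.

Observations are modelled as y_i ~ Normal(Y(t_i), sigma^2), independent
across ages (homoscedastic Gaussian errors on the mean weights).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

FAMILIES = ("logistic", "gompertz", "von_bertalanffy", "brody")

SEXES = ("female", "male")


class InvalidFamilyError(ValueError):
    """Unknown growth-curve family tag."""


class InvalidParameterError(ValueError):
    """Growth-curve or observation-model parameter outside its support."""


@dataclass(frozen=True)
class GrowthCurve:
    """A growth-curve family tag plus its three parameters.

    Parameters
    ----------
    family : str
        One of ``logistic``, ``gompertz``, ``von_bertalanffy``, ``brody``.
    A : float
        Asymptotic weight, grams.  Must be positive.
    B : float
        Inflection abscissa, days — except for ``brody``, where B is a
        dimensionless shape constant constrained to (0, 1] so that the
        weight at age 0 is non-negative.
    K : float
        Relative growth-rate constant, per day.  Must be positive.
    """

    family: str
    A: float
    B: float
    K: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidFamilyError(
                f"unknown growth-curve family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        if not (self.A > 0):
            raise InvalidParameterError(f"A must be > 0, got {self.A}")
        if not (self.K > 0):
            raise InvalidParameterError(f"K must be > 0, got {self.K}")
        if self.family == "brody" and not (0 < self.B <= 1):
            raise InvalidParameterError(
                f"Brody shape constant B must lie in (0, 1], got {self.B}"
            )


@dataclass(frozen=True)
class ObservationModel:
    """A growth curve plus the residual SD of the Gaussian errors."""

    curve: GrowthCurve
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class WeightSeries:
    """Mean body weights observed at a strictly increasing set of ages."""

    ages: np.ndarray
    weights: np.ndarray
    sex: str

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "weights", weights)
        if self.sex not in SEXES:
            raise InvalidParameterError(
                f"sex must be one of {SEXES}, got {self.sex!r}"
            )
        if ages.ndim != 1 or ages.shape != weights.shape:
            raise InvalidParameterError("ages and weights must be equal-length 1-d")
        if len(ages) == 0:
            raise InvalidParameterError("empty weight series")
        if np.any(ages < 0) or np.any(np.diff(ages) <= 0):
            raise InvalidParameterError("ages must be non-negative, strictly increasing")
        if np.any(weights[ages > 0] <= 0) or np.any(weights < 0):
            raise InvalidParameterError("weights must be positive (age 0 may be zero)")

    def __len__(self) -> int:
        return len(self.ages)


def mean_curve(family: str, A, B, K, t):
    """Expected weight under ``family`` with broadcastable parameter arrays.

    Vectorized workhorse behind :func:`mean_weight`; also used by the model
    comparison code to evaluate thousands of posterior draws at once.
    """
    if family not in FAMILIES:
        raise InvalidFamilyError(f"unknown growth-curve family {family!r}")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    K = np.asarray(K, dtype=float)
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        if family == "logistic":
            return A / (1.0 + np.exp(K * (B - t)))
        if family == "gompertz":
            return A * np.exp(-np.exp(K * (B - t)))
        if family == "von_bertalanffy":
            return A * (1.0 - np.exp(K * (B - t)) / 3.0) ** 3
        # brody
        return A * (1.0 - B * np.exp(-K * t))


def mean_weight(curve: GrowthCurve, t):
    """Expected weight (grams) at age ``t`` (days, scalar or array)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("age t must be non-negative")
    out = mean_curve(curve.family, curve.A, curve.B, curve.K, t)
    return float(out) if out.ndim == 0 else out


#: Weight fraction Y(B)/A at the inflection abscissa, by family.
INFLECTION_FRACTION = {
    "logistic": 0.5,
    "gompertz": math.exp(-1.0),
    "von_bertalanffy": (2.0 / 3.0) ** 3,
}


def inflection_point(curve: GrowthCurve) -> tuple[float, float] | None:
    """Inflection (age in days, weight in grams), or None for Brody.

    The logistic inflects at A/2, the Gompertz at A/e ~= 0.368 A and the
    von Bertalanffy (this parameterization) at (2/3)^3 A ~= 0.296 A, all at
    age t = B.  The Brody form is concave throughout and has no inflection.
    """
    if curve.family == "brody":
        return None
    return curve.B, INFLECTION_FRACTION[curve.family] * curve.A


def pointwise_log_likelihood(model: ObservationModel, data: WeightSeries) -> np.ndarray:
    """Per-observation Gaussian log densities log N(y_i | Y(t_i), sigma^2)."""
    mu = mean_weight(model.curve, data.ages)
    return stats.norm.logpdf(data.weights, loc=mu, scale=model.sigma)


def log_likelihood(model: ObservationModel, data: WeightSeries) -> float:
    """Total Gaussian log likelihood; the sum of the pointwise values."""
    return float(np.sum(pointwise_log_likelihood(model, data)))
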