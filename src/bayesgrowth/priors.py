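"""Elicited prior distributions for the growth parameters, per sex.

The informative priors were elicited from a meta-analysis of growth studies
on breeds comparable to the Utrerana chicken: Normal priors for the
asymptotic weight A and the inflection abscissa B (their supports cover the
plausible ranges), and a Gamma prior for the rate constant K (which keeps K
positive and at the right order of magnitude, ~0.015/day).  The defaults:

    sex      A ~ Normal(mu, sd)     B ~ Normal(mu, sd)   K ~ Gamma(shape, rate)
    female   (1950, 166.81)         (62, 5.32)           (25.60, 1496.80)
    male     (2800, 290.62)         (70, 4.43)           (17.740, 1144.55)

The Normal scale entries are standard deviations, and the male K shape is
17.740 (its implied prior mean 17.740/1144.55 ~= 0.0155/day matches the
scale of fitted K values; a shape in the tens of thousands would put the
prior mean near 15/day, i.e. full growth in hours).

The residual SD gets a weakly-informative half-t(3) prior whose scale
should be set to the sample SD of the observed weights (the common default
of Bayesian regression software); a fixed fallback scale of 700 g — the
right order for chicken mean-weight series spanning 0 to ~2.5 kg — is used
when no data are at hand.

For the Brody family B is a dimensionless shape constant in (0, 1], so the
day-scale Normal prior is replaced by Normal(0.95, 0.05) truncated to
(0, 1].

The module also provides the prior density of a between-sex parameter
difference, the denominator of the Savage–Dickey Bayes factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .models import SEXES, GrowthCurve

PRIOR_FAMILIES = ("normal", "gamma", "half_t", "truncated_normal")

#: Default half-t scale (grams) used when no weight data are available to
#: set it from; pass ``sigma_scale=np.std(weights)`` for a data-driven scale.
DEFAULT_SIGMA_SCALE = 700.0


class InvalidPriorError(ValueError):
    """Malformed prior specification or unsupported prior family."""


@dataclass(frozen=True)
class PriorSpec:
    """One univariate prior: a family tag plus its hyperparameters.

    Families and hyperparameters:

    - ``normal``: ``loc`` (mean), ``scale`` (standard deviation)
    - ``gamma``: ``shape`` alpha, ``rate`` beta (mean alpha/beta)
    - ``half_t``: ``df`` degrees of freedom, ``scale``; support (0, inf)
    - ``truncated_normal``: ``loc``, ``scale``, ``low``, ``high``
    """

    family: str
    loc: float = 0.0
    scale: float = 1.0
    shape: float = 1.0
    rate: float = 1.0
    df: float = 3.0
    low: float = -math.inf
    high: float = math.inf

    def __post_init__(self) -> None:
        if self.family not in PRIOR_FAMILIES:
            raise InvalidPriorError(f"unsupported prior family {self.family!r}")
        if self.family in ("normal", "half_t", "truncated_normal") and self.scale <= 0:
            raise InvalidPriorError("scale must be positive")
        if self.family == "gamma" and (self.shape <= 0 or self.rate <= 0):
            raise InvalidPriorError("gamma shape and rate must be positive")
        if self.family == "half_t" and self.df <= 0:
            raise InvalidPriorError("half_t df must be positive")
        if self.family == "truncated_normal" and not self.low < self.high:
            raise InvalidPriorError("truncation bounds must satisfy low < high")

    def _dist(self):
        if self.family == "normal":
            return stats.norm(loc=self.loc, scale=self.scale)
        if self.family == "gamma":
            return stats.gamma(a=self.shape, scale=1.0 / self.rate)
        if self.family == "truncated_normal":
            a = (self.low - self.loc) / self.scale
            b = (self.high - self.loc) / self.scale
            return stats.truncnorm(a, b, loc=self.loc, scale=self.scale)
        raise InvalidPriorError(self.family)

    def logpdf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.family == "half_t":
            out = np.where(
                x > 0,
                math.log(2.0) + stats.t.logpdf(x, df=self.df, scale=self.scale),
                -np.inf,
            )
        else:
            out = self._dist().logpdf(x)
        return float(out) if np.ndim(out) == 0 else out

    def pdf(self, x) -> np.ndarray | float:
        return np.exp(self.logpdf(x))

    def rvs(self, rng: np.random.Generator, size=None):
        if self.family == "half_t":
            return np.abs(stats.t.rvs(df=self.df, scale=self.scale,
                                      size=size, random_state=rng))
        return self._dist().rvs(size=size, random_state=rng)

    @property
    def mean(self) -> float:
        if self.family == "half_t":
            # mean of |t_df| * scale, finite for df > 1
            d = self.df
            if d <= 1:
                return math.inf
            return float(
                self.scale * 2 * math.sqrt(d / math.pi)
                * math.gamma((d + 1) / 2) / ((d - 1) * math.gamma(d / 2))
            )
        return float(self._dist().mean())

    @property
    def support(self) -> tuple[float, float]:
        if self.family == "normal":
            return (-math.inf, math.inf)
        if self.family in ("gamma", "half_t"):
            return (0.0, math.inf)
        return (self.low, self.high)


@dataclass(frozen=True)
class PriorSet:
    """The per-sex priors for (A, B, K, sigma)."""

    sex: str
    A: PriorSpec
    B: PriorSpec
    K: PriorSpec
    sigma: PriorSpec

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise InvalidPriorError(f"sex must be one of {SEXES}, got {self.sex!r}")

    def __getitem__(self, name: str) -> PriorSpec:
        if name not in ("A", "B", "K", "sigma"):
            raise KeyError(name)
        return getattr(self, name)


_TABLE = {
    "female": {
        "A": ("normal", 1950.0, 166.81),
        "B": ("normal", 62.0, 5.32),
        "K": ("gamma", 25.60, 1496.80),
    },
    "male": {
        "A": ("normal", 2800.0, 290.62),
        "B": ("normal", 70.0, 4.43),
        "K": ("gamma", 17.740, 1144.55),
    },
}


def default_priors(
    sex: str,
    family: str | None = None,
    sigma_scale: float = DEFAULT_SIGMA_SCALE,
) -> PriorSet:
    """Elicited priors for one sex.

    Parameters
    ----------
    sex : {"female", "male"}
    family : str, optional
        Growth-curve family the priors will be used with.  Only ``brody``
        changes anything: its dimensionless B gets Normal(0.95, 0.05)
        truncated to (0, 1] instead of the day-scale Normal prior.
    sigma_scale : float
        Scale of the half-t(3) prior on the residual SD, grams.  Set this
        to the sample SD of the weights being fitted.
    """
    if sex not in _TABLE:
        raise InvalidPriorError(f"unknown sex label {sex!r}")
    row = _TABLE[sex]
    a = PriorSpec("normal", loc=row["A"][1], scale=row["A"][2])
    if family == "brody":
        b = PriorSpec("truncated_normal", loc=0.95, scale=0.05, low=0.0, high=1.0)
    else:
        b = PriorSpec("normal", loc=row["B"][1], scale=row["B"][2])
    k = PriorSpec("gamma", shape=row["K"][1], rate=row["K"][2])
    sig = PriorSpec("half_t", df=3.0, scale=sigma_scale)
    return PriorSet(sex=sex, A=a, B=b, K=k, sigma=sig)


def log_prior(priors: PriorSet, curve: GrowthCurve, sigma: float) -> float:
    """Joint log prior density at (A, B, K, sigma); -inf outside support."""
    total = (
        priors.A.logpdf(curve.A)
        + priors.B.logpdf(curve.B)
        + priors.K.logpdf(curve.K)
        + priors.sigma.logpdf(sigma)
    )
    return float(total)


def difference_prior_density_at(
    prior_male: PriorSpec,
    prior_female: PriorSpec,
    delta: float,
    *,
    method: str = "auto",
    seed: int | None = None,
    n_mc: int = 200_000,
) -> float:
    """Prior density of theta_male - theta_female at ``delta``.

    Under prior independence, the normal-normal case is closed form
    (Normal(mu_m - mu_f, sqrt(s_m^2 + s_f^2))); the gamma-gamma case is
    computed by numerical convolution; any other pair falls back to a
    seeded Monte-Carlo + Gaussian-KDE estimate (``method="mc"`` forces it).
    """
    if method not in ("auto", "exact", "mc"):
        raise InvalidPriorError(f"unknown method {method!r}")
    pm, pf = prior_male, prior_female
    if method != "mc" and pm.family == "normal" and pf.family == "normal":
        scale = math.hypot(pm.scale, pf.scale)
        return float(stats.norm.pdf(delta, loc=pm.loc - pf.loc, scale=scale))
    if method != "mc" and pm.family == "gamma" and pf.family == "gamma":
        # f_D(d) = int f_m(x) f_f(x - d) dx over x > max(0, d)
        lo = max(0.0, delta)
        fm = stats.gamma(a=pm.shape, scale=1.0 / pm.rate)
        ff = stats.gamma(a=pf.shape, scale=1.0 / pf.rate)

        def integrand(x):
            return fm.pdf(x) * ff.pdf(x - delta)

        # split the integral at the two prior mass centres so quad does not
        # miss narrow peaks far from the lower limit
        cuts = sorted({max(lo, fm.mean()), max(lo, delta + ff.mean())})
        total = 0.0
        left = lo
        for c in cuts:
            if c > left:
                total += integrate.quad(integrand, left, c, limit=200)[0]
                left = c
        total += integrate.quad(integrand, left, np.inf, limit=200)[0]
        return float(total)
    if method == "exact":
        raise InvalidPriorError(
            f"no exact difference density for {pm.family!r} - {pf.family!r}"
        )
    rng = np.random.default_rng(seed)
    draws = pm.rvs(rng, size=n_mc) - pf.rvs(rng, size=n_mc)
    kde = stats.gaussian_kde(draws)
    return float(kde(delta)[0])
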