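"""Predictive model comparison: WAIC, PSIS-LOO and model ranking.

Both criteria start from the pointwise log-likelihood matrix ll[s, i] of
each posterior draw s at each observation i.

WAIC:  lppd   = sum_i log mean_s exp(ll[s, i])
       p_waic = sum_i var_s ll[s, i]          (effective parameter count)
       elpd_waic = lppd - p_waic;  WAIC = -2 elpd_waic.

PSIS-LOO estimates leave-one-out predictive density by importance
sampling with ratios r[s, i] = exp(-ll[s, i]) (full posterior relative to
the leave-one-out posterior).  Raw ratios can have infinite variance, so
the upper 20% tail of each observation's ratios is replaced by expected
order statistics of a generalized Pareto distribution fitted to that tail
by the method of moments, capped at the largest raw ratio.  The fitted
Pareto shape k is reported per observation; k > 0.7 marks the estimate as
unreliable.  LOO-IC = -2 elpd_loo.

Standard errors use sqrt(n * var) over the pointwise contributions.
Lower LOO-IC/WAIC (higher ELPD) indicates better expected predictive
performance; differences smaller than one standard error are flagged as
equivalent rather than treated as a real ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .models import WeightSeries, mean_curve
from .sampler import FitResult, PosteriorDraws

PARETO_K_WARN = 0.7
TAIL_FRACTION = 0.20


class ModelSelectionError(ValueError):
    """Ill-formed pointwise log-likelihood input."""


def pointwise_loglik_matrix(
    family: str, draws: PosteriorDraws, data: WeightSeries
) -> np.ndarray:
    """(total draws) x (observations) Gaussian log-density matrix."""
    need = {"A", "B", "K", "sigma"}
    if not need.issubset(draws.names):
        raise ModelSelectionError(f"draws must contain {sorted(need)}")
    A = draws.pooled("A")[:, None]
    B = draws.pooled("B")[:, None]
    K = draws.pooled("K")[:, None]
    sigma = draws.pooled("sigma")[:, None]
    mu = mean_curve(family, A, B, K, data.ages[None, :])
    return stats.norm.logpdf(data.weights[None, :], loc=mu, scale=sigma)


@dataclass(frozen=True)
class WaicResult:
    elpd_waic: float
    p_waic: float
    waic: float
    se_elpd: float
    pointwise: np.ndarray  # per-observation elpd contributions

    @property
    def se_waic(self) -> float:
        return 2.0 * self.se_elpd


@dataclass(frozen=True)
class LooResult:
    elpd_loo: float
    loo_ic: float
    se_elpd: float
    pareto_k: np.ndarray

    @property
    def se_loo_ic(self) -> float:
        return 2.0 * self.se_elpd

    @property
    def max_pareto_k(self) -> float:
        finite = self.pareto_k[np.isfinite(self.pareto_k)]
        return float(finite.max()) if finite.size else -math.inf


def _check_pll(pll) -> np.ndarray:
    pll = np.asarray(pll, dtype=float)
    if pll.ndim != 2:
        raise ModelSelectionError("pointwise log-likelihood must be 2-d (draws x obs)")
    if not np.all(np.isfinite(pll)):
        raise ModelSelectionError("non-finite pointwise log-likelihood values")
    return pll


def compute_waic(pll) -> WaicResult:
    """WAIC from a draws-by-observations log-likelihood matrix."""
    pll = _check_pll(pll)
    S, n = pll.shape
    if S < 2:
        raise ModelSelectionError("WAIC needs at least 2 draws (variance term)")
    lppd_i = logsumexp(pll, axis=0) - math.log(S)
    p_i = pll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    se = math.sqrt(n * elpd_i.var(ddof=1)) if n > 1 else 0.0
    elpd = float(elpd_i.sum())
    return WaicResult(
        elpd_waic=elpd,
        p_waic=float(p_i.sum()),
        waic=-2.0 * elpd,
        se_elpd=se,
        pointwise=elpd_i,
    )


def _gpd_fit_mom(exceedances: np.ndarray) -> tuple[float, float]:
    """Method-of-moments generalized-Pareto fit (shape k, scale sigma).

    Convention: survivor function (1 + k z / sigma)^(-1/k); k > 0 is a
    heavy tail, valid for k < 1/2 (finite variance needed by MoM).
    """
    m = float(exceedances.mean())
    v = float(exceedances.var(ddof=1))
    if v <= 0 or m <= 0:
        return 0.0, max(m, np.finfo(float).tiny)
    k = 0.5 * (1.0 - m * m / v)
    sigma = m * (1.0 - k)
    return k, sigma


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma / k * ((1.0 - p) ** (-k) - 1.0)


def _smooth_tail(log_ratios: np.ndarray) -> tuple[np.ndarray, float]:
    """Pareto-smooth one observation's log importance ratios.

    Returns the smoothed log ratios and the fitted tail shape k (NaN if
    the tail was degenerate and left untouched).
    """
    S = len(log_ratios)
    M = int(math.ceil(TAIL_FRACTION * S))
    if M < 5:
        return log_ratios, math.nan
    order = np.argsort(log_ratios)
    tail_idx = order[S - M:]
    cut = log_ratios[order[S - M - 1]]  # largest non-tail log ratio
    # work on the ratio scale relative to the cut to avoid overflow
    exceed = np.expm1(log_ratios[tail_idx] - cut)
    if np.all(exceed <= 0) or exceed.var(ddof=1) <= 0:
        return log_ratios, math.nan
    k, sigma = _gpd_fit_mom(exceed)
    p = (np.arange(1, M + 1) - 0.5) / M  # expected order-statistic positions
    smoothed = np.log1p(_gpd_quantile(p, k, sigma)) + cut
    cap = log_ratios[tail_idx].max()
    smoothed = np.minimum(smoothed, cap)
    out = log_ratios.copy()
    # assign smoothed quantiles to the tail draws in ascending order
    out[tail_idx[np.argsort(log_ratios[tail_idx], kind="stable")]] = smoothed
    return out, k


def compute_psis_loo(pll) -> LooResult:
    """PSIS-LOO from a draws-by-observations log-likelihood matrix."""
    pll = _check_pll(pll)
    S, n = pll.shape
    if S < 100:
        warnings.warn(
            f"only {S} draws; PSIS-LOO is unreliable below ~100 draws",
            stacklevel=2,
        )
    elpd_i = np.empty(n)
    ks = np.empty(n)
    for i in range(n):
        lw, k = _smooth_tail(-pll[:, i])
        ks[i] = k
        lw = lw - logsumexp(lw)  # normalised log weights
        elpd_i[i] = logsumexp(lw + pll[:, i])
    bad = np.isfinite(ks) & (ks > PARETO_K_WARN)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} observation(s) with Pareto k > {PARETO_K_WARN}; "
            "their LOO contributions may be unreliable",
            stacklevel=2,
        )
    elpd = float(elpd_i.sum())
    se = math.sqrt(n * elpd_i.var(ddof=1)) if n > 1 else 0.0
    return LooResult(elpd_loo=elpd, loo_ic=-2.0 * elpd, se_elpd=se, pareto_k=ks)


@dataclass(frozen=True)
class ComparisonRow:
    """One model's comparison indices (mirrors a comparison-table row)."""

    model: str
    elpd_loo: float
    se_elpd_loo: float
    loo_ic: float
    se_loo_ic: float
    waic: float
    se_waic: float
    max_pareto_k: float = math.nan
    sex: str | None = None

    def __post_init__(self) -> None:
        if not math.isclose(self.loo_ic, -2.0 * self.elpd_loo, rel_tol=1e-9,
                            abs_tol=1e-6):
            raise ModelSelectionError("loo_ic must equal -2 * elpd_loo")


def comparison_row(
    model: str, loo: LooResult, waic: WaicResult, sex: str | None = None
) -> ComparisonRow:
    return ComparisonRow(
        model=model,
        elpd_loo=loo.elpd_loo,
        se_elpd_loo=loo.se_elpd,
        loo_ic=loo.loo_ic,
        se_loo_ic=loo.se_loo_ic,
        waic=waic.waic,
        se_waic=waic.se_waic,
        max_pareto_k=loo.max_pareto_k,
        sex=sex,
    )


def compare_fit(fit: FitResult) -> ComparisonRow:
    """LOO + WAIC indices for one fitted model."""
    pll = pointwise_loglik_matrix(fit.family, fit.draws, fit.data)
    return comparison_row(fit.family, compute_psis_loo(pll), compute_waic(pll),
                          sex=fit.sex)


def combine_sexes(rows: list[ComparisonRow]) -> list[ComparisonRow]:
    """Sum indices across sexes per model (SEs add in quadrature).

    Used when a single family must serve both sexes, as the dimorphism
    test requires.
    """
    by_model: dict[str, list[ComparisonRow]] = {}
    for r in rows:
        by_model.setdefault(r.model, []).append(r)
    out = []
    for model, grp in by_model.items():
        out.append(
            ComparisonRow(
                model=model,
                elpd_loo=sum(r.elpd_loo for r in grp),
                se_elpd_loo=math.hypot(*[r.se_elpd_loo for r in grp]),
                loo_ic=sum(r.loo_ic for r in grp),
                se_loo_ic=math.hypot(*[r.se_loo_ic for r in grp]),
                waic=sum(r.waic for r in grp),
                se_waic=math.hypot(*[r.se_waic for r in grp]),
                max_pareto_k=max(r.max_pareto_k for r in grp),
                sex="combined",
            )
        )
    return out


def rank_models(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Rank models by LOO-IC (ascending; ties by WAIC, then name).

    The ``equivalent_to_best`` column flags models whose LOO-IC is within
    one standard error of the best model's — differences that small do not
    distinguish predictive performance.
    """
    if len(rows) < 2:
        raise ModelSelectionError("ranking needs at least 2 models")
    ordered = sorted(rows, key=lambda r: (r.loo_ic, r.waic, r.model))
    best = ordered[0]
    recs = []
    for rank, r in enumerate(ordered, start=1):
        d = r.loo_ic - best.loo_ic
        recs.append(
            {
                "rank": rank,
                "model": r.model,
                "sex": r.sex,
                "loo_ic": r.loo_ic,
                "se_loo_ic": r.se_loo_ic,
                "waic": r.waic,
                "se_waic": r.se_waic,
                "elpd_loo": r.elpd_loo,
                "se_elpd_loo": r.se_elpd_loo,
                "delta_loo_ic": d,
                "equivalent_to_best": bool(d < max(r.se_loo_ic, 1e-12)),
                "max_pareto_k": r.max_pareto_k,
            }
        )
    return pd.DataFrame(recs)
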