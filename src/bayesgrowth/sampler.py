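"""Posterior sampling and MCMC diagnostics for the growth models.

The posterior p(A, B, K, sigma | y) is proportional to the Gaussian
likelihood of the weight series times the elicited priors.  It is sampled
with an adaptive Metropolis-Hastings scheme:

1. A Laplace approximation (L-BFGS-B posterior mode, inverse
   finite-difference Hessian) shapes the initial random-walk proposal.
2. Chains start from independent prior draws — overdispersed starts, so
   the Gelman-Rubin diagnostic is meaningful — and warm up through three
   windows of cross-chain adaptation: each window re-estimates the
   posterior covariance from the chains' recent history (average
   within-chain covariance, excluding chains stranded far from the bulk)
   and rebuilds two proposals, a (2.38^2/d)-scaled random walk with
   Robbins-Monro step-size tuning toward 30% acceptance, and a
   multivariate Student-t(5) independence proposal over the bulk.
3. After warmup the kernel is frozen (alternating independence and
   random-walk Metropolis-Hastings steps), so the retained draws target
   the exact posterior.

The sampling engine is pluggable in principle — the contract is the
posterior distribution, not the algorithm — and the conjugate-oracle tests
pin that contract down.

Diagnostics follow standard practice: the Gelman-Rubin potential scale
reduction factor R-hat (split-chain by default), trace plots, and
posterior summaries with shortest 95% HPD intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import solve_triangular

from .models import WeightSeries, mean_curve
from .priors import PriorSet

PARAM_NAMES = ("A", "B", "K", "sigma")

#: Convergence band for R-hat recommended for these models.
RHAT_BAND = (0.99, 1.01)


class SamplingError(RuntimeError):
    """Sampler could not be initialized or run on the given inputs."""


#: Acceptance statistics of the most recent :func:`sample_posterior` call
#: (per chain, sampling phase); purely informational.
LAST_RUN_STATS: dict = {}


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings.

    Defaults mirror a standard 4-chain setup: 4,000 iterations per chain
    with the first 25% discarded as warmup, leaving 3,000 retained draws
    per chain (12,000 pooled).
    """

    n_chains: int = 4
    n_iterations: int = 4000
    warmup_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iterations < 4:
            raise ValueError("need at least 1 chain and 4 iterations")
        if not 0 <= self.warmup_fraction < 1:
            raise ValueError("warmup_fraction must be in [0, 1)")

    @property
    def n_warmup(self) -> int:
        return int(round(self.n_iterations * self.warmup_fraction))

    @property
    def n_retained(self) -> int:
        return self.n_iterations - self.n_warmup


@dataclass(frozen=True)
class PosteriorDraws:
    """Post-warmup draws, organised as (n_chains, n_draws) per parameter."""

    names: tuple[str, ...]
    chains: np.ndarray  # shape (n_chains, n_draws, n_params)

    def __post_init__(self) -> None:
        arr = np.asarray(self.chains, dtype=float)
        object.__setattr__(self, "chains", arr)
        object.__setattr__(self, "names", tuple(self.names))
        if arr.ndim != 3 or arr.shape[2] != len(self.names):
            raise ValueError("chains must have shape (n_chains, n_draws, n_params)")
        if arr.shape[1] == 0:
            raise ValueError("empty draws")

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def n_draws(self) -> int:
        return self.chains.shape[1]

    def per_chain(self, name: str) -> np.ndarray:
        """(n_chains, n_draws) array for one parameter."""
        return self.chains[:, :, self.names.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return self.per_chain(name).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long format: columns chain, iteration, then one per parameter."""
        n_c, n_d, _ = self.chains.shape
        out = {
            "chain": np.repeat(np.arange(n_c), n_d),
            "iteration": np.tile(np.arange(n_d), n_c),
        }
        for j, name in enumerate(self.names):
            out[name] = self.chains[:, :, j].reshape(-1)
        return pd.DataFrame(out)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PosteriorDraws":
        names = tuple(c for c in frame.columns if c not in ("chain", "iteration"))
        chains = []
        for c in sorted(frame["chain"].unique()):
            sub = frame[frame["chain"] == c].sort_values("iteration")
            chains.append(sub[list(names)].to_numpy())
        return cls(names=names, chains=np.stack(chains))


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter R-hat values and an overall pass flag."""

    rhat: dict[str, float]
    band: tuple[float, float] = RHAT_BAND

    @property
    def converged(self) -> bool:
        lo, hi = self.band
        return all(
            (not math.isnan(v)) and lo <= v <= hi for v in self.rhat.values()
        )

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


@dataclass(frozen=True)
class FitResult:
    """A fitted model: family, sex, draws and the inputs used."""

    family: str
    data: WeightSeries
    priors: PriorSet
    draws: PosteriorDraws
    convergence: ConvergenceReport

    @property
    def sex(self) -> str:
        return self.data.sex


# ---------------------------------------------------------------------------
# log posterior plumbing

_BOUNDS = {
    "A": (1e-6, None),
    "B": (None, None),
    "K": (1e-9, None),
    "sigma": (1e-9, None),
}
_BRODY_B_BOUNDS = (1e-6, 1.0)


_LOG_2PI = math.log(2.0 * math.pi)


def _scalar_logpdf(spec):
    """Closed-form scalar log density for one PriorSpec (hot-loop fast)."""
    if spec.family == "normal":
        loc, scale = spec.loc, spec.scale
        const = -math.log(scale) - 0.5 * _LOG_2PI

        def f(x):
            z = (x - loc) / scale
            return const - 0.5 * z * z

    elif spec.family == "gamma":
        a, rate = spec.shape, spec.rate
        const = a * math.log(rate) - math.lgamma(a)

        def f(x):
            if x <= 0:
                return -math.inf
            return const + (a - 1.0) * math.log(x) - rate * x

    elif spec.family == "half_t":
        df, scale = spec.df, spec.scale
        const = (
            math.log(2.0)
            + math.lgamma((df + 1.0) / 2.0)
            - math.lgamma(df / 2.0)
            - 0.5 * math.log(df * math.pi)
            - math.log(scale)
        )

        def f(x):
            if x <= 0:
                return -math.inf
            z = x / scale
            return const - (df + 1.0) / 2.0 * math.log1p(z * z / df)

    elif spec.family == "truncated_normal":
        from scipy import stats as _st

        loc, scale, lo, hi = spec.loc, spec.scale, spec.low, spec.high
        z_mass = _st.norm.cdf((hi - loc) / scale) - _st.norm.cdf((lo - loc) / scale)
        const = -math.log(scale) - 0.5 * _LOG_2PI - math.log(z_mass)

        def f(x):
            if not lo <= x <= hi:
                return -math.inf
            z = (x - loc) / scale
            return const - 0.5 * z * z

    else:  # pragma: no cover - PriorSpec validates families
        raise ValueError(spec.family)
    return f


def _make_log_post(family, data, priors, fixed):
    """Build the (unnormalised) log-posterior over the free parameters.

    For the Brody family the free B lives on the logit scale internally —
    its support (0, 1] would otherwise squeeze the posterior against a
    hard boundary and ruin Gaussian-shaped proposals — so the returned
    ``jB`` gives B's index in the sampled vector (None when no transform
    applies) and ``log_post`` includes the change-of-variables Jacobian
    log B(1-B).
    """
    fixed = dict(fixed or {})
    free = [n for n in PARAM_NAMES if n not in fixed]
    ages = np.asarray(data.ages, dtype=float)
    y = np.asarray(data.weights, dtype=float)
    n = len(y)
    prior_fns = {name: _scalar_logpdf(priors[name]) for name in PARAM_NAMES}
    brody = family == "brody"
    jB = free.index("B") if brody and "B" in free else None

    def log_post(vec):
        p = dict(fixed)
        p.update(zip(free, vec))
        jac = 0.0
        if jB is not None:
            u = p["B"]
            if abs(u) > 500.0:  # expit under/overflow guard
                return -np.inf
            b = 1.0 / (1.0 + math.exp(-u))
            # log B(1-B) in a form stable when b rounds to exactly 0 or 1
            jac = -abs(u) - 2.0 * math.log1p(math.exp(-abs(u)))
            p["B"] = b
        A, B, K, sigma = p["A"], p["B"], p["K"], p["sigma"]
        if A <= 0 or K <= 0 or sigma <= 0:
            return -np.inf
        if brody and not 0 < B <= 1:
            return -np.inf
        lp = jac
        for name in free:
            lp += prior_fns[name](p[name])
            if lp == -math.inf:
                return -np.inf
        mu = mean_curve(family, A, B, K, ages)
        resid = y - mu
        lp += -0.5 * n * _LOG_2PI - n * math.log(sigma) \
            - 0.5 * float(resid @ resid) / (sigma * sigma)
        return lp

    return free, log_post, jB


def _fd_hessian(f, x, rel_step=1e-4):
    """Central finite-difference Hessian of scalar f at x."""
    d = len(x)
    h = np.maximum(np.abs(x) * rel_step, 1e-8)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                val = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                val = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return H


def _laplace_cov(family, data, priors, fixed, free, log_post, jB=None):
    """MAP + inverse finite-difference Hessian -> proposal covariance.

    The optimisation and differentiation run in prior-standardised
    coordinates (parameters divided by their prior SDs) because the raw
    scales span five orders of magnitude (A ~ 2000 g vs K ~ 0.015/day),
    which defeats finite-difference steps on the natural scale.
    """
    start = []
    prior_sd = []
    for idx, name in enumerate(free):
        spec = priors[name]
        if idx == jB:
            # B on the logit scale: delta-method SD of logit(B) at the
            # prior location
            loc = min(max(spec.loc, 1e-3), 1 - 1e-3)
            start.append(math.log(loc / (1.0 - loc)))
            prior_sd.append(spec.scale / (loc * (1.0 - loc)))
        elif spec.family == "gamma":
            start.append(spec.shape / spec.rate)
            prior_sd.append(math.sqrt(spec.shape) / spec.rate)
        elif spec.family == "half_t":
            # the residual-SD mode is typically far below the half-t scale
            start.append(0.2 * spec.scale)
            prior_sd.append(spec.scale)
        else:
            start.append(spec.loc)
            prior_sd.append(spec.scale)
    start = np.array(start)
    prior_sd = np.array(prior_sd)

    bounds = []
    for i, name in enumerate(free):
        lo, hi = (None, None) if i == jB else _BOUNDS[name]
        bounds.append(
            (None if lo is None else lo / prior_sd[i],
             None if hi is None else hi / prior_sd[i])
        )

    def neg_std(v):
        val = log_post(v * prior_sd)
        return math.inf if not np.isfinite(val) else -val

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            neg_std, start / prior_sd, method="L-BFGS-B", bounds=bounds
        )
    v_map = res.x if np.isfinite(res.fun) else start / prior_sd
    # nudge boundary-pinned coordinates inside so the finite-difference
    # Hessian does not step out of the support (e.g. Brody's B at 1)
    for i, (lo, hi) in enumerate(bounds):
        nudge = 0.05
        if lo is not None and v_map[i] < lo + nudge:
            v_map[i] = lo + nudge
        if hi is not None and v_map[i] > hi - nudge:
            v_map[i] = hi - nudge
    x_map = v_map * prior_sd

    fallback = np.diag(prior_sd**2)
    try:
        with np.errstate(invalid="ignore"):
            H = _fd_hessian(neg_std, v_map)
        if not np.all(np.isfinite(H)):
            raise np.linalg.LinAlgError("non-finite Hessian")
        cov_std = np.linalg.inv(H)
        cov_std = (cov_std + cov_std.T) / 2
        np.linalg.cholesky(cov_std)
        cov = cov_std * np.outer(prior_sd, prior_sd)
    except np.linalg.LinAlgError:
        cov = fallback
    if not np.all(np.isfinite(cov)):
        cov = fallback
    return x_map, cov


class _TProposal:
    """Frozen multivariate Student-t proposal for independence MH steps."""

    def __init__(self, mean: np.ndarray, chol: np.ndarray, df: float) -> None:
        self.mean = mean
        self.chol = chol
        self.df = df
        d = len(mean)
        self._d = d
        self._const = (
            math.lgamma((df + d) / 2.0)
            - math.lgamma(df / 2.0)
            - 0.5 * d * math.log(df * math.pi)
            - float(np.sum(np.log(np.diag(chol))))
        )

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        z = self.chol @ rng.standard_normal(self._d)
        g = rng.chisquare(self.df) / self.df
        return self.mean + z / math.sqrt(g)

    def logpdf(self, x: np.ndarray) -> float:
        u = solve_triangular(self.chol, x - self.mean, lower=True)
        quad = float(u @ u)
        return self._const - (self.df + self._d) / 2.0 * math.log1p(quad / self.df)


def _draw_start(priors, fixed, free, log_post, rng, jB=None, max_tries=200):
    for _ in range(max_tries):
        vec = np.array([priors[name].rvs(rng) for name in free], dtype=float)
        if jB is not None:
            b = min(max(vec[jB], 1e-9), 1 - 1e-9)
            vec[jB] = math.log(b / (1.0 - b))
        if np.isfinite(log_post(vec)):
            return vec
    raise SamplingError(
        "could not find a prior draw with finite log posterior after "
        f"{max_tries} tries; check data scale and priors"
    )


def sample_posterior(
    family: str,
    data: WeightSeries,
    priors: PriorSet,
    config: ChainConfig = ChainConfig(),
    fixed: dict[str, float] | None = None,
) -> PosteriorDraws:
    """Draw from the posterior of (A, B, K, sigma) given a weight series.

    Parameters
    ----------
    family : str
        Growth-curve family to fit.
    data : WeightSeries
        Observed mean weights; needs at least 4 points.
    priors : PriorSet
        Per-parameter priors (see :func:`bayesgrowth.priors.default_priors`).
    config : ChainConfig
        Chains, iterations, warmup fraction and seed.
    fixed : dict, optional
        Parameters to hold at fixed values instead of sampling (e.g.
        ``{"B": 64.2, "K": 0.0152, "sigma": 30.0}`` to sample A alone) —
        useful for conditional-posterior checks.

    Returns
    -------
    PosteriorDraws
        ``config.n_chains`` x ``config.n_retained`` post-warmup draws of
        the free parameters.  Same seed, same inputs => identical draws.
    """
    if len(data) < 4:
        raise SamplingError("need at least 4 observations")
    if float(np.var(data.weights)) == 0.0:
        raise SamplingError("zero-variance weight data")
    free, log_post, jB = _make_log_post(family, data, priors, fixed)
    if not free:
        raise SamplingError("no free parameters to sample")
    d = len(free)

    x_map, cov = _laplace_cov(family, data, priors, fixed, free, log_post, jB)
    base_chol = np.linalg.cholesky(cov * (2.38**2 / d))

    n_warm = config.n_warmup
    n_keep = config.n_retained
    target_accept = 0.30

    t_df = 5.0  # df of the independence proposals
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    diag_floor = 1e-10 * np.diag(np.maximum(np.diag(cov), 1e-12))
    diag_jitter = diag_floor

    def _window_estimate(traces, trace_lps):
        """Cross-chain warmup draws -> covariance + centre.

        The shape is the average *within*-chain covariance of the chains
        that reached the posterior bulk (total pooled covariance would be
        inflated by residual between-chain dispersion during warmup).
        Chains whose mean log posterior sits far below the best chain's
        are excluded; the independence proposal pulls them in on the
        first accepted jump.
        """
        best = max(trace_lps)
        good = [t for t, l in zip(traces, trace_lps) if l > best - 100.0]
        if sum(len(t) for t in good) < 50:
            return None, None
        emp = np.mean(
            [np.cov(t, rowvar=False).reshape(d, d) for t in good], axis=0
        ) + diag_floor
        centre = np.mean([t.mean(axis=0) for t in good], axis=0)
        return emp, centre

    def _build_kernel(cov_k, centre, rw_fallback):
        try:
            rw = np.linalg.cholesky(cov_k * (2.38**2 / d))
            ind_chol = np.linalg.cholesky(cov_k * 1.2)
        except np.linalg.LinAlgError:
            return rw_fallback, None
        return rw, _TProposal(centre, ind_chol, t_df)

    def _advance(rng, x, lp, n_steps, rw_chol, ind, adapt,
                 log_scale=0.0, ind_every=2):
        """Advance one chain; returns final state, trace, mean lp, stats.

        ``adapt=True`` runs Robbins-Monro step-size tuning on the
        random-walk moves (warmup only); with ``ind`` set, every step
        except each ``ind_every``-th is an independence
        Metropolis-Hastings proposal from the frozen t approximation.
        """
        lq_x = ind.logpdf(x) if ind is not None else 0.0
        trace = np.empty((n_steps, d))
        lp_sum = 0.0
        acc = {True: [0, 0], False: [0, 0]}
        for i in range(n_steps):
            use_ind = ind is not None and i % ind_every != 0
            if use_ind:
                prop = ind.draw(rng)
                lq_prop = ind.logpdf(prop)
                lp_prop = log_post(prop)
                log_ratio = (lp_prop - lp) - (lq_prop - lq_x)
            else:
                prop = x + math.exp(log_scale) * (rw_chol @ rng.standard_normal(d))
                lp_prop = log_post(prop)
                log_ratio = lp_prop - lp
                if adapt:
                    alpha = 0.0 if not np.isfinite(log_ratio) else math.exp(
                        min(0.0, log_ratio)
                    )
                    log_scale += (alpha - target_accept) / (i + 1) ** 0.6
                    # a drifting chain accepts almost everything and would
                    # blow the step size up without this cap
                    log_scale = min(max(log_scale, -4.6), 1.6)
            acc[use_ind][1] += 1
            if log_ratio > math.log(rng.random()):
                acc[use_ind][0] += 1
                x, lp = prop, lp_prop
                if ind is not None:
                    lq_x = lq_prop if use_ind else ind.logpdf(x)
            trace[i] = x
            lp_sum += lp
        stats = {
            "ind_accept": acc[True][0] / max(acc[True][1], 1),
            "rw_accept": acc[False][0] / max(acc[False][1], 1),
            "log_scale": log_scale,
        }
        return x, lp, trace, (lp_sum / n_steps if n_steps else -math.inf), stats

    # --- warmup: three windows of cross-chain adaptation ------------------
    # From the very first iteration each chain alternates adaptive
    # random-walk steps with independence Metropolis-Hastings proposals
    # from a multivariate-t approximation of the posterior — initially the
    # Laplace approximation, so chains jump from their overdispersed prior
    # starts into the bulk almost immediately.  After each window the
    # posterior covariance is re-estimated from the chains' recent history
    # and both proposals are rebuilt; later windows mix better, so the
    # estimate sharpens each round.  The last window's independence
    # acceptance decides how often that proposal is used in the sampling
    # phase.  The retained draws are generated by the frozen final kernel
    # only, so they target the exact posterior.
    w1 = n_warm - 2 * ((n_warm - n_warm // 2) // 2)
    w2 = (n_warm - w1) // 2
    w3 = n_warm - w1 - w2
    rngs = [np.random.default_rng(ss) for ss in seeds]
    rw_chol = base_chol
    ind = _TProposal(x_map, np.linalg.cholesky(cov * 1.5 + diag_jitter), t_df)
    ind_every = 2
    states = []
    scales = [0.0] * config.n_chains
    traces1, lps1 = [], []
    for c, rng in enumerate(rngs):
        x = _draw_start(priors, fixed, free, log_post, rng, jB)
        lp = log_post(x)
        x, lp, trace, mean_lp, st = _advance(
            rng, x, lp, w1, rw_chol, ind, True
        )
        states.append((x, lp))
        scales[c] = st["log_scale"]
        traces1.append(trace[w1 // 2:])
        lps1.append(mean_lp)

    if n_warm >= 40:
        cov_k, centre = _window_estimate(traces1, lps1)
        if cov_k is not None:
            rw_chol, new_ind = _build_kernel(cov_k, centre, rw_chol)
            ind = new_ind or ind
            scales = [0.0] * config.n_chains

        ind_acc = 0.0
        for w in (w2, w3):
            traces_w, lps_w, accs = [], [], []
            for c, rng in enumerate(rngs):
                x, lp = states[c]
                x, lp, trace, mean_lp, st = _advance(
                    rng, x, lp, w, rw_chol, ind, True, scales[c]
                )
                states[c] = (x, lp)
                scales[c] = st["log_scale"]
                traces_w.append(trace[w // 2:])
                lps_w.append(mean_lp)
                accs.append(st["ind_accept"])
            cov_k, centre = _window_estimate(traces_w, lps_w)
            if cov_k is not None:
                rw_chol, new_ind = _build_kernel(cov_k, centre, rw_chol)
                ind = new_ind or ind
                scales = [0.0] * config.n_chains
            ind_acc = float(np.mean(accs))
        # freeze how often the independence proposal is used from its
        # acceptance in the last warmup window
        if ind_acc > 0.3:
            ind_every = 4
        elif ind_acc < 0.02:
            ind = None
    else:
        for c, rng in enumerate(rngs):
            x, lp = states[c]
            x, lp, _, _, st = _advance(
                rng, x, lp, w2 + w3, rw_chol, ind, True, scales[c]
            )
            states[c] = (x, lp)
            scales[c] = st["log_scale"]

    # --- sampling phase: frozen kernel ------------------------------------
    all_chains = np.empty((config.n_chains, n_keep, d))
    LAST_RUN_STATS.clear()
    LAST_RUN_STATS["chains"] = []
    for c, rng in enumerate(rngs):
        x, lp = states[c]
        _, _, trace, _, stats = _advance(
            rng, x, lp, n_keep, rw_chol, ind, False, scales[c], ind_every
        )
        LAST_RUN_STATS["chains"].append(stats)
        all_chains[c] = trace
    if jB is not None:
        with np.errstate(over="ignore"):
            all_chains[:, :, jB] = 1.0 / (1.0 + np.exp(-all_chains[:, :, jB]))
    return PosteriorDraws(names=tuple(free), chains=all_chains)


def fit_growth_model(
    family: str,
    data: WeightSeries,
    config: ChainConfig = ChainConfig(),
    priors: PriorSet | None = None,
) -> FitResult:
    """Convenience wrapper: default priors (sigma scale from the data),
    posterior sampling, and a convergence report in one call."""
    if priors is None:
        from .priors import default_priors

        priors = default_priors(
            data.sex, family=family, sigma_scale=float(np.std(data.weights))
        )
    draws = sample_posterior(family, data, priors, config)
    report = ConvergenceReport(rhat=gelman_rubin(draws))
    return FitResult(family=family, data=data, priors=priors,
                     draws=draws, convergence=report)


# ---------------------------------------------------------------------------
# diagnostics

def _rhat_from_matrix(x: np.ndarray) -> float:
    """Classic potential scale reduction for an (m_chains, n_draws) array."""
    m, n = x.shape
    chain_means = x.mean(axis=1)
    W = float(x.var(axis=1, ddof=1).mean())
    if W == 0.0:
        return math.nan
    B = n * float(chain_means.var(ddof=1)) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B / n
    return math.sqrt(var_plus / W)


def gelman_rubin(draws: PosteriorDraws, split: bool = True) -> dict[str, float]:
    """Gelman-Rubin R-hat per parameter.

    With ``split=True`` (default) each chain is halved first, which also
    detects within-chain drift; ``split=False`` gives the classic
    two-or-more-chain statistic.  Values inside [0.99, 1.01] are the
    customary evidence of convergence.  Zero within-chain variance yields
    NaN for that parameter.
    """
    if draws.n_chains < 2 and not split:
        raise ValueError("classic R-hat needs at least 2 chains")
    if draws.n_chains * (2 if split else 1) < 2:
        raise ValueError("need at least 2 (split) chains")
    if draws.n_draws < 4:
        raise ValueError("need at least 4 draws per chain")
    out = {}
    for name in draws.names:
        x = draws.per_chain(name)
        if split:
            half = x.shape[1] // 2
            x = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
        out[name] = _rhat_from_matrix(x)
    return out


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``prob`` of the draws.

    Ties (duplicated values giving equally short windows) resolve to the
    first shortest window in sorted order.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    m = int(math.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def summarize(draws: PosteriorDraws, prob: float = 0.95) -> pd.DataFrame:
    """Posterior mean, SD and shortest HPD interval per parameter."""
    rows = []
    for name in draws.names:
        x = draws.pooled(name)
        lo, hi = hpd_interval(x, prob)
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)),
                "hpd_low": lo,
                "hpd_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def traceplot(draws: PosteriorDraws, path) -> None:
    """Write a trace plot (one panel per parameter, chains overlaid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(draws.names)
    fig, axes = plt.subplots(n, 1, figsize=(8, 2.2 * n), squeeze=False)
    for ax, name in zip(axes[:, 0], draws.names):
        for c in range(draws.n_chains):
            ax.plot(draws.per_chain(name)[c], lw=0.5, alpha=0.8,
                    label=f"chain {c}" if name == draws.names[0] else None)
        ax.set_ylabel(name)
    axes[0, 0].legend(loc="upper right", fontsize="x-small", ncol=draws.n_chains)
    axes[-1, 0].set_xlabel("post-warmup iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
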