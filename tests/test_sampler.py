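"""Posterior sampler contract, convergence diagnostics and summaries."""

import math

import numpy as np
import pytest
from scipy import stats

import bayesgrowth as bg
from bayesgrowth.models import mean_curve
from bayesgrowth.sampler import SamplingError, _rhat_from_matrix
from bayesgrowth.simulate import STUDY_AGES


def _conjugate_setup(seed=11, sigma=30.0):
    """Data linear in A with B, K, sigma fixed -> closed-form posterior."""
    truth = bg.default_scenario().female
    ages = np.array(STUDY_AGES, dtype=float)
    g = mean_curve("von_bertalanffy", 1.0, truth.B, truth.K, ages)
    rng = np.random.default_rng(seed)
    y = truth.A * g + sigma * rng.standard_normal(len(g))
    y[0] = abs(y[0])
    data = bg.WeightSeries(ages=ages, weights=np.maximum(y, 1e-9), sex="female")
    muA, sdA = 1950.0, 166.81
    prec = 1 / sdA**2 + (g @ g) / sigma**2
    post_mean = (muA / sdA**2 + (g @ y) / sigma**2) / prec
    post_sd = math.sqrt(1 / prec)
    fixed = {"B": truth.B, "K": truth.K, "sigma": sigma}
    return data, fixed, post_mean, post_sd


class TestSamplePosterior:
    def test_seeded_reproducibility(self, study_data):
        cfg = bg.ChainConfig(n_chains=2, n_iterations=600, seed=42)
        priors = bg.default_priors("female", sigma_scale=500.0)
        d1 = bg.sample_posterior("gompertz", study_data["female"], priors, cfg)
        d2 = bg.sample_posterior("gompertz", study_data["female"], priors, cfg)
        assert np.array_equal(d1.chains, d2.chains)
        d3 = bg.sample_posterior(
            "gompertz", study_data["female"], priors,
            bg.ChainConfig(n_chains=2, n_iterations=600, seed=43),
        )
        assert not np.array_equal(d1.chains, d3.chains)

    def test_draw_count_is_exact(self, study_data):
        cfg = bg.ChainConfig(n_chains=3, n_iterations=800, warmup_fraction=0.25,
                             seed=0)
        priors = bg.default_priors("male", sigma_scale=500.0)
        draws = bg.sample_posterior("logistic", study_data["male"], priors, cfg)
        assert draws.n_chains == 3
        assert draws.n_draws == 600  # 800 * (1 - 0.25)

    def test_conjugate_posterior_of_linear_parameter(self):
        data, fixed, post_mean, post_sd = _conjugate_setup()
        priors = bg.default_priors("female")
        draws = bg.sample_posterior(
            "von_bertalanffy", data, priors, bg.ChainConfig(seed=3), fixed=fixed
        )
        a = draws.pooled("A")
        # conservative MCSE bound: treat every 10th draw as independent
        ess_floor = len(a) / 10
        mcse_mean = a.std(ddof=1) / math.sqrt(ess_floor)
        assert abs(a.mean() - post_mean) < 3 * mcse_mean
        assert a.std(ddof=1) == pytest.approx(post_sd, rel=0.1)

    def test_too_few_points_rejected(self):
        data = bg.WeightSeries(
            ages=np.array([0.0, 7.0, 14.0]),
            weights=np.array([40.0, 90.0, 160.0]),
            sex="female",
        )
        with pytest.raises(SamplingError):
            bg.sample_posterior(
                "gompertz", data, bg.default_priors("female"), bg.ChainConfig()
            )

    def test_zero_variance_data_rejected(self):
        data = bg.WeightSeries(
            ages=np.array([0.0, 7.0, 14.0, 21.0]),
            weights=np.full(4, 500.0),
            sex="female",
        )
        with pytest.raises(SamplingError):
            bg.sample_posterior(
                "gompertz", data, bg.default_priors("female"), bg.ChainConfig()
            )

    def test_hpd_recovery_across_replicates(self):
        """95% HPD for A covers the generating value in >=90% of fits."""
        truth = bg.default_scenario().female
        hits = 0
        for rep in range(20):
            data = bg.generate_mean_weights(seed=300 + rep)["female"]
            fit = bg.fit_growth_model(
                "von_bertalanffy", data,
                config=bg.ChainConfig(n_chains=4, n_iterations=2000, seed=rep),
            )
            lo, hi = bg.hpd_interval(fit.draws.pooled("A"))
            hits += lo <= truth.A <= hi
        assert hits >= 18


class TestGelmanRubin:
    def test_identical_chains_worked_example(self):
        chain = np.array([1.0, 2.0, 3.0, 4.0])
        draws = bg.PosteriorDraws(
            names=("x",), chains=np.stack([chain, chain])[:, :, None]
        )
        rhat = bg.gelman_rubin(draws, split=False)
        # B = 0, so R-hat = sqrt((n-1)/n) = sqrt(3/4)
        assert rhat["x"] == pytest.approx(math.sqrt(0.75), abs=1e-12)

    def test_iid_normal_chains_inside_band(self, rng):
        chains = rng.standard_normal((4, 3000, 1))
        draws = bg.PosteriorDraws(names=("x",), chains=chains)
        r = bg.gelman_rubin(draws)["x"]
        assert 0.99 <= r <= 1.01

    def test_offset_chains_detected(self, rng):
        a = rng.standard_normal((1, 500))
        b = a + 100.0
        draws = bg.PosteriorDraws(
            names=("x",), chains=np.stack([a[0], b[0]])[:, :, None]
        )
        assert bg.gelman_rubin(draws, split=False)["x"] > 1.1

    def test_single_chain_classic_rejected(self, rng):
        draws = bg.PosteriorDraws(
            names=("x",), chains=rng.standard_normal((1, 100, 1))
        )
        with pytest.raises(ValueError):
            bg.gelman_rubin(draws, split=False)

    def test_zero_variance_undefined(self):
        chains = np.full((2, 100, 1), 7.0)
        draws = bg.PosteriorDraws(names=("x",), chains=chains)
        assert math.isnan(bg.gelman_rubin(draws)["x"])

    def test_rhat_decreases_with_chain_length(self):
        """R-hat trends to 1 as chains lengthen on a unimodal target."""
        data = bg.generate_mean_weights(seed=51)["female"]
        rs = []
        for n_iter in (500, 2000, 8000):
            fit = bg.fit_growth_model(
                "gompertz", data,
                config=bg.ChainConfig(n_chains=4, n_iterations=n_iter, seed=5),
            )
            rs.append(max(fit.convergence.rhat.values()))
        assert rs[2] < rs[0]
        assert rs[2] < 1.01

    def test_matches_arviz_split_rhat(self, vb_fits):
        az = pytest.importorskip("arviz")
        draws = vb_fits["female"].draws
        mine = bg.gelman_rubin(draws)
        ref = az.rhat(az.from_dict({k: draws.per_chain(k) for k in draws.names}))
        for k in draws.names:
            # arviz rank-normalizes; agreement is approximate by design
            assert mine[k] == pytest.approx(float(ref[k]), abs=5e-3)


class TestSummaries:
    def test_mean_of_small_set(self):
        draws = bg.PosteriorDraws(
            names=("x",), chains=np.array([1.0, 2.0, 3.0])[None, :, None]
        )
        s = bg.summarize(draws)
        assert s.loc["x", "mean"] == pytest.approx(2.0)

    def test_hpd_of_standard_normal(self, rng):
        x = rng.standard_normal(1_000_000)
        lo, hi = bg.hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_hpd_shorter_than_equal_tails_for_skewed_draws(self, rng):
        x = rng.gamma(2.0, 1.0, 200_000)
        lo, hi = bg.hpd_interval(x, 0.95)
        q = np.quantile(x, [0.025, 0.975])
        assert (hi - lo) < (q[1] - q[0])

    def test_summary_columns(self, vb_fits):
        s = bg.summarize(vb_fits["male"].draws)
        assert list(s.columns) == ["mean", "sd", "hpd_low", "hpd_high"]
        assert set(s.index) == {"A", "B", "K", "sigma"}
        assert (s["hpd_low"] < s["mean"]).all()
        assert (s["mean"] < s["hpd_high"]).all()


class TestTraceplot:
    def test_writes_file(self, vb_fits, tmp_path):
        path = tmp_path / "trace.png"
        bg.traceplot(vb_fits["female"].draws, path)
        assert path.exists() and path.stat().st_size > 0

    def test_empty_draws_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            bg.PosteriorDraws(names=("x",), chains=np.empty((2, 0, 1)))


def test_rhat_formula_direct():
    # two chains with different means: hand-computed B and W
    x = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]])
    n = 4
    W = (x.var(axis=1, ddof=1)).mean()
    B = n * np.var([x[0].mean(), x[1].mean()], ddof=1)
    expected = math.sqrt(((n - 1) / n * W + B / n) / W)
    assert _rhat_from_matrix(x) == pytest.approx(expected, abs=1e-12)
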