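"""WAIC, PSIS-LOO and model ranking."""

import math

import numpy as np
import pytest
from scipy import stats

import bayesgrowth as bg
from bayesgrowth.selection import (
    ModelSelectionError,
    _gpd_fit_mom,
    _gpd_quantile,
    comparison_row,
    compute_psis_loo,
    compute_waic,
)


class TestWaic:
    def test_two_draw_hand_worked_example(self):
        res = compute_waic(np.array([[-1.0], [-2.0]]))
        lppd = math.log(0.5 * (math.e**-1 + math.e**-2))
        assert lppd == pytest.approx(-1.37990, abs=2e-5)
        assert res.p_waic == pytest.approx(0.5)
        assert res.elpd_waic == pytest.approx(lppd - 0.5, abs=1e-9)
        assert res.waic == pytest.approx(3.7598, abs=1e-4)

    def test_identical_draws_zero_penalty(self, rng):
        row = stats.norm.logpdf(rng.standard_normal(6))
        pll = np.tile(row, (50, 1))
        res = compute_waic(pll)
        assert res.p_waic == pytest.approx(0.0, abs=1e-20)
        assert res.elpd_waic == pytest.approx(row.sum())

    def test_identity_and_penalty_sign(self, rng):
        pll = -np.abs(rng.standard_normal((200, 10)))
        res = compute_waic(pll)
        assert res.waic == pytest.approx(-2 * res.elpd_waic, abs=1e-12)
        assert res.p_waic >= 0.0
        lppd = res.elpd_waic + res.p_waic
        assert res.elpd_waic <= lppd

    def test_single_draw_rejected(self):
        with pytest.raises(ModelSelectionError):
            compute_waic(np.array([[-1.0, -2.0]]))

    def test_non_finite_rejected(self):
        with pytest.raises(ModelSelectionError):
            compute_waic(np.array([[-1.0], [-np.inf]]))


class TestPsisLoo:
    def test_identical_draws_equal_lppd(self, rng):
        row = stats.norm.logpdf(rng.standard_normal(5))
        pll = np.tile(row, (200, 1))
        res = compute_psis_loo(pll)
        assert res.elpd_loo == pytest.approx(row.sum(), abs=1e-9)

    def test_identity(self, rng):
        pll = -np.abs(rng.standard_normal((300, 8)))
        res = compute_psis_loo(pll)
        assert res.loo_ic == pytest.approx(-2 * res.elpd_loo, abs=1e-12)

    def test_matches_exact_loo_on_conjugate_toy(self, rng):
        """PSIS-LOO vs brute-force exact leave-one-out refits.

        Normal-mean model with known variance and a normal prior: the
        leave-one-out posterior and predictive density are closed form,
        so exact LOO is computable without importance sampling.
        """
        y = np.array([0.3, -1.2, 0.8, 1.7, -0.4])
        s0, sig = 10.0, 1.0

        def posterior(yv):
            prec = 1 / s0**2 + len(yv) / sig**2
            return (yv.sum() / sig**2) / prec, math.sqrt(1 / prec)

        m, s = posterior(y)
        theta = rng.normal(m, s, 4000)
        pll = stats.norm.logpdf(y[None, :], loc=theta[:, None], scale=sig)
        res = compute_psis_loo(pll)
        exact = sum(
            stats.norm.logpdf(
                y[i], *(lambda mi, si: (mi, math.sqrt(si**2 + sig**2)))(
                    *posterior(np.delete(y, i))
                )
            )
            for i in range(len(y))
        )
        assert abs(res.elpd_loo - exact) < 0.1

    def test_agrees_with_arviz(self, vb_fits):
        az = pytest.importorskip("arviz")
        fit = vb_fits["female"]
        pll = bg.pointwise_loglik_matrix(fit.family, fit.draws, fit.data)
        mine = compute_psis_loo(pll)
        idata = az.from_dict(
            posterior={k: fit.draws.per_chain(k) for k in fit.draws.names},
            log_likelihood={
                "y": pll.reshape(fit.draws.n_chains, fit.draws.n_draws, -1)
            },
        )
        ref = az.loo(idata)
        assert mine.elpd_loo == pytest.approx(float(ref.elpd_loo), abs=0.5)
        assert mine.se_elpd == pytest.approx(float(ref.se), rel=0.25)

    def test_low_draw_warning(self, rng):
        pll = -np.abs(rng.standard_normal((50, 4)))
        with pytest.warns(UserWarning, match="unreliable below"):
            compute_psis_loo(pll)

    def test_pareto_k_reported_per_observation(self, vb_fits):
        fit = vb_fits["male"]
        pll = bg.pointwise_loglik_matrix(fit.family, fit.draws, fit.data)
        res = compute_psis_loo(pll)
        assert res.pareto_k.shape == (len(fit.data),)


def test_gpd_moment_fit_roundtrip(rng):
    # sample from a known GPD, recover shape and scale roughly
    k, sigma = 0.2, 2.0
    u = rng.random(200_000)
    x = _gpd_quantile(u, k, sigma)
    k_hat, s_hat = _gpd_fit_mom(x)
    assert k_hat == pytest.approx(k, abs=0.02)
    assert s_hat == pytest.approx(sigma, rel=0.03)


def _row(model, loo_ic, se_loo, waic, se_waic, sex=None):
    return bg.ComparisonRow(
        model=model,
        elpd_loo=-loo_ic / 2,
        se_elpd_loo=se_loo / 2,
        loo_ic=loo_ic,
        se_loo_ic=se_loo,
        waic=waic,
        se_waic=se_waic,
        sex=sex,
    )


class TestRankModels:
    # published comparison-table values for the four candidate families
    FEMALE = [
        _row("gompertz", 203.6, 12.7, 201.7, 11.0, "female"),
        _row("logistic", 241.0, 4.8, 240.3, 4.2, "female"),
        _row("von_bertalanffy", 203.1, 6.2, 202.5, 5.9, "female"),
        _row("brody", 313.7, 3.6, 313.6, 3.6, "female"),
    ]
    MALE = [
        _row("gompertz", 202.9, 5.8, 202.9, 5.6, "male"),
        _row("logistic", 233.9, 3.0, 233.7, 2.9, "male"),
        _row("von_bertalanffy", 205.5, 6.6, 204.9, 6.3, "male"),
        _row("brody", 319.6, 3.9, 319.6, 3.9, "male"),
    ]

    def test_female_order(self):
        ranked = bg.rank_models(self.FEMALE)
        assert list(ranked["model"]) == [
            "von_bertalanffy", "gompertz", "logistic", "brody",
        ]

    def test_male_order_gompertz_first(self):
        ranked = bg.rank_models(self.MALE)
        assert ranked.iloc[0]["model"] == "gompertz"

    def test_near_ties_flagged_equivalent(self):
        ranked = bg.rank_models(self.FEMALE)
        # Gompertz vs von Bertalanffy differ by 0.5 << one SE
        gomp = ranked[ranked["model"] == "gompertz"].iloc[0]
        assert bool(gomp["equivalent_to_best"])
        brody = ranked[ranked["model"] == "brody"].iloc[0]
        assert not bool(brody["equivalent_to_best"])

    def test_exact_tie_stable_name_order(self):
        rows = [
            _row("zeta", 200.0, 1.0, 200.0, 1.0),
            _row("alpha", 200.0, 1.0, 200.0, 1.0),
        ]
        ranked = bg.rank_models(rows)
        assert list(ranked["model"]) == ["alpha", "zeta"]

    def test_combine_sexes_sums_indices(self):
        combined = bg.combine_sexes(self.FEMALE + self.MALE)
        by_model = {r.model: r for r in combined}
        assert by_model["gompertz"].loo_ic == pytest.approx(203.6 + 202.9)
        assert by_model["gompertz"].se_loo_ic == pytest.approx(
            math.hypot(12.7, 5.8)
        )
        ranked = bg.rank_models(combined)
        assert ranked.iloc[-1]["model"] == "brody"

    def test_single_row_rejected(self):
        with pytest.raises(ModelSelectionError):
            bg.rank_models(self.FEMALE[:1])

    def test_loo_ic_identity_enforced(self):
        with pytest.raises(ModelSelectionError):
            bg.ComparisonRow(
                model="x", elpd_loo=-100.0, se_elpd_loo=1.0,
                loo_ic=150.0, se_loo_ic=2.0, waic=200.0, se_waic=2.0,
            )


def test_brody_ranks_last_when_truth_is_gompertz():
    """Qualitative ranking: the non-sigmoid Brody curve loses in ELPD on
    data generated from a Gompertz truth in >= 9/10 replicates."""
    scen = bg.TruthScenario(
        female=bg.GrowthCurve("gompertz", A=2109.8286, B=64.2118, K=0.0152),
        male=bg.GrowthCurve("gompertz", A=2560.5027, B=65.1733, K=0.0156),
    )
    last = 0
    for rep in range(10):
        data = bg.generate_mean_weights(scen, seed=200 + rep)["female"]
        rows = []
        for fam in bg.FAMILIES:
            fit = bg.fit_growth_model(
                fam, data,
                config=bg.ChainConfig(n_chains=2, n_iterations=2000, seed=rep),
            )
            rows.append(bg.compare_fit(fit))
        ranked = bg.rank_models(rows)
        last += ranked.iloc[-1]["model"] == "brody"
    assert last >= 9


def test_psis_loo_close_to_waic_on_well_specified_fit(vb_fits):
    fit = vb_fits["female"]
    pll = bg.pointwise_loglik_matrix(fit.family, fit.draws, fit.data)
    loo = compute_psis_loo(pll)
    waic = compute_waic(pll)
    assert abs(loo.elpd_loo - waic.elpd_waic) < 2 * waic.se_elpd
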