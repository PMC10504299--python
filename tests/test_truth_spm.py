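"""Surplus-production truth model: primitives, priors, posterior, sampler."""

import math

import numpy as np
import pytest
from scipy import stats

from comsim import truth_spm as ts
from comsim._mcmc import (
    beta_from_mean_cv,
    lognormal_range_prior,
    sample_invgamma,
    split_rhat,
)


@pytest.fixture(scope="module")
def schaefer_ss_data():
    """Series simulated from the state-space Schaefer model itself."""
    rng = np.random.default_rng(42)
    T = 60
    r, K, sig = 1.0, 500_000.0, 0.05
    q = 5e-6
    B = np.empty(T)
    B[0] = 0.93 * K
    catch = np.empty(T)
    for t in range(T):
        catch[t] = 0.3 * r * K / 4 * (1 + 0.5 * np.sin(t / 8))
        if t < T - 1:
            pred = B[t] + r * B[t] * (1 - B[t] / K) - catch[t]
            B[t + 1] = pred * np.exp(rng.normal(0, sig))
    index = q * B * np.exp(rng.normal(0, 0.05, T))
    return {"catch": catch, "index": index, "B": B, "r": r, "K": K, "q": q}


class TestPellaTomlinson:
    def test_production_vanishes_at_k(self):
        assert ts.pt_surplus_production(1000.0, 0.5, 1000.0, 2.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("r,K,B", [(0.5, 1000.0, 300.0), (1.2, 5e5, 4e5)])
    def test_m2_equals_schaefer(self, r, K, B):
        assert ts.pt_surplus_production(B, r, K, 2.0) == pytest.approx(
            r * B * (1 - B / K), rel=1e-12
        )

    @pytest.mark.parametrize("m", [0.7, 1.2, 2.0, 3.0])
    def test_bmsy_matches_grid_argmax(self, m):
        K = 1000.0
        grid = np.linspace(1e-3, K, 200_001)
        prod = ts.pt_surplus_production(grid, 0.8, K, m)
        assert ts.pt_bmsy(K, m) == pytest.approx(grid[np.argmax(prod)], rel=1e-4)

    def test_bmsy_continuity_near_m2(self):
        lo = ts.pt_bmsy(1000.0, 2.0 - 1e-7)
        hi = ts.pt_bmsy(1000.0, 2.0 + 1e-7)
        assert lo == pytest.approx(500.0, abs=1e-3)
        assert hi == pytest.approx(500.0, abs=1e-3)
        assert ts.pt_bmsy(1000.0, 2.0) == pytest.approx(500.0)

    @pytest.mark.parametrize("m", [0.5, 1.5, 2.0, 4.0])
    def test_bmsy_below_k(self, m):
        assert 0 < ts.pt_bmsy(1000.0, m) < 1000.0

    def test_fox_limit_rejected(self):
        with pytest.raises(ValueError):
            ts.pt_surplus_production(100.0, 0.5, 1000.0, 1.0)

    def test_shape_inversion_round_trip(self):
        for m in (1.2, 2.0, 3.5):
            ratio = float(ts.pt_bmsy(1.0, m))
            assert ts.shape_from_bmsy_ratio(ratio) == pytest.approx(m, rel=1e-6)


class TestPriors:
    def test_beta_moment_match_round_trip(self):
        a, b = beta_from_mean_cv(0.93, 0.02)
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(0.93, abs=1e-10)
        assert math.sqrt(var) / mean == pytest.approx(0.02, abs=1e-10)

    def test_lognormal_range_hits_bounds(self):
        mu, sd = lognormal_range_prior(50_000, 2_000_000)
        dist = stats.lognorm(s=sd, scale=math.exp(mu))
        assert dist.ppf(0.025) == pytest.approx(50_000, rel=1e-9)
        assert dist.ppf(0.975) == pytest.approx(2_000_000, rel=1e-9)


class TestLogPosterior:
    def _params(self, data):
        return {
            "r": data["r"], "K": data["K"], "q": data["q"],
            "proc_var": 0.0025, "B": data["B"],
        }

    def test_matches_naive_reimplementation(self, schaefer_ss_data):
        """Independent term-by-term summation agrees to 1e-10."""
        data = schaefer_ss_data
        cfg = ts.SPMConfig(mcmc=ts.TEST_MCMC).resolve(data["catch"], data["index"])
        params = self._params(data)
        got = ts.log_posterior(params, data["catch"], data["index"], cfg)

        # naive oracle, written out longhand
        r, K, q, pv, B = params["r"], params["K"], params["q"], params["proc_var"], params["B"]
        catch, index = data["catch"], data["index"]
        sig = math.sqrt(pv)
        expected = 0.0
        for t in range(len(catch) - 1):
            pred = B[t] + r / (cfg.shape_m - 1) * B[t] * (
                1 - (B[t] / K) ** (cfg.shape_m - 1)) - catch[t]
            expected += stats.norm.logpdf(math.log(B[t + 1]), math.log(pred), sig)
            expected -= math.log(B[t + 1])
        for t in range(len(catch)):
            expected += stats.norm.logpdf(math.log(index[t]), math.log(q * B[t]),
                                          cfg.sigma_obs)
            expected -= math.log(index[t])
        mu_k, sd_k = lognormal_range_prior(*cfg.k_bounds)
        mu_r, sd_r = lognormal_range_prior(*cfg.r_bounds)
        expected += stats.norm.logpdf(math.log(K), mu_k, sd_k) - math.log(K)
        expected += stats.norm.logpdf(math.log(r), mu_r, sd_r) - math.log(r)
        a, b = beta_from_mean_cv(cfg.phi_mean, cfg.phi_cv)
        expected += stats.beta.logpdf(B[0] / K, a, b)
        expected += -math.log(cfg.q_bounds[1] - cfg.q_bounds[0])
        expected += stats.invgamma.logpdf(pv, cfg.proc_var_shape,
                                          scale=cfg.proc_var_rate)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_purity(self, schaefer_ss_data):
        data = schaefer_ss_data
        cfg = ts.SPMConfig(mcmc=ts.TEST_MCMC)
        params = self._params(data)
        first = ts.log_posterior(params, data["catch"], data["index"], cfg)
        second = ts.log_posterior(params, data["catch"], data["index"], cfg)
        assert first == second

    def test_mode_property_state_perturbation(self, schaefer_ss_data):
        """A self-consistent trajectory is a local optimum in each state."""
        data = schaefer_ss_data
        r, K = data["r"], data["K"]
        T = 40
        B = np.empty(T)
        B[0] = 0.93 * K
        catch = np.full(T, 0.05 * K / 4)
        for t in range(T - 1):
            B[t + 1] = B[t] + r * B[t] * (1 - B[t] / K) - catch[t]
        q = 5e-6
        index = q * B
        cfg = ts.SPMConfig(mcmc=ts.TEST_MCMC)
        base = {"r": r, "K": K, "q": q, "proc_var": 1e-4, "B": B.copy()}
        lp0 = ts.log_posterior(base, catch, index, cfg)
        for t in (5, 20, T - 1):
            for eps in (0.99, 1.01):
                pert = dict(base, B=B.copy())
                pert["B"][t] *= eps
                assert ts.log_posterior(pert, catch, index, cfg) < lp0

    def test_length_mismatch_rejected(self, schaefer_ss_data):
        data = schaefer_ss_data
        cfg = ts.SPMConfig(mcmc=ts.TEST_MCMC)
        with pytest.raises(ValueError):
            ts.log_posterior(self._params(data), data["catch"][:-1], data["index"], cfg)

    def test_negative_predicted_biomass_is_minus_inf(self, schaefer_ss_data):
        data = schaefer_ss_data
        cfg = ts.SPMConfig(mcmc=ts.TEST_MCMC)
        params = self._params(data)
        params = dict(params, B=np.full_like(data["B"], np.max(data["catch"]) * 0.5))
        assert ts.log_posterior(params, data["catch"], data["index"], cfg) == -np.inf


class TestSampler:
    def test_conjugate_process_variance_subproblem(self):
        """Gibbs step reproduces the closed-form inverse-gamma update."""
        rng = np.random.default_rng(0)
        resid = rng.normal(0, 0.07, size=59)
        cfg = ts.SPMConfig(mcmc=ts.TEST_MCMC)
        shape, rate = ts.proc_var_posterior(resid, cfg)
        assert shape == pytest.approx(cfg.proc_var_shape + len(resid) / 2)
        assert rate == pytest.approx(cfg.proc_var_rate + 0.5 * np.sum(resid**2))
        draws = sample_invgamma(np.random.default_rng(1), shape, rate, size=200_000)
        exact = stats.invgamma(shape, scale=rate)
        assert np.mean(draws) == pytest.approx(exact.mean(), rel=0.02)
        assert np.var(draws) == pytest.approx(exact.var(), rel=0.05)

    def test_parameter_recovery(self, schaefer_ss_data):
        data = schaefer_ss_data
        cfg = ts.SPMConfig(mcmc=ts.TEST_MCMC)
        post = ts.fit_spm(data["catch"], data["index"], cfg, rng=1)
        assert not post.failed
        assert np.median(post.r) == pytest.approx(data["r"], rel=0.30)
        assert np.median(post.K) == pytest.approx(data["K"], rel=0.30)
        n_expected = cfg.mcmc.chains * (cfg.mcmc.iterations - cfg.mcmc.burn_in) // cfg.mcmc.thin
        assert post.r.size == n_expected

    def test_determinism(self, schaefer_ss_data):
        data = schaefer_ss_data
        cfg = ts.SPMConfig(mcmc=ts.MCMCSettings(3, 400, 200, 2))
        a = ts.fit_spm(data["catch"], data["index"], cfg, rng=3)
        b = ts.fit_spm(data["catch"], data["index"], cfg, rng=3)
        assert np.array_equal(a.biomass, b.biomass)
        assert np.array_equal(a.r, b.r)

    def test_split_rhat_sanity(self):
        rng = np.random.default_rng(0)
        same = rng.normal(size=(3, 400))
        assert split_rhat(same) < 1.05
        apart = same + np.array([[0.0], [5.0], [10.0]])
        assert split_rhat(apart) > 2.0


class TestStatus:
    def test_degenerate_posterior_zero_width(self, schaefer_ss_data):
        data = schaefer_ss_data
        cfg = ts.SPMConfig(mcmc=ts.TEST_MCMC).resolve(data["catch"], data["index"])
        T = len(data["catch"])
        post = ts.SPMPosterior(
            r=np.full((1, 5), 0.5), K=np.full((1, 5), 1e5), phi=np.full((1, 5), 0.9),
            q=np.full((1, 5), 1e-5), proc_var=np.full((1, 5), 0.01),
            biomass=np.full((1, 5, T), 5e4), rhat={}, accept={}, converged=True,
            config=cfg,
        )
        st = ts.derive_status(post)
        assert np.allclose(st.hi95, st.lo95)
        assert np.allclose(st.median, 5e4 / ts.pt_bmsy(1e5, cfg.shape_m))

    def test_k_scale_equivariance(self, schaefer_ss_data):
        data = schaefer_ss_data
        cfg = ts.SPMConfig(mcmc=ts.TEST_MCMC, shape_m=2.0).resolve(
            data["catch"], data["index"])
        T = len(data["catch"])
        rng = np.random.default_rng(5)
        K = np.exp(rng.normal(11, 0.1, (2, 10)))
        B = np.exp(rng.normal(10, 0.2, (2, 10, T)))
        base = ts.SPMPosterior(
            r=np.ones((2, 10)), K=K, phi=np.full((2, 10), 0.9), q=np.ones((2, 10)),
            proc_var=np.ones((2, 10)), biomass=B, rhat={}, accept={}, converged=True,
            config=cfg,
        )
        doubled = ts.SPMPosterior(
            r=base.r, K=2 * K, phi=base.phi, q=base.q, proc_var=base.proc_var,
            biomass=B, rhat={}, accept={}, converged=True, config=cfg,
        )
        st1 = ts.derive_status(base)
        st2 = ts.derive_status(doubled)
        assert np.allclose(st2.median, st1.median / 2)

    def test_empty_posterior_rejected(self, schaefer_ss_data):
        data = schaefer_ss_data
        cfg = ts.SPMConfig(mcmc=ts.TEST_MCMC).resolve(data["catch"], data["index"])
        post = ts.SPMPosterior(
            r=np.empty((3, 0)), K=np.empty((3, 0)), phi=np.empty((3, 0)),
            q=np.empty((3, 0)), proc_var=np.empty((3, 0)),
            biomass=np.empty((3, 0, 10)), rhat={}, accept={}, converged=False,
            config=cfg,
        )
        with pytest.raises(ValueError):
            ts.derive_status(post)
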