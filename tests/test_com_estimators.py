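"""Catch-only estimators: projections, viability, inversion, state-space fit."""

import dataclasses
import math

import numpy as np
import pytest

from comsim import com_estimators as ce
from comsim.truth_spm import MCMCSettings


def det_cfg(**kw):
    """CMSY config with the deterministic projection (no process error)."""
    kw.setdefault("n_draws", 1000)
    kw.setdefault("sigma_proc", 0.0)
    return ce.CmsyConfig(**kw)


class TestSchaeferProject:
    def test_msy_equilibrium_constant(self):
        traj, collapsed = ce.schaefer_project(500.0, 0.5, 1000.0, [125.0, 125.0])
        assert not collapsed
        assert np.allclose(traj, 500.0)

    def test_logistic_growth_toward_k(self):
        traj, collapsed = ce.schaefer_project(100.0, 0.5, 1000.0, np.zeros(40))
        assert not collapsed
        assert np.all(np.diff(traj) > 0)
        assert traj[-1] == pytest.approx(1000.0, rel=1e-3)

    def test_collapse_truncates(self):
        traj, collapsed = ce.schaefer_project(100.0, 0.1, 1000.0, [150.0, 150.0])
        assert collapsed
        assert len(traj) < 3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ce.schaefer_project(0.0, 0.5, 1000.0, [1.0])


class TestCmsy2013:
    def test_brute_force_equivalence(self, schaefer_series):
        """Vectorised viability equals an exhaustive scalar-loop oracle."""
        catch = schaefer_series["catch"]
        cfg = det_cfg().resolve(catch)
        r_grid = np.repeat(np.linspace(0.3, 1.5, 5), 20)
        k_grid = np.tile(np.repeat(np.linspace(catch.max(), 10 * catch.max(), 5), 4), 5)
        d_grid = np.tile(np.linspace(0.31, 0.59, 4), 25)
        got = ce.cmsy_viable(catch, r_grid, k_grid, d_grid, cfg)

        expected = []
        for r, k, d0 in zip(r_grid, k_grid, d_grid):
            b = d0 * k
            ok = True
            for c in catch:
                b = b + r * b * (1 - b / k) - c
                if b <= 0 or b > k * (1 + 1e-12):
                    ok = False
                    break
            if ok:
                dep = b / k
                ok = cfg.final_depletion_range[0] <= dep <= cfg.final_depletion_range[1]
            expected.append(ok)
        assert np.array_equal(got, np.array(expected))
        assert got.any()  # the grid straddles the viable region

    def test_unfished_series_has_no_viable_pairs(self):
        """Near-zero catches leave the stock at ~K, outside medium depletion."""
        catch = np.full(20, 1e-9)
        res = ce.cmsy2013_fit(catch, det_cfg(k_range=(100.0, 1000.0),
                                             start_depletion_range=(0.3, 0.6)), rng=0)
        assert res.failed
        assert res.n_viable == 0
        assert res.diagnostics["n_outside_final_depletion"] > 0

    def test_msy_geometric_mean_identity(self, schaefer_series):
        catch = schaefer_series["catch"]
        res = ce.cmsy2013_fit(catch, det_cfg(n_draws=5000), rng=1)
        assert not res.failed
        # a single-pair ensemble: MSY = r K / 4 exactly
        one = ce.cmsy_viable(catch, np.array([0.6]), np.array([10_000.0]),
                             np.array([0.5]), det_cfg())
        if one[0]:
            assert 0.6 * 10_000 / 4 == pytest.approx(1500.0)

    def test_failure_counts_partition_draws(self):
        catch = np.full(20, 1e-9)
        cfg = det_cfg(k_range=(100.0, 1000.0), start_depletion_range=(0.3, 0.6))
        res = ce.cmsy2013_fit(catch, cfg, rng=0)
        d = res.diagnostics
        assert (d["n_collapsed"] + d["n_over_k"] + d["n_outside_final_depletion"]
                == d["n_draws"])

    def test_determinism(self, schaefer_series):
        catch = schaefer_series["catch"]
        a = ce.cmsy2013_fit(catch, det_cfg(n_draws=2000), rng=11)
        b = ce.cmsy2013_fit(catch, det_cfg(n_draws=2000), rng=11)
        assert a.n_viable == b.n_viable
        if not a.failed:
            assert np.array_equal(a.bbmsy_median, b.bbmsy_median)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ce.cmsy2013_fit(np.ones(5), det_cfg(), rng=0)


class TestCmsy2017:
    def test_correction_inactive_above_quarter_k(self):
        """With B/K >= 0.25 throughout, 2017 projection equals 2013's."""
        catches = np.full(10, 10.0)
        r = np.array([0.5])
        k = np.array([1000.0])
        b0 = np.array([500.0])
        plain, _ = ce._project_ensemble(catches, r, k, b0, correction=False)
        corr, _ = ce._project_ensemble(catches, r, k, b0, correction=True)
        assert np.array_equal(plain, corr)

    def test_low_biomass_production_halved_at_eighth_k(self):
        # at B/K = 0.125 the multiplier 4 B/K halves the surplus production
        r, k = 0.5, 1000.0
        b = 125.0
        plain, _ = ce._project_ensemble(np.array([0.0]), np.array([r]), np.array([k]),
                                        np.array([b]), correction=False)
        corr, _ = ce._project_ensemble(np.array([0.0]), np.array([r]), np.array([k]),
                                       np.array([b]), correction=True)
        growth_plain = plain[0, 1] - b
        growth_corr = corr[0, 1] - b
        assert growth_corr == pytest.approx(0.5 * growth_plain, rel=1e-12)

    def test_tip_selection_on_banana_cloud(self):
        """The chosen r sits above the cloud's median r."""
        rng = np.random.default_rng(0)
        log_r = rng.normal(0.0, 0.3, 500)
        log_k = 10.0 - 1.0 * log_r + rng.normal(0, 0.05, 500)  # banana: K falls with r
        r_pt, k_pt = ce._rk_tip(log_r, log_k)
        assert math.log(r_pt) > np.median(log_r)
        # K read off the regression at the tip
        assert math.log(k_pt) == pytest.approx(10.0 - math.log(r_pt), abs=0.05)

    def test_reduces_to_2013_with_2013_choices(self, schaefer_series):
        catch = schaefer_series["catch"]
        c13 = det_cfg(n_draws=2000)
        c17 = det_cfg(n_draws=2000, variant="2017", low_biomass_correction=False,
                      log_k_sampling=False, selection="geometric-mean")
        a = ce.cmsy2013_fit(catch, c13, rng=5)
        b = ce.cmsy2017_fit(catch, c17, rng=5)
        assert a.n_viable == b.n_viable
        if not a.failed:
            assert np.array_equal(a.bbmsy_median, b.bbmsy_median)
            assert a.params["MSY"] == pytest.approx(b.params["MSY"])


class TestSaturationPrior:
    def test_formula_endpoints(self):
        flat = np.full(10, 100.0)
        mu, sd = ce.saturation_prior_from_catch(flat)
        assert 1 / (1 + math.exp(-mu)) == pytest.approx(0.8)
        assert sd == 1.0
        declining = np.concatenate([np.full(5, 100.0), np.full(5, 1e-9)])
        mu_lo, _ = ce.saturation_prior_from_catch(declining)
        assert 1 / (1 + math.exp(-mu_lo)) == pytest.approx(0.2, abs=1e-6)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ce.saturation_prior_from_catch(np.ones(4))


class TestOcom:
    def test_k_inversion_self_consistency(self, schaefer_series):
        """With (r, s) fixed at truth, the solved K is within 2% of truth."""
        data = schaefer_series
        k_sol, hit = ce._solve_k_ensemble(
            data["catch"], np.array([data["r"]]), np.array([data["final_saturation"]]),
            (data["catch"].max(), 200 * data["catch"].max()),
        )
        assert not hit[0]
        assert k_sol[0] == pytest.approx(data["k"], rel=0.02)

    def test_k_monotone_in_target_saturation(self, schaefer_series):
        data = schaefer_series
        s = np.array([0.2, 0.35, 0.5, 0.65])
        r = np.full_like(s, data["r"])
        k_sol, hit = ce._solve_k_ensemble(data["catch"], r, s,
                                          (data["catch"].max(), 200 * data["catch"].max()))
        assert not hit.any()
        assert np.all(np.diff(k_sol) > 0)

    def test_msy_identity_degenerate_ensemble(self, schaefer_series):
        cfg = ce.OcomConfig(M=1.35, n_quantiles=1, n_r_draws=1,
                            saturation_prior=(0.0, 1e-6), r_median=0.8, r_cv=1e-6)
        res = ce.ocom_fit(schaefer_series["catch"], cfg, rng=0)
        assert not res.failed
        assert res.params["MSY"] == pytest.approx(
            res.params["r"] * res.params["K"] / 4, rel=1e-9)

    def test_full_fit_and_determinism(self, schaefer_series):
        cfg = ce.OcomConfig(M=1.35, n_r_draws=50)
        a = ce.ocom_fit(schaefer_series["catch"], cfg, rng=2)
        b = ce.ocom_fit(schaefer_series["catch"], cfg, rng=2)
        assert not a.failed
        assert np.array_equal(a.bbmsy_median, b.bbmsy_median)
        assert np.all(a.bbmsy_median > 0) and np.all(np.isfinite(a.bbmsy_median))


@pytest.fixture(scope="module")
def sscom_sim():
    """Data simulated from the SSCOM generative model itself."""
    rng = np.random.default_rng(7)
    T = 50
    r, K, chi, d = 0.9, 10_000.0, 0.15, 0.4
    B, E, lq = K, 0.1, math.log(0.05)
    catch = np.empty(T)
    status = np.empty(T)
    for t in range(T):
        status[t] = 2 * B / K
        H = math.exp(lq) * E * B
        catch[t] = H * math.exp(rng.normal(0, 0.02))
        Bn = (B + r * B * (1 - B / K) - H) * math.exp(rng.normal(0, 0.05))
        E = E * math.exp(np.clip(chi * (B / (d * K) - 1), -chi, chi)
                         + rng.normal(0, 0.05))
        lq = lq + rng.normal(0, 0.02)
        B = max(Bn, 1.0)
    return {"catch": catch, "r": r, "K": K, "chi": chi, "status": status}


class TestSscom:
    def test_effort_stationary_at_bioeconomic_point(self):
        # B = d K makes the drift exactly zero; elsewhere it is capped at +-chi
        chi = np.array([0.2])
        assert ce.effort_drift(np.array([1.0]), chi)[0] == 0.0
        assert ce.effort_drift(np.array([100.0]), chi)[0] == pytest.approx(0.2)
        assert ce.effort_drift(np.array([0.0]), chi)[0] == pytest.approx(-0.2)

    def test_parameter_recovery_from_own_model(self, sscom_sim):
        cfg = ce.SscomConfig(M=1.35, mcmc=MCMCSettings(3, 2000, 1000, 2))
        res = ce.sscom_fit(sscom_sim["catch"], cfg, rng=11)
        assert res.params["r"] == pytest.approx(sscom_sim["r"], rel=0.40)
        if not res.failed:
            # status trajectory tracks the simulated truth's direction
            assert res.bbmsy_median[0] > res.bbmsy_median[-1]

    def test_determinism(self, sscom_sim):
        cfg = ce.SscomConfig(M=1.35, mcmc=MCMCSettings(3, 400, 200, 2),
                             convergence_rhat_threshold=1e9)
        a = ce.sscom_fit(sscom_sim["catch"], cfg, rng=3)
        b = ce.sscom_fit(sscom_sim["catch"], cfg, rng=3)
        assert np.array_equal(a.bbmsy_median, b.bbmsy_median)
        assert a.params == b.params

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ce.sscom_fit(np.ones(10), ce.SscomConfig(), rng=0)


class TestDispatch:
    def test_unknown_method(self):
        with pytest.raises(ValueError):
            ce.fit_com("zbrt", np.ones(20))

    def test_failed_results_carry_no_trajectory(self):
        res = ce.cmsy2013_fit(np.full(20, 1e-9),
                              det_cfg(k_range=(100.0, 1000.0),
                                      start_depletion_range=(0.3, 0.6)), rng=0)
        assert res.failed and res.bbmsy_median is None and res.diagnostics
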