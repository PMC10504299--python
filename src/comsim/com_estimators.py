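"""Catch-only stock-assessment methods (COMs).

Four mechanistic estimators of stock status B/B_MSY from a catch time
series alone:

* ``cmsy2013_fit`` — stock reduction analysis with uniform r-K priors and
  depletion-range viability filtering (Catch-MSY).
* ``cmsy2017_fit`` — the updated variant: log-uniform K sampling, a linear
  reduction of surplus production at low biomass, and a "tip of the viable
  cloud" point estimate of (r, K).
* ``ocom_fit`` — optimized catch-only model: r prior from natural
  mortality, final-year saturation prior, K solved by one-dimensional
  inversion per (r, s) pair.
* ``sscom_fit`` — state-space catch-only model: latent coupled
  biomass/effort/catchability dynamics fitted by MCMC.

All Schaefer-based quantities use MSY = rK/4 and B_MSY = K/2.  Every
estimator is deterministic given (inputs, config, seed) and returns a
:class:`ComResult`; failure (no viable pairs, optimizer at its bounds,
non-converged chains) is a value, not an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._mcmc import (
    RMScale,
    lognormal_range_prior,
    sample_invgamma,
    split_rhat,
)
from .truth_spm import MCMCSettings

#: Reduced-scale sampler settings for the state-space catch-only model;
#: longer than the surplus-production test preset because the coupled
#: latent paths mix more slowly.
SSCOM_TEST_MCMC = MCMCSettings(chains=3, iterations=4_000, burn_in=2_400, thin=2)

__all__ = [
    "SSCOM_TEST_MCMC",
    "CmsyConfig",
    "OcomConfig",
    "SscomConfig",
    "ComResult",
    "schaefer_project",
    "cmsy_viable",
    "cmsy2013_fit",
    "cmsy2017_fit",
    "saturation_prior_from_catch",
    "ocom_fit",
    "sscom_fit",
    "fit_com",
]


# ---------------------------------------------------------------------------
# configuration and result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CmsyConfig:
    """Catch-MSY settings.

    ``k_range=None`` resolves to (Cmax, 10*Cmax).  ``start_depletion_range
    =None`` applies the conventional rule based on the ratio of the first
    to the maximum catch: (0.5, 0.9) when C_1/C_max < 0.5, else (0.3,
    0.6).  The final-year depletion window defaults to the "medium
    depletion" range (0.2, 0.6).

    The 2017 variant differs through ``log_k_sampling`` (log-uniform K),
    ``low_biomass_correction`` (production scaled by 4B/K below B/K =
    0.25) and ``selection='tip'`` (point (r, K) from the high-r tip of the
    viable cloud); each resolves from ``variant`` when left None, so that
    forcing the 2013 choices onto the 2017 variant reproduces CMSY-2013
    draw for draw.
    """

    r_range: tuple[float, float] = (0.4, 2.0)
    k_range: tuple[float, float] | None = None
    start_depletion_range: tuple[float, float] | None = None
    final_depletion_range: tuple[float, float] = (0.2, 0.6)
    n_draws: int = 30_000
    variant: str = "2013"
    low_biomass_correction: bool | None = None
    log_k_sampling: bool | None = None
    selection: str | None = None
    #: lognormal process-error sd of the stock-reduction projection, as in
    #: the published implementations; 0 gives a deterministic projection
    sigma_proc: float = 0.05

    def __post_init__(self) -> None:
        if self.variant not in ("2013", "2017"):
            raise ValueError(f"unknown CMSY variant: {self.variant!r}")
        if self.n_draws < 1000:
            raise ValueError("n_draws must be >= 1000")
        for rng_ in (self.r_range, self.k_range, self.start_depletion_range,
                     self.final_depletion_range):
            if rng_ is not None and not (0 < rng_[0] < rng_[1]):
                raise ValueError("ranges must be positive and ordered")
        if self.selection not in (None, "geometric-mean", "tip"):
            raise ValueError(f"unknown selection rule: {self.selection!r}")

    def resolve(self, catch: np.ndarray) -> "CmsyConfig":
        out = self
        is17 = self.variant == "2017"
        if out.k_range is None:
            cmax = float(np.max(catch))
            out = replace(out, k_range=(cmax, 10.0 * cmax))
        if out.start_depletion_range is None:
            ratio = float(catch[0]) / float(np.max(catch))
            rng_ = (0.5, 0.9) if ratio < 0.5 else (0.3, 0.6)
            out = replace(out, start_depletion_range=rng_)
        if out.low_biomass_correction is None:
            out = replace(out, low_biomass_correction=is17)
        if out.log_k_sampling is None:
            out = replace(out, log_k_sampling=is17)
        if out.selection is None:
            out = replace(out, selection="tip" if is17 else "geometric-mean")
        return out


@dataclass(frozen=True)
class OcomConfig:
    """Optimized catch-only model settings.

    The r prior is lognormal with median ``2 * 0.87 * M`` (twice the
    teleost FMSY ~ 0.87 M rule) and CV ``r_cv``, truncated at ``r_max``
    because the discrete-time Schaefer projection is oscillatory beyond
    r ~ 2.  The final-year saturation prior (logit-normal) defaults to
    the catch-ratio heuristic of :func:`saturation_prior_from_catch`.
    """

    M: float = 1.35
    r_median: float | None = None
    r_cv: float = 0.5
    r_max: float = 2.5
    saturation_prior: tuple[float, float] | None = None
    n_quantiles: int = 13
    n_r_draws: int = 100
    k_search_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("M must be > 0")
        if self.n_quantiles < 1 or self.n_r_draws < 1:
            raise ValueError("ensemble sizes must be >= 1")
        if self.saturation_prior is not None and self.saturation_prior[1] <= 0:
            raise ValueError("saturation prior sd must be > 0")


@dataclass(frozen=True)
class SscomConfig:
    """State-space catch-only model settings.

    Effort responds to the bioeconomic signal B/(d K): it is stationary at
    B = d K and otherwise drifts by at most a factor exp(chi) per year.
    Process variances (biomass, effort, catchability random walk) carry
    inverse-gamma priors and are Gibbs-sampled; the observed catch is
    lognormal around the latent harvest q_t E_t B_t with a small fixed
    observation sd.
    """

    M: float = 1.35
    r_median: float | None = None
    r_cv: float = 0.5
    chi_median: float = 0.1
    chi_sigma: float = 0.7
    #: biomass fraction of K at which effort is stationary; 0.5 puts the
    #: bioeconomic equilibrium at B_MSY, the original method's prior centre
    d: float = 0.5
    k_range: tuple[float, float] | None = None  # default (Cmax, 10*Cmax)
    sigma_catch_obs: float = 0.05
    var_prior_biomass: tuple[float, float] = (4.0, 0.12)
    var_prior_effort: tuple[float, float] = (4.0, 0.12)
    var_prior_q: tuple[float, float] = (4.0, 0.03)
    mcmc: MCMCSettings = field(default_factory=lambda: MCMCSettings(3, 10_000, 2_500, 5))
    #: split-R-hat bound on the reported status trajectory above which the
    #: fit is flagged failed.  Coupled latent effort/biomass/catchability
    #: paths mix slowly on weakly-informative (flat) catch series, so the
    #: default catches gross chain disagreement rather than demanding
    #: publication-grade 1.1 convergence at desk-scale chain lengths;
    #: tighten via config when running long chains.
    convergence_rhat_threshold: float = 1.5

    def __post_init__(self) -> None:
        if self.chi_median <= 0:
            raise ValueError("chi must be > 0")
        if not (0 < self.d < 1):
            raise ValueError("d must be in (0, 1)")
        if self.M <= 0 or self.sigma_catch_obs <= 0:
            raise ValueError("M and sigma_catch_obs must be > 0")

    def r_prior(self) -> tuple[float, float]:
        med = self.r_median if self.r_median is not None else 2.0 * 0.87 * self.M
        sd = math.sqrt(math.log1p(self.r_cv**2))
        return math.log(med), sd


@dataclass
class ComResult:
    """One estimator's B/B_MSY trajectory and parameter summaries."""

    method: str
    years: np.ndarray | None
    bbmsy_median: np.ndarray | None
    bbmsy_lo: np.ndarray | None
    bbmsy_hi: np.ndarray | None
    params: dict
    n_viable: int
    converged: bool
    failed: bool
    diagnostics: dict
    seed: object = None


def _failed_result(method: str, diagnostics: dict, seed=None) -> ComResult:
    return ComResult(
        method=method, years=None, bbmsy_median=None, bbmsy_lo=None,
        bbmsy_hi=None, params={}, n_viable=0, converged=False, failed=True,
        diagnostics=diagnostics, seed=seed,
    )


# ---------------------------------------------------------------------------
# Schaefer projection
# ---------------------------------------------------------------------------


def schaefer_project(b0: float, r: float, k: float, catches) -> tuple[np.ndarray, bool]:
    """Project B_{t+1} = B_t + r B_t (1 - B_t/K) - C_t from B_1 = b0.

    Returns (trajectory, collapsed).  The trajectory has length
    ``len(catches) + 1`` (a final post-catch biomass is included); on
    collapse it is truncated at the first non-positive value.
    """
    if min(b0, r, k) <= 0:
        raise ValueError("b0, r, k must be > 0")
    catches = np.asarray(catches, dtype=float)
    out = np.empty(len(catches) + 1)
    out[0] = b0
    for t, c in enumerate(catches):
        b = out[t]
        nb = b + r * b * (1.0 - b / k) - c
        if nb <= 0:
            return out[: t + 1], True
        out[t + 1] = nb
    return out, False


def _project_ensemble(catch: np.ndarray, r: np.ndarray, k: np.ndarray,
                      b0: np.ndarray, correction: bool,
                      noise: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Schaefer projection for many (r, K, B_1) triples.

    ``noise`` (n, T), if given, multiplies each annual update (lognormal
    process error).  Returns (B, alive): B has shape (n, T+1); after a
    collapse the entries are held at 0 and ``alive`` is False for that
    trajectory.
    """
    n, T = len(r), len(catch)
    B = np.zeros((n, T + 1))
    B[:, 0] = b0
    alive = np.ones(n, dtype=bool)
    b = b0.astype(float).copy()
    for t in range(T):
        prod = r * b * (1.0 - b / k)
        if correction:
            frac = b / k
            prod = np.where(frac < 0.25, prod * 4.0 * frac, prod)
        b = b + prod - catch[t]
        if noise is not None:
            b = b * noise[:, t]
        b = np.where(alive, b, 0.0)
        alive &= b > 0
        b = np.where(alive, b, 0.0)
        B[:, t + 1] = b
    return B, alive


def cmsy_viable(catch, r, k, start_dep, cfg: CmsyConfig) -> np.ndarray:
    """Viability mask for given (r, K, start-depletion) triples.

    A triple is viable when the projected (deterministic) biomass stays
    within (0, K] every year and the final depletion B_{T+1}/K falls
    inside the configured final-depletion window.  (The Bernoulli
    "likelihood" of Catch-MSY is exactly this indicator.)
    """
    cfg = cfg.resolve(np.asarray(catch, dtype=float))
    catch = np.asarray(catch, dtype=float)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    k = np.atleast_1d(np.asarray(k, dtype=float))
    d0 = np.atleast_1d(np.asarray(start_dep, dtype=float))
    B, alive = _project_ensemble(catch, r, k, d0 * k, bool(cfg.low_biomass_correction))
    within_k = (B <= k[:, None] * (1.0 + 1e-12)).all(axis=1)
    final_dep = B[:, -1] / k
    lo, hi = cfg.final_depletion_range
    return alive & within_k & (final_dep >= lo) & (final_dep <= hi)


# ---------------------------------------------------------------------------
# Catch-MSY (2013 / 2017)
# ---------------------------------------------------------------------------


def _rk_tip(log_r: np.ndarray, log_k: np.ndarray, quantile: float = 0.75) -> tuple[float, float]:
    """Point (r, K) at the high-r tip of the viable cloud.

    r is the given quantile of viable log-r; K is read off the log-log
    linear regression of K on r at that r.
    """
    lr = float(np.quantile(log_r, quantile))
    if len(log_r) > 1 and np.ptp(log_r) > 0:
        slope, intercept = np.polyfit(log_r, log_k, 1)
        lk = intercept + slope * lr
    else:
        lk = float(np.mean(log_k))
    return math.exp(lr), math.exp(lk)


def _cmsy_fit(catch, cfg: CmsyConfig, rng, method: str) -> ComResult:
    catch = np.asarray(catch, dtype=float)
    if len(catch) < 10:
        raise ValueError("catch series must have at least 10 years")
    if np.any(catch < 0):
        raise ValueError("catch must be non-negative")
    cfg = cfg.resolve(catch)
    rng = np.random.default_rng(rng)
    n = cfg.n_draws

    r = rng.uniform(*cfg.r_range, size=n)
    if cfg.log_k_sampling:
        k = np.exp(rng.uniform(math.log(cfg.k_range[0]), math.log(cfg.k_range[1]), size=n))
    else:
        k = rng.uniform(*cfg.k_range, size=n)
    d0 = rng.uniform(*cfg.start_depletion_range, size=n)
    noise = None
    if cfg.sigma_proc > 0:
        noise = np.exp(rng.normal(0.0, cfg.sigma_proc, size=(n, len(catch))))

    B, alive = _project_ensemble(catch, r, k, d0 * k, bool(cfg.low_biomass_correction),
                                 noise)
    within_k = (B <= k[:, None] * (1.0 + 1e-12)).all(axis=1)
    final_dep = np.where(alive, B[:, -1] / k, -1.0)
    lo, hi = cfg.final_depletion_range
    in_window = (final_dep >= lo) & (final_dep <= hi)
    viable = alive & within_k & in_window

    if not viable.any():
        return _failed_result(method, {
            "n_draws": n,
            "n_collapsed": int((~alive).sum()),
            "n_over_k": int((alive & ~within_k).sum()),
            "n_outside_final_depletion": int((alive & within_k & ~in_window).sum()),
        })

    rv, kv = r[viable], k[viable]
    status = B[viable][:, :-1] / (kv[:, None] / 2.0)
    med = np.median(status, axis=0)
    lo_q = np.quantile(status, 0.025, axis=0)
    hi_q = np.quantile(status, 0.975, axis=0)

    if cfg.selection == "tip":
        r_pt, k_pt = _rk_tip(np.log(rv), np.log(kv))
    else:
        r_pt = float(np.exp(np.mean(np.log(rv))))
        k_pt = float(np.exp(np.mean(np.log(kv))))
    msy = float(np.exp(np.mean(np.log(rv * kv / 4.0)))) if cfg.selection != "tip" \
        else r_pt * k_pt / 4.0

    return ComResult(
        method=method, years=None,
        bbmsy_median=med, bbmsy_lo=lo_q, bbmsy_hi=hi_q,
        params={"r": r_pt, "K": k_pt, "MSY": msy,
                "bmsy": k_pt / 2.0},
        n_viable=int(viable.sum()), converged=True, failed=False,
        diagnostics={"accept_rate": float(viable.mean())},
    )


def cmsy2013_fit(catch, cfg: CmsyConfig | None = None, rng=None) -> ComResult:
    """Catch-MSY (2013): uniform r-K priors, geometric-mean MSY,
    median viable-trajectory B/B_MSY."""
    cfg = cfg or CmsyConfig()
    if cfg.variant != "2013":
        cfg = replace(cfg, variant="2013")
    return _cmsy_fit(catch, cfg, rng, "cmsy13")


def cmsy2017_fit(catch, cfg: CmsyConfig | None = None, rng=None) -> ComResult:
    """CMSY (2017): log-uniform K, low-biomass production correction,
    tip-of-cloud (r, K) point estimate."""
    cfg = cfg or CmsyConfig(variant="2017")
    if cfg.variant != "2017":
        cfg = replace(cfg, variant="2017")
    return _cmsy_fit(catch, cfg, rng, "cmsy17")


# ---------------------------------------------------------------------------
# OCOM
# ---------------------------------------------------------------------------


def saturation_prior_from_catch(catch) -> tuple[float, float]:
    """Final-year saturation prior (logit mean, logit sd) from the catch.

    A deterministic stand-in for an externally trained saturation
    predictor: mean saturation 0.2 + 0.6 * (C_recent / C_max) with
    C_recent the mean of the last five years, sd fixed at 1.0 on the
    logit scale.
    """
    catch = np.asarray(catch, dtype=float)
    if len(catch) < 5:
        raise ValueError("catch series must have at least 5 years")
    if np.any(catch < 0):
        raise ValueError("catch must be non-negative")
    mean_s = 0.2 + 0.6 * float(np.mean(catch[-5:])) / float(np.max(catch))
    return math.log(mean_s / (1.0 - mean_s)), 1.0


def _solve_k_ensemble(catch, r, s, bounds, n_iter=60):
    """Vectorised bisection in log K for final depletion == target s.

    The projection starts at B_1 = K; final depletion B_{T+1}/K is
    (weakly) increasing in K, so the root is bracketed whenever the
    target is attainable inside ``bounds``.  Returns (K, hit_bound).
    """
    catch = np.asarray(catch, dtype=float)

    def final_dep(k):
        B, alive = _project_ensemble(catch, r, k, k.copy(), correction=False)
        return np.where(alive, B[:, -1] / k, -1.0)

    lo = np.full(len(r), math.log(bounds[0]))
    hi = np.full(len(r), math.log(bounds[1]))
    f_lo = final_dep(np.exp(lo)) - s
    f_hi = final_dep(np.exp(hi)) - s
    hit = (f_lo > 0) | (f_hi < 0)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f_mid = final_dep(np.exp(mid)) - s
        go_hi = f_mid < 0
        lo = np.where(go_hi, mid, lo)
        hi = np.where(go_hi, hi, mid)
    return np.exp(0.5 * (lo + hi)), hit


def ocom_fit(catch, cfg: OcomConfig | None = None, rng=None) -> ComResult:
    """Optimized catch-only model.

    r is drawn from its M-based lognormal prior; the final-year
    saturation s takes the prior's ``n_quantiles`` central quantiles; for
    every (r, s) pair K is found by bisection so that the Schaefer
    projection started at B_1 = K ends at saturation s.  The ensemble of
    solved (r, K) pairs yields the median B/B_MSY trajectory and the
    parameter summaries (medians; MSY = rK/4).
    """
    cfg = cfg or OcomConfig()
    catch = np.asarray(catch, dtype=float)
    if np.any(catch <= 0):
        raise ValueError("catch must be strictly positive")
    rng = np.random.default_rng(rng)

    r_med = cfg.r_median if cfg.r_median is not None else 2.0 * 0.87 * cfg.M
    sd = math.sqrt(math.log1p(cfg.r_cv**2))
    r_draws = np.exp(rng.normal(math.log(r_med), sd, size=cfg.n_r_draws))
    r_draws = np.clip(r_draws, 0.05, cfg.r_max)

    mu_s, sd_s = (cfg.saturation_prior if cfg.saturation_prior is not None
                  else saturation_prior_from_catch(catch))
    probs = (np.arange(cfg.n_quantiles) + 0.5) / cfg.n_quantiles
    from scipy.special import ndtri
    s_vals = 1.0 / (1.0 + np.exp(-(mu_s + sd_s * ndtri(probs))))

    rr, ss = np.meshgrid(r_draws, s_vals, indexing="ij")
    rr, ss = rr.ravel(), ss.ravel()
    cmax = float(np.max(catch))
    bounds = cfg.k_search_bounds or (cmax, 200.0 * cmax)
    kk, hit = _solve_k_ensemble(catch, rr, ss, bounds)

    n_pairs = len(rr)
    n_hit = int(hit.sum())
    diagnostics = {"n_pairs": n_pairs, "n_bound_hits": n_hit,
                   "saturation_logit_mean": mu_s, "saturation_logit_sd": sd_s}
    if n_hit > 0.5 * n_pairs:
        return _failed_result("ocom", diagnostics)

    ok = ~hit
    rv, kv = rr[ok], kk[ok]
    B, alive = _project_ensemble(catch, rv, kv, kv.copy(), correction=False)
    status = B[:, :-1] / (kv[:, None] / 2.0)
    return ComResult(
        method="ocom", years=None,
        bbmsy_median=np.median(status, axis=0),
        bbmsy_lo=np.quantile(status, 0.025, axis=0),
        bbmsy_hi=np.quantile(status, 0.975, axis=0),
        params={"r": float(np.median(rv)), "K": float(np.median(kv)),
                "MSY": float(np.median(rv * kv / 4.0)),
                "bmsy": float(np.median(kv)) / 2.0},
        n_viable=int(ok.sum()), converged=True, failed=False,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# SSCOM
# ---------------------------------------------------------------------------


def effort_drift(b_over_dk: np.ndarray, chi: np.ndarray) -> np.ndarray:
    """Log-effort drift clip(chi * (B/(dK) - 1), -chi, +chi).

    Effort is stationary at B = d K and can change by at most a factor
    exp(chi) per year in either direction.
    """
    return np.clip(chi * (b_over_dk - 1.0), -chi, chi)


def sscom_fit(catch, cfg: SscomConfig | None = None, rng=None) -> ComResult:
    """State-space catch-only model.

    Latent states: log-biomass x (Schaefer dynamics with process error,
    B_1 = K), log-effort e (bioeconomic drift toward B = d K), and a
    log-catchability random walk u.  The observed catch is lognormal
    around the latent harvest q_t E_t B_t.  Sampled by the same blocked
    adaptive Metropolis-within-Gibbs machinery as the surplus-production
    truth model; non-convergence (split-R-hat above the threshold on r,
    K or chi) yields a failed result.
    """
    cfg = cfg or SscomConfig()
    catch = np.asarray(catch, dtype=float)
    if len(catch) < 15:
        raise ValueError("catch series must have at least 15 years")
    if np.any(catch <= 0):
        raise ValueError("catch must be strictly positive")
    rng = np.random.default_rng(rng)
    T = len(catch)
    C = cfg.mcmc.chains
    log_catch = np.log(catch)
    cmax = float(np.max(catch))
    k_range = cfg.k_range or (cmax, 10.0 * cmax)

    mu_k, sd_k = lognormal_range_prior(*k_range)
    mu_r, sd_r = cfg.r_prior()
    mu_chi, sd_chi = math.log(cfg.chi_median), cfg.chi_sigma
    d = cfg.d
    s_obs = cfg.sigma_catch_obs
    (aB, bB), (aE, bE), (aQ, bQ) = (cfg.var_prior_biomass, cfg.var_prior_effort,
                                    cfg.var_prior_q)

    # --- initialisation ------------------------------------------------
    offs = np.linspace(-0.3, 0.3, C)
    logK = np.maximum(mu_k + sd_k * offs, math.log(3.0 * cmax))
    logr = np.full(C, mu_r)
    logchi = np.full(C, mu_chi)
    s2B = np.full(C, 0.01)
    s2E = np.full(C, 0.01)
    s2Q = np.full(C, 0.005)

    # deterministic Schaefer path as the biomass start, floored at 0.1 K.
    # The depletion history is only weakly identified, so the chains start
    # from overdispersed trajectory SHAPES: the projection itself, and
    # geometric blends of it with the flat path at K.  Shared-shape starts
    # would let every chain inherit the projection's bias without the
    # split-R-hat diagnostic noticing.
    x = np.empty((C, T))
    blend = np.linspace(1.0, 0.6, C)
    for c in range(C):
        k0, r0 = math.exp(logK[c]), math.exp(logr[c])
        b = k0
        for t in range(T):
            x[c, t] = math.log(b)
            b = max(b + r0 * b * (1.0 - b / k0) - catch[t], 0.1 * k0)
        x[c] = blend[c] * x[c] + (1.0 - blend[c]) * logK[c]
    x[:, 0] = logK
    # split log C - x between effort (starts at 0) and catchability
    u0 = log_catch[0] - x[:, 0]
    u = np.tile(u0[:, None], (1, T))
    e = log_catch[None, :] - x - u
    e1_mu, u1_mu = 0.0, u0.copy()

    # catch-observation precision; during early burn-in the observation
    # likelihood is tempered (sd inflated up to 5x, annealed away by 80% of
    # burn-in) so chains started from different depletion histories can
    # traverse trajectory shapes and merge before exact sampling begins
    inv_obs_exact = 1.0 / (2.0 * s_obs**2)
    inv_obs = inv_obs_exact / 25.0
    inv_sdk = 1.0 / (2.0 * sd_k**2)
    inv_sdr = 1.0 / (2.0 * sd_r**2)
    inv_sdchi = 1.0 / (2.0 * sd_chi**2)

    def total_lp(logr_, logK_, logchi_, x_, e_, u_, s2B_, s2E_, s2Q_):
        # log posterior up to additive terms that are constant within any
        # single Metropolis comparison (normalisations; the variance terms
        # are refreshed after each Gibbs draw)
        r_, K_, chi_ = np.exp(logr_), np.exp(logK_), np.exp(logchi_)
        B = np.exp(x_)
        harvest = np.exp(u_ + e_ + x_)
        bb = B[:, :-1]
        pred = bb + r_[:, None] * bb * (1.0 - bb / K_[:, None]) - harvest[:, :-1]
        ok = pred > 0
        z = x_[:, 1:] - np.log(np.where(ok, pred, 1.0))
        trans = np.where(ok.all(axis=1), -(z * z).sum(axis=1) / (2.0 * s2B_), -np.inf)
        drift = effort_drift(bb / (d * K_[:, None]), chi_[:, None])
        ze = e_[:, 1:] - e_[:, :-1] - drift
        zq = u_[:, 1:] - u_[:, :-1]
        zo = log_catch[None, :] - (u_ + e_ + x_)
        lp = trans - (ze * ze).sum(axis=1) / (2.0 * s2E_) \
            - (zq * zq).sum(axis=1) / (2.0 * s2Q_) - (zo * zo).sum(axis=1) * inv_obs
        lp -= (logr_ - mu_r) ** 2 * inv_sdr + (logK_ - mu_k) ** 2 * inv_sdk
        lp -= (logchi_ - mu_chi) ** 2 * inv_sdchi
        lp -= 0.5 * (e_[:, 0] - e1_mu) ** 2 + 0.5 * (u_[:, 0] - u1_mu) ** 2
        return lp

    lp = total_lp(logr, logK, logchi, x, e, u, s2B, s2E, s2Q)
    for _ in range(40):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        logK = np.where(bad, logK + 0.3, logK)
        for c in np.where(bad)[0]:
            k0, r0 = math.exp(logK[c]), math.exp(logr[c])
            b = k0
            for t in range(T):
                x[c, t] = math.log(b)
                b = max(b + r0 * b * (1.0 - b / k0) - catch[t], 0.1 * k0)
        u0 = log_catch[0] - x[:, 0]
        u = np.tile(u0[:, None], (1, T))
        e = log_catch[None, :] - x - u
        u1_mu = u0.copy()
        lp = total_lp(logr, logK, logchi, x, e, u, s2B, s2E, s2Q)
    if not np.all(np.isfinite(lp)):
        return _failed_result("sscom", {"reason": "no feasible starting state"})

    tgrid = np.arange(T) / (T - 1)
    # shaped global moves: weight profile (0 at the pinned B_1 = K) and
    # which path compensates the biomass reshape
    shape_moves = [
        ("tilt_e", tgrid, "e"),
        ("tilt_u", tgrid, "u"),
        ("sin1_e", np.sin(np.pi * tgrid), "e"),
        ("sin2_e", np.sin(2.0 * np.pi * tgrid), "e"),
        ("sin1_u", np.sin(np.pi * tgrid), "u"),
        ("sin3_e", np.sin(3.0 * np.pi * tgrid), "e"),
    ]
    param_scales = {k: RMScale(C, init=0.1, target=0.3)
                    for k in ("logr", "logK", "logchi", "scale_move", "eu_move",
                              "rk_move", *[m[0] for m in shape_moves])}
    scales = {name: RMScale((C, T), init=0.05, target=0.44) for name in ("x", "e", "u")}
    free_x = np.arange(1, T)
    halves_x = [free_x[free_x % 2 == 1], free_x[free_x % 2 == 0]]
    all_t = np.arange(T)
    halves_all = [all_t[all_t % 2 == 1], all_t[all_t % 2 == 0]]

    n_kept = cfg.mcmc.n_kept
    kept = {k: np.empty((C, n_kept)) for k in ("r", "K", "chi", "s2B", "s2E", "s2Q")}
    kept_b = np.empty((C, n_kept, T))
    ptr = 0
    acc_count = {k: 0.0 for k in ("params", "states")}

    anneal_end = max(1, int(0.8 * cfg.mcmc.burn_in))
    for it in range(cfg.mcmc.iterations):
        adapting = it < cfg.mcmc.burn_in
        rm_step = min(0.25, 2.0 / math.sqrt(it + 1)) if adapting else 0.0

        # annealed observation precision (exact from 80% of burn-in on)
        frac = min(1.0, it / anneal_end)
        infl = (5.0 * (1.0 - frac) + 1.0 * frac) ** 2
        new_inv = inv_obs_exact / infl
        if new_inv != inv_obs:
            inv_obs = new_inv
            lp = total_lp(logr, logK, logchi, x, e, u, s2B, s2E, s2Q)

        # ---- parameters ------------------------------------------------
        for name in ("logr", "logK", "logchi"):
            sc = param_scales[name]
            step = sc.scale * rng.normal(size=C)
            p_logr, p_logK, p_logchi = logr, logK, logchi
            x_prop = x
            if name == "logr":
                p_logr = logr + step
            elif name == "logchi":
                p_logchi = logchi + step
            else:
                p_logK = logK + step
                x_prop = x.copy()
                x_prop[:, 0] = p_logK  # B_1 = K pinned
            lp_prop = total_lp(p_logr, p_logK, p_logchi, x_prop, e, u, s2B, s2E, s2Q)
            acc = np.log(rng.uniform(size=C)) < lp_prop - lp
            logr = np.where(acc, p_logr, logr)
            logK = np.where(acc, p_logK, logK)
            logchi = np.where(acc, p_logchi, logchi)
            if name == "logK":
                x = np.where(acc[:, None], x_prop, x)
            lp = np.where(acc, lp_prop, lp)
            sc.update(acc, adapting)
            acc_count["params"] += acc.mean() / 3.0

        # ---- joint ridge moves -----------------------------------------
        # (0) r-K trade-off: higher K / lower r leave the production level
        #     roughly unchanged.
        sc = param_scales["rk_move"]
        dstep = sc.scale * rng.normal(size=C)
        x_prop = x.copy()
        x_prop[:, 0] = logK + dstep
        lp_prop = total_lp(logr - dstep, logK + dstep, logchi, x_prop, e, u, s2B, s2E, s2Q)
        acc = np.log(rng.uniform(size=C)) < lp_prop - lp
        logr = np.where(acc, logr - dstep, logr)
        logK = np.where(acc, logK + dstep, logK)
        x = np.where(acc[:, None], x_prop, x)
        lp = np.where(acc, lp_prop, lp)
        sc.update(acc, adapting)

        # (a) scale: K, B down / q up leaves the harvest and drift terms
        #     invariant; only catch-vs-production and priors inform it.
        sc = param_scales["scale_move"]
        dstep = sc.scale * rng.normal(size=C)
        lp_prop = total_lp(logr, logK - dstep, logchi, x - dstep[:, None],
                           e, u + dstep[:, None], s2B, s2E, s2Q)
        acc = np.log(rng.uniform(size=C)) < lp_prop - lp
        logK = np.where(acc, logK - dstep, logK)
        x = np.where(acc[:, None], x - dstep[:, None], x)
        u = np.where(acc[:, None], u + dstep[:, None], u)
        lp = np.where(acc, lp_prop, lp)
        sc.update(acc, adapting)

        # (b) effort/catchability trade-off: e + d, u - d.
        sc = param_scales["eu_move"]
        dstep = sc.scale * rng.normal(size=C)
        lp_prop = total_lp(logr, logK, logchi, x, e + dstep[:, None],
                           u - dstep[:, None], s2B, s2E, s2Q)
        acc = np.log(rng.uniform(size=C)) < lp_prop - lp
        e = np.where(acc[:, None], e + dstep[:, None], e)
        u = np.where(acc[:, None], u - dstep[:, None], u)
        lp = np.where(acc, lp_prop, lp)
        sc.update(acc, adapting)

        # (c) smooth trajectory reshapes: tilt and low-order Fourier modes
        #     of the biomass path, compensated in the effort (or
        #     catchability) path so the harvest — hence the catch fit —
        #     stays put.  These traverse the broad "which depletion
        #     history" directions that single-site updates only reach
        #     diffusively.
        for name, w, comp in shape_moves:
            sc = param_scales[name]
            dstep = sc.scale * rng.normal(size=C)
            bump = dstep[:, None] * w[None, :]
            if comp == "e":
                lp_prop = total_lp(logr, logK, logchi, x - bump, e + bump, u,
                                   s2B, s2E, s2Q)
            else:
                lp_prop = total_lp(logr, logK, logchi, x - bump, e, u + bump,
                                   s2B, s2E, s2Q)
            acc = np.log(rng.uniform(size=C)) < lp_prop - lp
            x = np.where(acc[:, None], x - bump, x)
            if comp == "e":
                e = np.where(acc[:, None], e + bump, e)
            else:
                u = np.where(acc[:, None], u + bump, u)
            lp = np.where(acc, lp_prop, lp)
            sc.update(acc, adapting)

        # ---- Gibbs for the three process variances ---------------------
        r_, K_, chi_ = np.exp(logr), np.exp(logK), np.exp(logchi)
        B = np.exp(x)
        harvest = np.exp(u + e + x)
        pred = B[:, :-1] + r_[:, None] * B[:, :-1] * (1.0 - B[:, :-1] / K_[:, None]) \
            - harvest[:, :-1]
        residB = x[:, 1:] - np.log(pred)
        drift = effort_drift(B[:, :-1] / (d * K_[:, None]), chi_[:, None])
        residE = e[:, 1:] - e[:, :-1] - drift
        residQ = u[:, 1:] - u[:, :-1]
        s2B = sample_invgamma(rng, aB + 0.5 * (T - 1), bB + 0.5 * (residB**2).sum(axis=1), size=C)
        s2E = sample_invgamma(rng, aE + 0.5 * (T - 1), bE + 0.5 * (residE**2).sum(axis=1), size=C)
        s2Q = sample_invgamma(rng, aQ + 0.5 * (T - 1), bQ + 0.5 * (residQ**2).sum(axis=1), size=C)
        lp = total_lp(logr, logK, logchi, x, e, u, s2B, s2E, s2Q)

        # ---- red/black state updates ----------------------------------
        # Each site's Metropolis delta touches only the terms containing
        # that state, so per half-sweep we recompute just the affected
        # columns of the prediction/drift arrays.
        invB = 1.0 / (2.0 * s2B)[:, None]
        invE = 1.0 / (2.0 * s2E)[:, None]
        invQ = 1.0 / (2.0 * s2Q)[:, None]
        invO = inv_obs
        rr = r_[:, None]
        KK = K_[:, None]
        cc = chi_[:, None]

        B = np.exp(x)
        H = np.exp(u + e + x)
        pred = B[:, :-1] + rr * B[:, :-1] * (1.0 - B[:, :-1] / KK) - H[:, :-1]
        log_pred = np.log(np.where(pred > 0, pred, 1.0))
        drift = effort_drift(B[:, :-1] / (d * KK), cc)

        for which, halves in (("x", halves_x), ("e", halves_all), ("u", halves_all)):
            sc_arr = scales[which]
            for idx in halves:
                has_prev = (idx >= 1)[None, :]
                prv = np.maximum(idx - 1, 0)
                has_next = (idx < T - 1)[None, :]
                nxt = np.minimum(idx + 1, T - 1)
                safe = np.minimum(idx, T - 2)

                cur = {"x": x, "e": e, "u": u}[which][:, idx]
                prop = cur + sc_arr.scale[:, idx] * rng.normal(size=(C, len(idx)))

                if which == "x":
                    Bp = np.exp(prop)
                    Hp = H[:, idx] * np.exp(prop - cur)
                    pc = Bp + rr * Bp * (1.0 - Bp / KK) - Hp
                    driftp = effort_drift(Bp / (d * KK), cc)
                    tin = (-((prop - log_pred[:, prv]) ** 2)
                           + ((cur - log_pred[:, prv]) ** 2)) * invB
                    out_cur = -((x[:, nxt] - log_pred[:, safe]) ** 2) * invB
                    out_prop = np.where(pc > 0,
                                        -((x[:, nxt] - np.log(np.where(pc > 0, pc, 1.0))) ** 2) * invB,
                                        -np.inf)
                    eff_cur = -((e[:, nxt] - e[:, idx] - drift[:, safe]) ** 2) * invE
                    eff_prop = -((e[:, nxt] - e[:, idx] - driftp) ** 2) * invE
                    obs_d = (-((log_catch[None, idx] - u[:, idx] - e[:, idx] - prop) ** 2)
                             + ((log_catch[None, idx] - u[:, idx] - e[:, idx] - cur) ** 2)) * invO
                    delta = tin + np.where(has_next, (out_prop - out_cur)
                                           + (eff_prop - eff_cur), 0.0) + obs_d
                else:
                    if which == "e":
                        base = u[:, idx] + x[:, idx]
                        walk_in = (-((prop - e[:, prv] - drift[:, prv]) ** 2)
                                   + ((cur - e[:, prv] - drift[:, prv]) ** 2)) * invE
                        walk_out = (-((e[:, nxt] - prop - drift[:, safe]) ** 2)
                                    + ((e[:, nxt] - cur - drift[:, safe]) ** 2)) * invE
                        init_d = (-0.5 * (prop - e1_mu) ** 2 + 0.5 * (cur - e1_mu) ** 2)
                    else:
                        base = e[:, idx] + x[:, idx]
                        walk_in = (-((prop - u[:, prv]) ** 2) + ((cur - u[:, prv]) ** 2)) * invQ
                        walk_out = (-((u[:, nxt] - prop) ** 2) + ((u[:, nxt] - cur) ** 2)) * invQ
                        init_d = (-0.5 * (prop - u1_mu[:, None]) ** 2
                                  + 0.5 * (cur - u1_mu[:, None]) ** 2)
                    # harvest at t changes; biomass transition t -> t+1 shifts
                    Hp = H[:, idx] * np.exp(prop - cur)
                    pc = pred[:, safe] + H[:, idx] - Hp
                    out_cur = -((x[:, nxt] - log_pred[:, safe]) ** 2) * invB
                    out_prop = np.where(pc > 0,
                                        -((x[:, nxt] - np.log(np.where(pc > 0, pc, 1.0))) ** 2) * invB,
                                        -np.inf)
                    obs_d = (-((log_catch[None, idx] - base - prop) ** 2)
                             + ((log_catch[None, idx] - base - cur) ** 2)) * invO
                    delta = np.where(has_prev, walk_in, 0.0) \
                        + np.where(has_next, walk_out + (out_prop - out_cur), 0.0) \
                        + obs_d + np.where((idx == 0)[None, :], init_d, 0.0)

                acc = np.log(rng.uniform(size=delta.shape)) < delta
                upd = np.where(acc, prop, cur)
                sel = idx[idx <= T - 2]
                if which == "x":
                    x[:, idx] = upd
                    B[:, idx] = np.exp(upd)
                    H[:, idx] = np.exp(u[:, idx] + e[:, idx] + upd)
                    drift[:, sel] = effort_drift(B[:, sel] / (d * KK), cc)
                else:
                    if which == "e":
                        e[:, idx] = upd
                    else:
                        u[:, idx] = upd
                    H[:, idx] = np.exp(u[:, idx] + e[:, idx] + x[:, idx])
                pred[:, sel] = B[:, sel] + rr * B[:, sel] * (1.0 - B[:, sel] / KK) - H[:, sel]
                log_pred[:, sel] = np.log(np.where(pred[:, sel] > 0, pred[:, sel], 1.0))
                lp = lp + np.sum(np.where(acc, delta, 0.0), axis=1)
                if rm_step:
                    sc_arr.log_scale[:, idx] += rm_step * (acc - 0.44)
                acc_count["states"] += acc.mean() / 6.0

        if it >= cfg.mcmc.burn_in and (it - cfg.mcmc.burn_in) % cfg.mcmc.thin == 0 and ptr < n_kept:
            kept["r"][:, ptr] = np.exp(logr)
            kept["K"][:, ptr] = np.exp(logK)
            kept["chi"][:, ptr] = np.exp(logchi)
            kept["s2B"][:, ptr] = s2B
            kept["s2E"][:, ptr] = s2E
            kept["s2Q"][:, ptr] = s2Q
            kept_b[:, ptr, :] = np.exp(x)
            ptr += 1

    rhat = {k: split_rhat(kept[k]) for k in ("r", "K", "chi")}
    status = kept_b / (kept["K"][:, :, None] / 2.0)
    # Convergence is judged on the reported quantity: r and K individually
    # are ridge directions that a catch series only weakly identifies,
    # while the B/B_MSY trajectory is the estimand.  Split-R-hat of the
    # log status at representative years gates the failure flag.
    check_years = sorted({T // 4, T // 2, 3 * T // 4, T - 1})
    rhat_status = {f"status_y{y + 1}": split_rhat(np.log(status[:, :, y]))
                   for y in check_years}
    rhat.update(rhat_status)
    converged = all(np.isfinite(v) and v <= cfg.convergence_rhat_threshold
                    for v in rhat_status.values())
    flat = status.reshape(-1, T)
    diagnostics = {"rhat": rhat,
                   "accept": {k: v / cfg.mcmc.iterations for k, v in acc_count.items()}}
    if not converged:
        res = _failed_result("sscom", diagnostics)
        res.params = {k: float(np.median(kept[k])) for k in ("r", "K", "chi")}
        return res
    return ComResult(
        method="sscom", years=None,
        bbmsy_median=np.median(flat, axis=0),
        bbmsy_lo=np.quantile(flat, 0.025, axis=0),
        bbmsy_hi=np.quantile(flat, 0.975, axis=0),
        params={"r": float(np.median(kept["r"])), "K": float(np.median(kept["K"])),
                "chi": float(np.median(kept["chi"])),
                "MSY": float(np.median(kept["r"] * kept["K"] / 4.0)),
                "bmsy": float(np.median(kept["K"])) / 2.0},
        n_viable=kept["r"].size, converged=True, failed=False,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_METHODS = {"cmsy13": cmsy2013_fit, "cmsy17": cmsy2017_fit,
            "ocom": ocom_fit, "sscom": sscom_fit}


def fit_com(method: str, catch, cfg=None, rng=None) -> ComResult:
    """Run one catch-only method by its tag (cmsy13 | cmsy17 | ocom | sscom)."""
    if method not in _METHODS:
        raise ValueError(f"unknown method: {method!r}")
    return _METHODS[method](catch, cfg, rng)
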