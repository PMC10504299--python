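"""Shared building blocks for the hand-rolled Gibbs/Metropolis samplers.

Both state-space models in this package (the surplus-production truth model
and the state-space catch-only estimator) use the same machinery: adaptive
random-walk Metropolis for parameters, red/black single-site updates for
latent log-states, conjugate inverse-gamma Gibbs steps for process
variances, and split-R-hat convergence diagnostics.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import ndtri

LOG_2PI = math.log(2.0 * math.pi)


def norm_logpdf(x, mu, sd):
    """Normal log density, vectorised."""
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * LOG_2PI


def invgamma_logpdf(x, shape, rate):
    """Inverse-gamma log density (shape/rate parameterisation), unnormalised-safe."""
    x = np.asarray(x, dtype=float)
    return (
        shape * np.log(rate)
        - math.lgamma(shape)
        - (shape + 1.0) * np.log(x)
        - rate / x
    )


def beta_logpdf(x, a, b):
    x = np.asarray(x, dtype=float)
    out = np.full(np.shape(x), -np.inf, dtype=float)
    ok = (x > 0) & (x < 1)
    xo = np.where(ok, x, 0.5)
    lp = (
        (a - 1.0) * np.log(xo)
        + (b - 1.0) * np.log1p(-xo)
        + math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
    )
    return np.where(ok, lp, out)[()]


def lognormal_range_prior(lo: float, hi: float, coverage: float = 0.95) -> tuple[float, float]:
    """Lognormal whose central ``coverage`` interval spans (lo, hi).

    This realises the "range" style prior of JABBA-like models: the stated
    bounds are interpreted as the 2.5% and 97.5% quantiles.
    """
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lo < hi")
    zq = float(ndtri(0.5 + coverage / 2.0))
    mu = 0.5 * (math.log(lo) + math.log(hi))
    sd = (math.log(hi) - math.log(lo)) / (2.0 * zq)
    return mu, sd


def beta_from_mean_cv(mean: float, cv: float) -> tuple[float, float]:
    """Moment-matched beta(a, b) with the given mean and coefficient of variation."""
    if not (0 < mean < 1) or cv <= 0:
        raise ValueError("need 0 < mean < 1 and cv > 0")
    var = (cv * mean) ** 2
    nu = mean * (1.0 - mean) / var - 1.0
    if nu <= 0:
        raise ValueError("mean/cv combination is not beta-representable")
    return mean * nu, (1.0 - mean) * nu


def sample_invgamma(rng: np.random.Generator, shape, rate, size=None):
    """Draw from an inverse-gamma (shape/rate) distribution."""
    return rate / rng.gamma(shape, 1.0, size=size)


def sample_invgamma_truncated(rng: np.random.Generator, shape, rate, lower):
    """Inverse-gamma draw truncated below at ``lower`` (exact, via the CDF)."""
    from scipy.stats import invgamma

    dist = invgamma(shape, scale=rate)
    lo = dist.cdf(lower)
    u = lo + (1.0 - lo) * rng.uniform(size=np.shape(rate))
    return np.maximum(dist.ppf(u), lower)


def split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of Gelman et al. for draws shaped (chains, iterations).

    Each chain is split in half, then the classic potential-scale-reduction
    statistic is computed on the 2*chains half-chains.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected (chains, draws)")
    n = x.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0 if b == 0 else np.inf
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


class RMScale:
    """Robbins-Monro adapted proposal scale(s), frozen after burn-in.

    ``accept`` is called with a boolean array (or scalar) of acceptances of
    the same shape as the scale array; the log-scale moves toward the
    target acceptance rate with a decaying step size.
    """

    def __init__(self, shape, init=0.5, target=0.3):
        self.log_scale = np.full(shape, math.log(init))
        self.target = target
        self._t = 0

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted, adapting: bool) -> None:
        self._t += 1
        if not adapting:
            return
        step = min(0.25, 2.0 / math.sqrt(self._t))
        self.log_scale += step * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_scale, math.log(1e-5), math.log(50.0), out=self.log_scale)
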