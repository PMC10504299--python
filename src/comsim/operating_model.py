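"""Age-structured operating model for a short-lived small pelagic stock.

This module plays the role of "reality" in a simulation-testing framework:
an annual-time-step age-structured population with von Bertalanffy growth,
allometric length-weight, logistic maturity, Beverton-Holt recruitment and
age-based fishery selectivity.  It produces the true biomass/status series
and the observed catch and abundance-index series that the assessment
methods are scored against.

Conventions
-----------
* Numbers are individuals; weights are grams; aggregated biomass and yield
  are reported in tonnes (1 t = 1e6 g).
* Mortality is continuous within a year: Z_a = M + S_a * F, survival
  exp(-Z), catch by the Baranov equation.
* Spawning occurs mid-year by default (``spawn_frac`` of the annual
  mortality is endured before spawning).
* The oldest age is a plus group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "LifeHistory",
    "FleetSpec",
    "ObservationSpec",
    "ScenarioSpec",
    "PopulationTrajectory",
    "SimulatedDataset",
    "RefPoints",
    "ScenarioRun",
    "length_at_age",
    "weight_at_length",
    "maturity_at_age",
    "selectivity_at_age",
    "unfished_refs",
    "bh_recruits",
    "project_population",
    "equilibrium_curve",
    "find_fmsy",
    "observe_catch",
    "observe_index",
    "run_scenario",
]

G_PER_TONNE = 1.0e6


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeHistory:
    """Biological parameters of the simulated stock.

    Defaults describe a short-lived small pelagic (anchovy-like) stock:
    high natural mortality, fast growth, maturity at age 1, ages 0-5.

    Parameters
    ----------
    M : natural mortality (yr^-1).
    Linf, k, t0 : von Bertalanffy parameters (cm, yr^-1, yr).
    lw_a, lw_b : length-weight scaling and allometric exponent (W = a L^b, g).
    a50_mat : age at 50% maturity (yr).
    cv_a50_mat : relative spread of the maturity ogive; also used as the
        between-replicate variability of the maturity midpoint.
    ages : inclusive (min, max) integer age range; max age is a plus group.
    n0 : numbers at the first age in the first (unfished) year; this is the
        unfished recruitment R0.
    steepness : Beverton-Holt steepness h on (0.2, 1].
    sigma_R : lognormal recruitment-deviation scale.
    cv_M : between-replicate coefficient of variation of M.
    spawn_frac : fraction of the annual total mortality endured before
        spawning (0 = spawn at the start of the year, 0.5 = mid-year).
    """

    M: float = 1.35
    Linf: float = 17.0
    k: float = 1.39
    t0: float = 0.0
    lw_a: float = 0.0041
    lw_b: float = 3.1818
    a50_mat: float = 1.0
    cv_a50_mat: float = 0.15
    ages: tuple[int, int] = (0, 5)
    n0: float = 200_000.0
    steepness: float = 0.5
    sigma_R: float = 0.3
    cv_M: float = 0.15
    spawn_frac: float = 0.5

    def __post_init__(self) -> None:
        if min(self.M, self.Linf, self.k, self.lw_a, self.lw_b, self.n0) <= 0:
            raise ValueError("rates, lengths and scalings must be strictly positive")
        if self.a50_mat <= 0 or self.cv_a50_mat < 0:
            raise ValueError("a50_mat must be positive and cv_a50_mat >= 0")
        lo, hi = self.ages
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))):
            raise ValueError("age bounds must be integers")
        if hi < lo or lo < 0:
            raise ValueError("age range must satisfy 0 <= min <= max")
        if not (0.2 < self.steepness <= 1.0):
            raise ValueError("steepness must be in (0.2, 1]")
        if self.sigma_R < 0 or self.cv_M < 0:
            raise ValueError("cv/sd values must be >= 0")
        if not (0.0 <= self.spawn_frac <= 1.0):
            raise ValueError("spawn_frac must be in [0, 1]")

    @property
    def age_vector(self) -> np.ndarray:
        lo, hi = self.ages
        return np.arange(lo, hi + 1)


@dataclass(frozen=True)
class FleetSpec:
    """Fishery selectivity configuration.

    ``logistic`` uses a sigmoid with midpoint ``a50_sel`` and spread
    ``cv_sel * a50_sel``; ``double-normal`` a plateau-1 dome centred at
    ``a50_sel`` with the same relative spread on each limb.  Either form is
    zeroed outside the fished age window [min_f_age, max_f_age].
    """

    a50_sel: float = 1.5
    cv_sel: float = 0.15
    min_f_age: int = 1
    max_f_age: int = 3
    form: str = "logistic"

    def __post_init__(self) -> None:
        if self.a50_sel <= 0 or self.cv_sel < 0:
            raise ValueError("a50_sel must be positive and cv_sel >= 0")
        if self.min_f_age > self.max_f_age:
            raise ValueError("min_f_age must be <= max_f_age")
        if self.form not in ("logistic", "double-normal"):
            raise ValueError(f"unknown selectivity form: {self.form!r}")


@dataclass(frozen=True)
class ObservationSpec:
    """Observation-error configuration for the sampled data streams."""

    sigma_log_catch: float = 0.005
    cv_catch_numbers: float = 0.2
    q_index: float = 1.0e-4
    gamma: float = 1.0
    cv_index: float = 0.2
    aggregate_index: bool = True

    def __post_init__(self) -> None:
        if min(self.sigma_log_catch, self.cv_catch_numbers, self.cv_index) < 0:
            raise ValueError("error scales must be >= 0")
        if self.q_index <= 0:
            raise ValueError("q_index must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """Definition of one fishing scenario.

    ``f_rule='constant'`` applies ``f_multipliers[0] * FMSY`` every year;
    ``f_rule='two-phase'`` applies ``f_multipliers[0] * FMSY`` through
    ``phase_break_year`` (1-based, inclusive) and ``f_multipliers[1] * FMSY``
    afterwards.  A burn-in of ``burn_in_years`` under the scenario's
    initial F precedes the reported series, so each scenario starts at
    its own fished quasi-equilibrium with a randomised age structure
    rather than at an arbitrary initial state.
    """

    name: str = "scenario-1"
    n_years: int = 100
    f_rule: str = "constant"
    f_multipliers: tuple[float, ...] = (1.0,)
    phase_break_year: int = 75
    calendar_start: int = 1951
    n_replicates: int = 500
    seed: int = 1234
    burn_in_years: int = 10

    def __post_init__(self) -> None:
        if self.n_years < 1 or self.n_replicates < 1:
            raise ValueError("n_years and n_replicates must be >= 1")
        if self.f_rule not in ("constant", "two-phase"):
            raise ValueError(f"unknown f_rule: {self.f_rule!r}")
        if self.f_rule == "two-phase" and len(self.f_multipliers) < 2:
            raise ValueError("two-phase rule needs two f multipliers")
        if any(m <= 0 for m in self.f_multipliers):
            raise ValueError("f multipliers must be > 0")
        if not (1 <= self.phase_break_year < self.n_years):
            raise ValueError("phase_break_year must lie inside the horizon")

    def f_multiplier_series(self) -> np.ndarray:
        if self.f_rule == "constant":
            return np.full(self.n_years, float(self.f_multipliers[0]))
        out = np.full(self.n_years, float(self.f_multipliers[1]))
        out[: self.phase_break_year] = float(self.f_multipliers[0])
        return out


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class PopulationTrajectory:
    """One realisation of the true population dynamics."""

    numbers_at_age: np.ndarray  # (n_ages, n_years)
    ssb: np.ndarray  # tonnes
    total_biomass: np.ndarray  # tonnes
    exploitable_biomass: np.ndarray  # tonnes
    f_by_year: np.ndarray
    true_catch_weight: np.ndarray  # tonnes
    catch_numbers_at_age: np.ndarray  # (n_ages, n_years)
    true_status: np.ndarray | None = None  # total_biomass / BMSY_OM


@dataclass
class SimulatedDataset:
    """Observed series plus the underlying truth for one replicate."""

    years: np.ndarray
    observed_catch: np.ndarray
    observed_index: np.ndarray
    trajectory: PopulationTrajectory
    replicate_id: int
    seed: int
    collapsed: bool = False
    m_draw: float | None = None
    a50_mat_draw: float | None = None


@dataclass(frozen=True)
class RefPoints:
    """Deterministic equilibrium reference points of the operating model."""

    fmsy: float
    msy: float
    bmsy: float  # equilibrium total biomass at FMSY (t)
    b0: float  # unfished equilibrium total biomass (t)


@dataclass
class ScenarioRun:
    spec: ScenarioSpec
    refs: RefPoints
    datasets: list[SimulatedDataset]


# ---------------------------------------------------------------------------
# vital rates
# ---------------------------------------------------------------------------


def length_at_age(age, lh: LifeHistory):
    """von Bertalanffy length (cm) at ``age`` (yr), clipped below at zero."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    out = lh.Linf * (1.0 - np.exp(-lh.k * (age - lh.t0)))
    return np.clip(out, 0.0, None)[()]


def weight_at_length(length, lh: LifeHistory):
    """Allometric weight (g) at ``length`` (cm): W = a * L^b."""
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("length must be >= 0")
    return (lh.lw_a * length**lh.lw_b)[()]


def maturity_at_age(age, lh: LifeHistory, a50: float | None = None):
    """Logistic maturity ogive with slope 1 / (cv_a50_mat * a50_mat)."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    a50 = lh.a50_mat if a50 is None else a50
    slope = 1.0 / (lh.cv_a50_mat * a50)
    return (1.0 / (1.0 + np.exp(-slope * (age - a50))))[()]


def selectivity_at_age(age, fleet: FleetSpec):
    """Age-based fishery selectivity in [0, 1], zeroed outside the fished window."""
    age = np.asarray(age, dtype=float)
    spread = fleet.cv_sel * fleet.a50_sel
    if fleet.form == "logistic":
        sel = 1.0 / (1.0 + np.exp(-(age - fleet.a50_sel) / spread))
    else:  # double-normal: plateau-1 dome centred at a50_sel
        sel = np.exp(-((age - fleet.a50_sel) ** 2) / (2.0 * spread**2))
    window = (age >= fleet.min_f_age) & (age <= fleet.max_f_age)
    return np.where(window, sel, 0.0)[()]


# ---------------------------------------------------------------------------
# equilibrium and recruitment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnfishedRefs:
    """Analytic unfished per-recruit quantities (spawning discounted by spawn_frac)."""

    r0: float
    sbpr0: float  # grams of spawning biomass per recruit
    ssb0: float  # tonnes

    @property
    def ssb0_grams(self) -> float:
        return self.ssb0 * G_PER_TONNE


def _survivorship(z: np.ndarray) -> np.ndarray:
    """Equilibrium numbers-per-recruit for total mortality ``z`` per age.

    Last age is a plus group: l_A = l_{A-1} e^{-Z_{A-1}} / (1 - e^{-Z_A}).
    """
    n = len(z)
    l = np.ones(n)
    for a in range(1, n):
        l[a] = l[a - 1] * np.exp(-z[a - 1])
    l[-1] = l[-1] / (1.0 - np.exp(-z[-1]))
    return l


def _weights_and_maturity(lh: LifeHistory, a50: float | None = None):
    ages = lh.age_vector
    w = weight_at_length(length_at_age(ages, lh), lh)
    mat = np.asarray(maturity_at_age(ages, lh, a50=a50), dtype=float).copy()
    # the first age class was spawned this year and does not spawn itself
    mat[0] = 0.0
    return ages, np.atleast_1d(w), mat


def unfished_refs(lh: LifeHistory, a50: float | None = None) -> UnfishedRefs:
    """Unfished equilibrium R0, spawning-biomass-per-recruit, and SSB0."""
    ages, w, mat = _weights_and_maturity(lh, a50)
    z = np.full(len(ages), lh.M)
    l = _survivorship(z)
    sbpr = float(np.sum(l * mat * w * np.exp(-lh.spawn_frac * z)))
    r0 = lh.n0
    return UnfishedRefs(r0=r0, sbpr0=sbpr, ssb0=r0 * sbpr / G_PER_TONNE)


def bh_recruits(ssb, lh: LifeHistory, refs: UnfishedRefs, dev=1.0):
    """Steepness-parameterised Beverton-Holt recruitment.

    R = 4 h R0 S / (SSB0 (1-h) + S (5h-1)), times a (bias-corrected,
    caller-supplied) lognormal deviation ``dev``.  ``ssb`` in tonnes.
    """
    ssb = np.asarray(ssb, dtype=float)
    if np.any(ssb < 0):
        raise ValueError("ssb must be >= 0")
    h = lh.steepness
    num = 4.0 * h * refs.r0 * ssb
    den = refs.ssb0 * (1.0 - h) + ssb * (5.0 * h - 1.0)
    return (np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0) * dev)[()]


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def project_population(
    lh: LifeHistory,
    fleet: FleetSpec,
    f_series: Sequence[float],
    recruit_devs: Sequence[float] | None = None,
    a50_mat: float | None = None,
) -> PopulationTrajectory:
    """Project the age-structured population under a per-year F series.

    The population starts at the unfished equilibrium age structure implied
    by R0 = n0.  Within each year: spawning biomass is evaluated after
    ``spawn_frac`` of the year's mortality, recruits enter the first age
    class, the Baranov catch is removed, and survivors advance one age with
    the oldest age acting as a plus group.
    """
    f_series = np.asarray(f_series, dtype=float)
    if not np.all(np.isfinite(f_series)):
        raise ValueError("f_series must be finite")
    if recruit_devs is None:
        recruit_devs = np.ones_like(f_series)
    recruit_devs = np.asarray(recruit_devs, dtype=float)
    if len(recruit_devs) != len(f_series):
        raise ValueError("recruit_devs must match f_series in length")

    ages, w, mat = _weights_and_maturity(lh, a50_mat)
    sel = np.atleast_1d(np.asarray(selectivity_at_age(ages, fleet), dtype=float))
    refs = unfished_refs(lh, a50_mat)

    n_years = len(f_series)
    n_ages = len(ages)
    numbers = np.zeros((n_ages, n_years))
    catch_n = np.zeros((n_ages, n_years))
    ssb = np.zeros(n_years)
    yield_t = np.zeros(n_years)

    l0 = _survivorship(np.full(n_ages, lh.M))
    current = refs.r0 * l0

    for t in range(n_years):
        z = lh.M + sel * f_series[t]
        # spawning biomass after spawn_frac of this year's mortality
        ssb_t = float(np.sum(mat * w * current * np.exp(-lh.spawn_frac * z))) / G_PER_TONNE
        if t > 0:
            current[0] = bh_recruits(ssb_t, lh, refs, dev=recruit_devs[t])
            ssb_t = float(np.sum(mat * w * current * np.exp(-lh.spawn_frac * z))) / G_PER_TONNE
        numbers[:, t] = current
        ssb[t] = ssb_t
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(z > 0, (sel * f_series[t]) / np.where(z > 0, z, 1.0), 0.0)
        catch_n[:, t] = frac * (1.0 - np.exp(-z)) * current
        yield_t[t] = float(np.sum(catch_n[:, t] * w)) / G_PER_TONNE
        survivors = current * np.exp(-z)
        nxt = np.zeros(n_ages)
        nxt[1:] = survivors[:-1]
        nxt[-1] += survivors[-1]  # plus group
        current = nxt

    total_b = (w[:, None] * numbers).sum(axis=0) / G_PER_TONNE
    expl_b = ((sel * w)[:, None] * numbers).sum(axis=0) / G_PER_TONNE
    return PopulationTrajectory(
        numbers_at_age=numbers,
        ssb=ssb,
        total_biomass=total_b,
        exploitable_biomass=expl_b,
        f_by_year=f_series.copy(),
        true_catch_weight=yield_t,
        catch_numbers_at_age=catch_n,
    )


def equilibrium_curve(
    lh: LifeHistory, fleet: FleetSpec, f_grid: np.ndarray, n_years: int = 250
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic long-run yield and total biomass for each F on a grid.

    Vectorised over the grid: every F is projected for ``n_years`` with zero
    recruitment deviations and the final-year yield/biomass are returned.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    ages, w, mat = _weights_and_maturity(lh)
    sel = np.atleast_1d(np.asarray(selectivity_at_age(ages, fleet), dtype=float))
    refs = unfished_refs(lh)
    n_f, n_ages = len(f_grid), len(ages)

    l0 = _survivorship(np.full(n_ages, lh.M))
    numbers = np.tile(refs.r0 * l0, (n_f, 1))  # (n_f, n_ages)
    z = lh.M + f_grid[:, None] * sel[None, :]
    spawn_disc = np.exp(-lh.spawn_frac * z)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(z > 0, (f_grid[:, None] * sel[None, :]) / np.where(z > 0, z, 1.0), 0.0)
    catch_frac = frac * (1.0 - np.exp(-z))
    surv = np.exp(-z)

    yields = np.zeros(n_f)
    for t in range(n_years):
        ssb = (numbers * mat[None, :] * w[None, :] * spawn_disc).sum(axis=1) / G_PER_TONNE
        if t > 0:
            numbers[:, 0] = bh_recruits(ssb, lh, refs)
            ssb = (numbers * mat[None, :] * w[None, :] * spawn_disc).sum(axis=1) / G_PER_TONNE
        yields = (numbers * catch_frac * w[None, :]).sum(axis=1) / G_PER_TONNE
        survivors = numbers * surv
        nxt = np.zeros_like(numbers)
        nxt[:, 1:] = survivors[:, :-1]
        nxt[:, -1] += survivors[:, -1]
        numbers = nxt

    biomass = (numbers * w[None, :]).sum(axis=1) / G_PER_TONNE
    return yields, biomass


def find_fmsy(
    lh: LifeHistory, fleet: FleetSpec, f_grid: np.ndarray | None = None
) -> RefPoints:
    """Grid search for the deterministic equilibrium MSY reference points.

    Raises if the yield curve has no interior maximum on the grid (a
    diagnostic for configurations where equilibrium yield is monotone in F).
    """
    if f_grid is None:
        f_grid = np.linspace(0.0, 6.0, 241)
    f_grid = np.asarray(f_grid, dtype=float)
    if len(f_grid) < 100:
        raise ValueError("f_grid must have at least 100 points")
    yields, biomass = equilibrium_curve(lh, fleet, f_grid)
    i = int(np.argmax(yields))
    if i == len(f_grid) - 1:
        raise RuntimeError(
            "equilibrium yield is monotone on the F grid; no interior FMSY"
        )
    return RefPoints(
        fmsy=float(f_grid[i]),
        msy=float(yields[i]),
        bmsy=float(biomass[i]),
        b0=float(biomass[0]),
    )


# ---------------------------------------------------------------------------
# observation processes
# ---------------------------------------------------------------------------


def observe_catch(true_catch, obs: ObservationSpec, rng: np.random.Generator):
    """Multiplicative lognormal observation error on the yield series."""
    true_catch = np.asarray(true_catch, dtype=float)
    if obs.sigma_log_catch == 0:
        return true_catch.copy()
    return true_catch * np.exp(rng.normal(0.0, obs.sigma_log_catch, size=true_catch.shape))


def observe_index(
    numbers_at_age: np.ndarray,
    obs: ObservationSpec,
    rng: np.random.Generator | None = None,
    survey_sel: np.ndarray | None = None,
):
    """Abundance index IA_{a,t} = q * N_{a,t}^gamma with lognormal error.

    The error scale is derived from the relative error: sd(log) =
    sqrt(log(1 + cv^2)); the error is median-centred on the noise-free
    index.  If ``aggregate_index`` the survey-selectivity-weighted sum over
    ages is returned per year (survey selectivity defaults to 1 at all
    ages).
    """
    n = np.asarray(numbers_at_age, dtype=float)
    if np.any(n < 0):
        raise ValueError("numbers must be >= 0")
    ia = obs.q_index * n**obs.gamma
    if obs.cv_index > 0:
        if rng is None:
            raise ValueError("an rng is required when cv_index > 0")
        sd = np.sqrt(np.log1p(obs.cv_index**2))
        ia = ia * np.exp(rng.normal(0.0, sd, size=ia.shape))
    if not obs.aggregate_index or ia.ndim == 1:
        return ia
    if survey_sel is None:
        survey_sel = np.ones(ia.shape[0])
    return (survey_sel[:, None] * ia).sum(axis=0)


# ---------------------------------------------------------------------------
# scenario driver
# ---------------------------------------------------------------------------


def replicate_rng(base_seed: int, replicate: int, stream: int = 0) -> np.random.Generator:
    """Deterministic per-replicate RNG via seed-sequence spawning."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(replicate), int(stream)))
    return np.random.default_rng(ss)


def run_scenario(
    spec: ScenarioSpec,
    lh: LifeHistory | None = None,
    fleet: FleetSpec | None = None,
    obs: ObservationSpec | None = None,
    refs: RefPoints | None = None,
    deterministic: bool = False,
) -> ScenarioRun:
    """Simulate ``spec.n_replicates`` datasets under one fishing scenario.

    FMSY is computed once from the base life history; each replicate draws
    its own natural mortality and maturity midpoint (cv_M, cv_a50_mat) and
    its own recruitment deviations, projects the population through a
    burn-in at the scenario's initial F followed by the scenario F series,
    and samples the observed catch and abundance index.
    ``deterministic=True`` switches off every stochastic element (useful
    for equilibrium checks).
    """
    lh = lh or LifeHistory()
    fleet = fleet or FleetSpec()
    obs = obs or ObservationSpec()
    if refs is None:
        refs = find_fmsy(lh, fleet)

    mults = spec.f_multiplier_series()
    f_scenario = mults * refs.fmsy
    nb = spec.burn_in_years
    years = spec.calendar_start + np.arange(spec.n_years)

    datasets: list[SimulatedDataset] = []
    for i in range(spec.n_replicates):
        rng = replicate_rng(spec.seed, i)
        if deterministic:
            lh_i = lh
            a50_i = lh.a50_mat
            devs = np.ones(nb + spec.n_years)
        else:
            m_i = lh.M * np.exp(rng.normal(0.0, lh.cv_M))
            a50_i = lh.a50_mat * np.exp(rng.normal(0.0, lh.cv_a50_mat))
            lh_i = replace(lh, M=m_i)
            z = rng.normal(0.0, 1.0, size=nb + spec.n_years)
            devs = np.exp(lh.sigma_R * z - 0.5 * lh.sigma_R**2)

        f_full = np.concatenate([np.full(nb, f_scenario[0]), f_scenario])
        traj = project_population(lh_i, fleet, f_full, devs, a50_mat=a50_i)

        # drop burn-in years from every reported series
        sl = slice(nb, None)
        traj = PopulationTrajectory(
            numbers_at_age=traj.numbers_at_age[:, sl],
            ssb=traj.ssb[sl],
            total_biomass=traj.total_biomass[sl],
            exploitable_biomass=traj.exploitable_biomass[sl],
            f_by_year=traj.f_by_year[sl],
            true_catch_weight=traj.true_catch_weight[sl],
            catch_numbers_at_age=traj.catch_numbers_at_age[:, sl],
            true_status=traj.total_biomass[sl] / refs.bmsy,
        )
        collapsed = bool(np.any(traj.total_biomass < 1e-9 * refs.b0))

        if deterministic:
            obs_i = replace(obs, sigma_log_catch=0.0, cv_index=0.0)
        else:
            obs_i = obs
        catch_obs = observe_catch(traj.true_catch_weight, obs_i, rng)
        # the survey fleet shares the fishery's selectivity pattern
        survey_sel = np.atleast_1d(
            np.asarray(selectivity_at_age(lh.age_vector, fleet), dtype=float))
        index_obs = observe_index(traj.numbers_at_age, obs_i, rng,
                                  survey_sel=survey_sel)
        datasets.append(
            SimulatedDataset(
                years=years.copy(),
                observed_catch=catch_obs,
                observed_index=np.asarray(index_obs),
                trajectory=traj,
                replicate_id=i,
                seed=spec.seed,
                collapsed=collapsed,
                m_draw=lh_i.M,
                a50_mat_draw=a50_i,
            )
        )
    return ScenarioRun(spec=spec, refs=refs, datasets=datasets)
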