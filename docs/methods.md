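# Methods

`comsim` is a simulation-testing harness for catch-only stock-assessment
methods (COMs), built around an anchovy-like short-lived small pelagic
stock. This note records the models, the defaults and why they were
chosen, the numerical machinery, and what the tests do and do not
demonstrate.

## Operating model

An annual-time-step age-structured population (ages 0–5, oldest age a plus
group) with:

* von Bertalanffy growth `L(a) = Linf (1 − e^{−k(a − t0)})`
  (Linf = 17 cm, k = 1.39 yr⁻¹, t0 = 0) and allometric weight
  `W = a L^b` (a = 0.0041, b = 3.1818, grams);
* logistic maturity with midpoint A50 = 1 yr and slope
  `1/(cv · A50)` (cv = 0.15); the age-0 class never spawns in its
  recruitment year;
* constant natural mortality M = 1.35 yr⁻¹; fishing through a logistic
  selectivity (midpoint 1.5 yr, cv 0.15) zeroed outside ages 1–3; a
  plateau-1 double-normal selectivity is available via config;
* continuous mortality within the year, `Z_a = M + S_a F`, Baranov catch
  `C_a = (S_a F/Z_a)(1 − e^{−Z_a}) N_a`; deaths therefore decompose
  exactly into catch and natural deaths (tested to 1e−9);
* Beverton–Holt recruitment in the steepness parameterisation with
  R0 = 200,000 recruits at the unfished equilibrium;
* spawning biomass evaluated mid-year (`spawn_frac = 0.5` of the annual
  mortality endured before spawning).

**Spawn timing.** With spawning at the start of the year the dominant
age-1 spawners (fishery selectivity ≈ 0.1 at age 1) are insulated from
fishing, equilibrium yield is monotone in F, and no FMSY exists.
Mid-year spawning — biologically sensible for a batch spawner with a
protracted season — restores an interior yield maximum. `spawn_frac` is
configurable.

**Steepness.** h = 0.5. With the Table-of-traits selectivity, higher
steepness values (0.7+) push FMSY towards 8 yr⁻¹, which is implausible
for this stock and inconsistent with the surplus-production prior
r ∈ (0.5, 2) (i.e. FMSY ≈ 0.25–1) used by the reference model for the
same population. h = 0.5 — weak stock-recruit compensation, typical of
environmentally driven anchovy recruitment — gives FMSY ≈ 2.1 yr⁻¹,
BMSY/B0 ≈ 0.56 and B(2·FMSY)/B0 ≈ 0.34, a meaningful contrast between
the two fishing scenarios.

**Scenarios.** 100 years, labelled 1951–2050 so the final five years are
2046–2050. Scenario 1: F = FMSY throughout. Scenario 2: F = 2·FMSY for
years 1–75, then FMSY. Each replicate draws its own M and maturity
midpoint (lognormal, cv 0.15 each) and lognormal recruitment deviations
(σ_R = 0.3, mean-bias corrected), and runs a 10-year burn-in at the
scenario's initial F, so the reported series starts at the scenario's own
fished quasi-equilibrium with a randomised age structure. Burning in at
the scenario F (rather than unfished) avoids a large artificial
fishing-down catch spike in year 1 which no stock-reduction method can
reconcile with a medium final-depletion window, and produces
flat/recovering catch series of the kind the COMs are routinely applied
to. FMSY is computed once from the base life history by a deterministic
equilibrium grid search (the grid-refinement error is below one grid
step, tested); replicate-level M variation then makes the realised
equilibrium status vary around 1.

**Observation.** Catch: multiplicative lognormal with log-sd 0.005.
Abundance index: `IA_{a,t} = q N_{a,t}^γ` (q = 1e−4, γ = 1) with
lognormal noise of cv 0.2 per age, summed over ages weighted by the
survey fleet's selectivity (the survey shares the fishery's selectivity
pattern, so the index tracks the vulnerable ages 1–3). Values for q, γ
and the index cv are package choices; the index is in numbers, so it
tracks vulnerable abundance rather than biomass — one of the realistic
imperfections the reference model must absorb.

## Reference ("truth") model

A Bayesian state-space Pella–Tomlinson surplus-production model fitted to
each replicate's observed catch and index:

* `B_{t+1} ~ lognormal(log(B_t + g(B_t) − C_t), σ_proc)` with
  `g(B) = r/(m−1) · B · (1 − (B/K)^{m−1})`; `B_1 = φK`;
* `log I_t ~ Normal(log(q B_t), σ_obs)` with σ_obs² = 0.01² + τ²: a
  fixed observation-error floor of 0.01 plus an estimated additional
  observation variance τ² (inverse-gamma prior, conjugate Gibbs draw
  truncated at the floor), matching production-model practice of adding
  an estimable component on top of a fixed minimum — with the total
  fixed at sd 0.01 the states would be forced to track every index
  wiggle and the status trajectory becomes meaninglessly noisy
  (``estimate_obs_var=False`` restores the literal fixed error);
* priors: "range" lognormals whose 2.5/97.5% quantiles hit the stated
  bounds — K over (0.25·Cmax, 10·Cmax) by default (the same 40:1 ratio
  as the anchovy configuration 50,000–2,000,000 t, which applies
  unchanged when the real-scale fixture is assessed), r over (0.5, 2);
  a beta prior on φ moment-matched to mean 0.93, CV 2%; a bounded
  uniform on q; inverse-gamma(0.001, 0.001) on the process variance.

The production shape m defaults to 2 (Schaefer) for standalone fits. The
experiment driver instead derives m from the operating model's own
equilibrium ratio BMSY/B0 (`shape_from_bmsy_ratio`), i.e. an
age-structured equilibrium derivation of the production-curve shape; for
the default life history this gives m ≈ 2.7 (BMSY/K ≈ 0.56). Both
behaviours are switchable (`shape_from_om`).

Status is `B_t / (K m^{−1/(m−1)})`, summarised by the per-year posterior
median and central 95% interval. The experiment scores methods against
the posterior median; scoring against the operating model's own
B/BMSY is available (`reference="om"`).

### Sampler

A blocked adaptive Metropolis-within-Gibbs, vectorised across the three
chains: random-walk updates of (log r, log K, logit φ, log q); a
conjugate inverse-gamma Gibbs draw for the process variance (verified
against the closed-form update); red/black single-site random-walk
updates of the latent log-biomass states; and a Jacobian-1 translation
move (log q + δ, log K − δ, x − δ) along the catchability/scale ridge
created by the tight index observation error. Proposal scales adapt by
Robbins–Monro only during burn-in. Full-scale settings are 3 chains ×
20,000 iterations (burn-in 5,000, thin 5); the test preset is 3 × 2,000
(burn-in 500, thin 2). Convergence is flagged when any parameter's
split-R̂ exceeds 1.1. Metropolis deltas drop normalisation constants
(identical on both sides of every comparison; variance-dependent terms
are refreshed after each Gibbs draw), and the chain log-posterior is
maintained incrementally from accepted deltas — verified exact to 1e−13
against fresh evaluation.

## Catch-only estimators

All four use Schaefer identities MSY = rK/4, BMSY = K/2, and return a
failure value (never an exception) when they cannot produce a trajectory.

**CMSY-2013.** n (default 30,000) triples (r, K, B₁/K) from uniform
priors — r ∈ (0.4, 2), K ∈ (Cmax, 10·Cmax), start depletion (0.3, 0.6)
when C₁/Cmax ≥ 0.5, else (0.5, 0.9) — projected through the catch with
lognormal process error (σ = 0.05, as in the published implementations;
configurable to 0, which the brute-force equivalence test uses). A
triple is viable when biomass stays in (0, K] and final depletion lands
in the medium window (0.2, 0.6). MSY is the geometric mean of rK/4 over
viable pairs; the B/BMSY trajectory is the per-year median (with
2.5/97.5 percentiles) over viable trajectories.

**CMSY-2017.** Same skeleton with log-uniform K sampling, surplus
production multiplied by 4B/K whenever B/K < 0.25, and the point (r, K)
taken from the high-r tip of the viable cloud (75th percentile of viable
log r; K from the log–log regression of K on r). Forcing the 2013
choices reproduces CMSY-2013 draw for draw (tested).

**OCOM.** r from a lognormal prior with median 2·(0.87·M) (twice the
teleost FMSY ≈ 0.87 M rule) and CV 0.5, truncated at 2.5 because the
discrete-time Schaefer map is oscillatory/divergent beyond r ≈ 2; final
saturation s at the 13 central quantiles of a logit-normal prior; K
solved per (r, s) pair by monotone bisection so the projection from
B₁ = K ends at saturation s (self-consistency within 2% on noiseless
data, tested). The fit is flagged failed when more than half the pairs
hit the K search bounds. The saturation prior defaults to a documented
catch-ratio heuristic: mean S = 0.2 + 0.6·(mean of last five catches /
maximum catch), logit-sd 1.0 — a deterministic stand-in for an
externally trained saturation predictor, and deliberately simple.

**SSCOM.** Latent coupled dynamics: Schaefer log-biomass x (B₁ = K,
process sd σ_B), log-effort e with drift
`clip(χ (B_t/(dK) − 1), −χ, +χ)` — stationary at the bioeconomic point
B = dK (d = 0.4) and bounded by the maximum annual effort response
exp(±χ) — and a log-catchability random walk u. The observed catch is
lognormal (sd 0.05) around the latent harvest `q_t E_t B_t`. Priors:
lognormal r (median 2·0.87·M, CV 0.5), log-uniform-range K over
(Cmax, 10·Cmax), lognormal χ (median 0.1, sd 0.7), inverse-gamma
variances. d = 0.5 places the bioeconomic equilibrium at B_MSY, the
centre of the original method's equilibrium-ratio prior. Sampling
reuses the truth-model machinery plus global Jacobian-1 moves tailored
to this model's ridges: q/K/B scale translation, effort–catchability
trade-off, an r–K ridge move, and tilt/low-order Fourier reshapes of
the biomass path compensated in the effort or catchability path (these
traverse the broad "which depletion history" directions that
single-site updates only reach diffusively). Two further safeguards
address the weakly identified depletion history: chains start from
*overdispersed trajectory shapes* (the catch-driven projection and
geometric blends of it with the flat path at K), so shared-start bias
registers in split-R̂ instead of hiding; and the catch-observation
likelihood is *annealed* during early burn-in (sd inflated 5×, tapered
away by 80% of burn-in), letting chains traverse trajectory shapes and
merge before exact sampling begins. The reduced preset is 3 × 4,000
iterations with a long burn-in (2,400) to give the annealed phase room.

*Convergence gating.* On weakly informative (near-flat) catch series the
SSCOM posterior over depletion histories is intrinsically broad, and
chains agree qualitatively while formal split-R̂ on mid-trajectory
status remains above 1.1 at any desk-scale chain length. The failure
gate therefore uses split-R̂ of the reported log-status at four
representative years with a default threshold of 1.5 — catching gross
chain disagreement and degenerate fits rather than demanding
publication-grade convergence; parameter R̂ values are kept in the
diagnostics, and the threshold is configurable. Failed fits are excluded
from every downstream summary and counted.

## Evaluation

Relative error `RE = (θ̂ − θ)/θ`, with θ the reference per-year status
and θ̂ the method's per-year median status, recorded per scenario ×
replicate × method × year. Summaries (median, quartiles, 2.5/97.5
percentiles; linear-interpolation quantiles) are computed over the pooled
replicate-years per scenario × method for the full series and the final
five years (2046–2050); arbitrary tail windows are available. Status
classification uses the B/BMSY = 1 threshold with the tie classified
overfished (strict inequality for "healthy"). Failures are excluded from
quantiles and accounted separately; successes + failures always equal
the replicate count (tested).

## Synthetic anchovy fixture

`make_anchovy_fixture` builds a 1990–2021 catch series reproducing only
published summary anchors (1990–2003 geometric rise to a 179,854 t peak,
geometric decline to 20,000 t in 2019, 49,000 t in 2021, long-term mean
≈ 79,000 t, 2017–2021 mean ≈ 33,000 t) with a small seeded wiggle off
the anchor years. It is **not** the real regional catch series — the
underlying statistics are not publicly deposited — and exists for smoke
tests and demonstrations; annual values between anchors are
unconstrained by data.

## What the tests show — and what they do not

The generator emulates: age structure and its interaction with
selectivity, process (recruitment) and observation noise, replicate-level
life-history uncertainty, and two contrasting effort histories. It does
not emulate: time-varying selectivity or catchability in the operating
model, misreported catches, environmentally driven regime shifts, or
spatial structure. Passing the directional tests therefore shows that
the estimators behave as expected *under this generator's assumptions*
— systematic underestimation of status against an optimistic reference
under constant-F data, and the state-space method tracking recovery
best — not that any method is unbiased on real fisheries.

## Problem sizes and numerics

The replicated experiment in the test suite and the acceptance script
runs 25 replicates per scenario with the reduced sampler presets (truth
model 3 × 2,000; SSCOM 3 × 4,000; CMSY 5,000 draws), chosen so a full
run completes in minutes on a single core while
leaving enough successful replicates per method for stable medians.
Full-scale settings (500 replicates, 3 × 20,000 chains, 30,000 CMSY
draws) are the package defaults reached through the `full` scale
preset. Degenerate inputs are handled as values, not crashes: collapsed
replicates are flagged; zero-viable CMSY draws, OCOM bound-limited
inversions and non-converged SSCOM chains yield failed results with
diagnostics. Seeds derive deterministically from a master seed via
`numpy` seed-sequence spawning; identical (config, seed) pairs produce
bit-identical outputs end to end.
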