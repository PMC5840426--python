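# Methods

This note documents the model, the estimators, the synthetic-data
generator and the numerical choices in `roosttrend`, in enough detail to
judge what a passing test suite does and does not establish.

## State-space model

The population is modelled on a monthly axis with two latent layers and
one observation layer, all log-normal with log-scale location and
log-scale variance:

* **Process.** `X_t ~ logN(log(X_{t−1} exp(ρ_t − μ_t)), σ²_proc)`.
  Recruitment `ρ_t` equals `ρ` in December–February (the breeding window,
  when young enter the countable population) and 0 otherwise; mortality
  `μ_t = μ (1 + (c_μ − 1) I_C(t))`. There is no density dependence: the
  model is exponential growth plus noise, which is the right null for a
  population far from any carrying-capacity signal.
* **Availability.** `X_t^C ~ logN(log(p_t X_t), σ²_camp)` with
  `p_t = (cos(2πc_t/12) + α₁)/α₂ · (1 − c_R I_C(t))`, `c_t` the calendar
  month. The cosine is phased so `p_t` peaks in December
  (`(α₁+1)/α₂`) and troughs in June (`(α₁−1)/α₂`); the constraints
  `α₁ > 1`, `α₂ > α₁ + 1` keep `p_t ∈ (0,1)`. `σ_camp` absorbs
  year-to-year deviation of roosting aggregation from the smooth seasonal
  trend.
* **Observation.** `Y_t ~ logN(log(X_t^C), σ²_obs)`, where `Y_t` is the
  sum of the per-camp counts in month `t`. Unsurveyed months simply lack
  this term; the latent layers persist through them.

**Cyclone profile.** `I_C(t)` steps to 1 at an event month and decays
linearly to 0 over `ramp_length` months (default 12). The ramp applies to
the *excess* mortality multiplier `c_μ − 1`, so the rate returns exactly
to `μ` after recovery. Overlapping ramps combine by pointwise maximum. A
pure 12-month year-indicator variant is available
(`CycloneSchedule(indicator="year")`). The recruitment multiplier `c_ρ`
applies to all three months of the first breeding season that *starts*
(December) at or after the event; later seasons are unaffected.

**Priors** (bounded, mostly flat): `ρ ~ U(0, 0.11)` (at most a ~40%
increase over one 3-month season), `μ ~ U(0, 0.1)` (at most ~70% loss
over a year), `c_μ ~ U(1, 10)`, `c_ρ, c_R ~ Beta(1.01, 1.01)` (near-flat
on (0,1), down-weighting the endpoints), `σ_obs ~ U(0.05, 0.47)`
(counting CV between 5% and 50%), `σ_proc ~ U(0, 10)`,
`σ_camp ~ U(0, 100)`, `α₁ ~ U(1, 49)`, `α₂ | α₁ ~ U(α₁+1, 50)`. The
nominally unbounded α supports are truncated at 50 — far beyond anything
compatible with `p_t ∈ (0,1)` — and the truncation is exposed on
`PriorSet`.

**Initial state.** `X₀ ~ logN(log(Y_first / 0.5), 1)`: centred on the
first observed count divided by a *fixed* nominal availability of 0.5,
with SD 1 on the log scale (a factor of ~7 either way). Centring on the
parameter-dependent `p_t` instead would cancel the availability level out
of the likelihood entirely and leave `α₂` unidentified — the absolute
scale of `X` is only ever identified through this prior, because `Y`
informs `p_t · X_t` jointly. This weak identification is by design;
`α₂`'s posterior is accordingly wide.

## Inference

Conditional on the parameters the model is **linear-Gaussian in the log
states**: `log X_t` is a Gaussian random walk with known drifts, and an
observed `log Y_t` is `log X_t + log p_t` plus Gaussian noise of variance
`σ²_camp + σ²_obs` (the in-camp layer marginalised). The sampler exploits
this structure:

* **Parameters** move one at a time by adaptive random-walk Metropolis on
  the natural scale, evaluated against the *exact marginal likelihood*
  from a scalar Kalman filter (latent states integrated out). All priors
  are bounded boxes, so out-of-support proposals are rejected through the
  prior; no transforms are needed. One additional correlated move steps
  along the recruitment–mortality ridge (`δμ = δρ/4`, holding
  `3ρ − 12μ` fixed), which the trend identifies tightly while `ρ` and `μ`
  individually are not. Proposal scales adapt toward 44% acceptance
  during burn-in only (Robbins–Monro, step `(i+1)^−0.6`) and are frozen
  afterwards, so the post-burn-in chain is a valid fixed-kernel sampler.
* **Latent states** are drawn exactly from their full conditional by
  forward-filtering backward-sampling (FFBS), then the in-camp layer by
  its conjugate normal conditional. This is an exact Gibbs step: no
  latent-state tuning, no autocorrelation from state random walks.

Together these give a Metropolis-within-Gibbs chain targeting the same
joint posterior as the hierarchical density in `model_core.log_joint`
(the two routes are cross-checked in the tests, both term-by-term and by
numerical integration on a tiny instance). Marginalisation buys a lot:
reduced-scale runs (3 chains × 5,000 after 2,000 burn-in) converge with
R̂ < 1.01 on 154-month data in seconds.

Defaults mirror the monitoring-study scale: 3 chains × 50,000 after
10,000 burn-in; parameter draws stored unthinned, state draws every 10
iterations. Convergence uses the plain Gelman–Rubin PSRF
(`sqrt(((n−1)/n·W + B/n)/W)`); values below 1 from finite-sample noise
are reported as exactly 1. The conventional 1.2 threshold is asserted in
the acceptance suite. Chains are initialized overdispersed (parameters
from the prior; states at `Y_t/p_t`, log-linearly interpolated over
missing months). Prior-only runs of the identical kernel
(`sample_prior`) reproduce every prior marginal with two-sample KS
distance < 0.05, a detailed-balance check.

Known identifiability limits, accepted rather than fought: `ρ` vs `μ`
(ridge; summaries are framed on `r₀ = 3ρ − 12μ`), `σ_obs` vs `σ_camp`
(only their quadrature sum enters the marginal likelihood; the informative
`σ_obs` prior separates them), and the `α₂`/`X`-scale coupling described
above.

## Derived quantities

`rate_of_increase(draws, f)` computes, per posterior draw, the mean
yearly log change of the deterministic monthly skeleton with cyclones
expected `f` times per year. At `f = 0` this is exactly `r₀ = 3ρ − 12μ`
(a 12-month skeleton sum). For `f > 0` the per-event log decrement `D` is
obtained by running a single-event skeleton against an event-free one and
differencing, averaged over the 12 possible calendar placements, giving
`r = r₀ − f·D`; this equals the long-horizon skeleton at frequency `f`
without horizon end-effects (the equivalence is tested against an
explicit month-loop oracle). In closed form
`D = 6.5·μ·(c_μ−1) + 3ρ(1−c_ρ)`: the integrated 12-month mortality ramp
plus one suppressed breeding season. `prob_decline` is the fraction of
draws with `r < 0`. At the default point parameters and 3 events per
12.8 years the skeleton gives `r ≈ −0.13 /yr`.

`november_summary` reports posterior quantiles of both latent layers for
each November (the month conventionally used to index this population's
size); `percent_decline` compares two Novembers' medians.
`project` simulates each retained draw's process and availability layers
forward from its final state, with ramps of past events still decaying
and any supplied future events applied.

## Early-warning analysis (drift-diffusion-jump)

The analysis treats the log monthly total as a jump-diffusion sampled at
Δt = 1 month and asks *when* the increment distribution grows heavy
tails. Pipeline, all deterministic:

1. log-transform (adding half the minimum positive value if zeros occur —
   this keeps the whole analysis exactly invariant to rescaling the
   counts); log-linear interpolation of missing months (≤ 10% allowed);
   optional removal of the mean calendar-month cycle.
2. local drift by Nadaraya–Watson regression of the increments on time
   (Gaussian kernel, default SD 6 months); residuals standardised for the
   smoother's leverage so their second moment is unbiased under Gaussian
   noise.
3. residuals are **studentized by a jump-robust local scale** (kernel
   variance of residuals winsorized at 3 robust SDs). This matters twice:
   a jump otherwise inflates its own local variance and masks itself in
   the kurtosis, and smooth variance structure (e.g. residual
   seasonality) otherwise displaces the kurtosis peaks by several months.
4. conditional 2nd/4th/6th moments of the studentized residuals by the
   same kernel regression; *excess* moments `q₄ = c₄ − 3c₂²`,
   `q₆ = c₆ − 15c₂³` over their Gaussian values. At monthly spacing the
   raw continuous-time moment estimators would charge even pure Gaussian
   variation to jumps (the diffusion's O(Δt²) term is not small at
   Δt = 1); using excess moments makes the jump intensity vanish for
   Gaussian input while the strongly correlated sampling noise of `c₄`
   and `3c₂²` largely cancels.
5. the Gaussian-mixture moment relations `q₄ ≈ 3λs²`,
   `q₆/q₄ = 15a + 5s` yield a pointwise jump-size variance `s`, which is
   pooled into one series-wide scale weighted by `q₄` (a pointwise
   normalisation would rank quiet grid points above real jumps); the
   jump intensity is `λ(t) = q₄(t)/(3s²)` clipped to [0, 1], and the
   variance decomposition maps the jump share back to the raw residual
   variance: total = diffusion + jump contribution, all non-negative by
   construction (clamps counted in `n_clamped`).

Behaviour: constant series → all zeros; Gaussian random walks → mean λ
of a few percent and total variance within sampling error of σ²; three
injected single-month shocks of 5× the increment SD in a 154-month
study-like series → the three largest λ peaks land within ±2 months of
the injections. The 6-month default bandwidth balances localization
(events two years apart stay separate) against moment stability (~15
increments per window); it is a parameter, not a constant.

## Synthetic-data generator

`default_scenario()` encodes the study conditions: 154 monthly surveys
starting May 2004; 64 camps with Binomial occupancy averaging 10.5 per
month and symmetric-Dirichlet allocation of the monthly total among the
occupied camps; `x₀ = 326,000`; cyclones at month indices 22, 81, 105
(March 2006, February 2011, February 2013); truth parameters
σ_proc = 0.149, σ_obs = 0.096, μ = 0.017, c_μ = 5.7, c_R = 0.24,
c_ρ = 0.79, with α₁ ≈ 2.071, α₂ ≈ 3.571 solved from the 86%/30%
December/June availability and ρ = 4μ = 0.068 solved so the cyclone-free
yearly rate is zero. σ_camp has no published point value; 0.10 is used
as a realistic year-to-year roosting deviation. No months are missing by
default (no missingness rate is documented for the real programme);
scenarios state theirs explicitly.

Observation error applies to the monthly total, as in the model; the
per-camp table partitions the *observed* total (so written files
round-trip exactly to the series used for fitting) and is
presentation-layer realism, not a per-camp error model. Counts are
real-valued (the model is continuous); `round_counts=True` produces
integer tables.

What passing tests on these data do **not** show about real data: the
generator is the model, so recovery tests certify internal consistency
(correct likelihood, sampler and coverage under the stated conditions),
not robustness to the things real programmes add — camp-level detection
differences between counting methods, heat-wave mortality pulses,
drifting survey effort, non-log-normal observation errors. Process noise
at σ_proc = 0.149 also makes individual 154-month realisations vary
enormously (the log-scale random walk accumulates SD ≈ 1.8 over the
span), so realisation-level summaries (November declines, posterior mean
r) scatter widely around their generating mechanism; mechanism-level
quantities (the skeleton rate, per-event decrement) are the stable ones.

## Numerical choices and edge cases

* Kalman/FFBS kernels are scalar O(T) loops, JIT-compiled with numba
  when importable (pure-Python fallback, bit-identical results since all
  normal variates are pre-drawn outside the kernel).
* Reproducibility: every stochastic entry point takes a seed;
  per-chain/replicate streams derive from `numpy.random.SeedSequence`
  spawning. Re-running any pipeline command with the same seed and
  configuration reproduces its output files byte-for-byte.
* `σ = 0` is admitted in the simulator (noise-free skeletons for
  testing) but excluded from the prior support; the FFBS handles `q = 0`
  by degenerate (deterministic) transitions.
* Per-camp splits pin the column sum to the monthly total by assigning
  the float residual to the largest allocation.
* Month indices are 0-based ("months since series start") everywhere;
  calendar months 1–12 ride alongside via `TimeAxis` and drive the
  cosine phase and breeding window, so projections beyond the observed
  axis keep the correct phase.
* `gelman_rubin` requires ≥ 2 chains of ≥ 10 draws; degenerate
  zero-variance cases return 1 (identical) or ∞ (separated constants).

## Limitations

* The availability cosine is fixed-phase and single-harmonic; a
  population with a shifted or double-peaked aggregation season needs a
  different `p_t`.
* Cyclone effects share one ramp shape and one set of multipliers across
  events; severity differences between events are absorbed by process
  noise rather than estimated per event.
* The DDJ analysis localizes perturbations but provides no significance
  test for a peak; treat the intensity curve as exploratory.
* Absolute abundance rests on the initial-state prior's nominal
  availability (see above): credible intervals for totals are honest
  about this (they are wide), but a different nominal centre shifts the
  scale of `X` by a bounded factor.
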