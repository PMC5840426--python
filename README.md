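# roosttrend

Bayesian state-space trend estimation for roost-counted, highly mobile
animal populations — built for monitoring programmes like the monthly
flying-fox camp censuses of tropical Australia, where only a seasonally
varying fraction of the population is in known roosts ("camps") on any
survey, counts are noisy, and episodic disturbances (tropical cyclones)
punch holes in the series.

## The problem

Monthly totals from such a programme swing by a factor of ~3 within each
year, yet most of that swing is *availability*, not abundance: in December
roughly 86% of animals are in known camps, in June only ~30%. Raw-count
regressions confound this availability cycle, observation error and true
population change. `roosttrend` separates them with a hierarchical
state-space model and gives posterior answers to the questions managers
actually ask: *what is the total population, is it declining, and what are
the disturbances doing to it?*

## The model

With `t` in months, latent total population `X_t`, latent in-camp
population `X_t^C` and observed total count `Y_t`:

    X_t   ~ logN( log( X_{t-1} · exp(ρ_t − μ_t) ), σ²_proc )
    X_t^C ~ logN( log( p_t · X_t ),                σ²_camp )
    Y_t   ~ logN( log( X_t^C ),                    σ²_obs  )

    p_t = (cos(2πt/12) + α₁) / α₂ · (1 − c_R · I_C(t))

where `logN(m, v)` has log-scale location `m` and variance `v`, recruitment
`ρ_t = ρ` in the December–February breeding window (0 otherwise), `μ_t` is
background mortality `μ`, and the seasonal availability `p_t` peaks in
December at `(α₁+1)/α₂` and bottoms in June at `(α₁−1)/α₂`. A cyclone acts
through the disturbance profile `I_C(t)` — a step to 1 at impact decaying
linearly to 0 over 12 months — multiplying mortality up to `c_μ·μ` at
impact, removing a fraction `c_R` of animals from camps, and scaling the
first subsequent breeding season by `c_ρ`.

Everything is estimated jointly by MCMC (uniform/Beta priors on bounded
supports). Conditional on the parameters the model is linear-Gaussian in
the log states, which the sampler exploits: parameters move by adaptive
random-walk Metropolis against the exact Kalman-filter marginal likelihood,
and latent trajectories are drawn exactly by forward-filtering
backward-sampling. Convergence is checked with the Gelman–Rubin potential
scale reduction factor.

Derived quantities include the average yearly exponential rate of increase
`r` (per posterior draw, from the deterministic monthly skeleton; without
cyclones `r₀ = 3ρ − 12μ` exactly), the posterior probability of decline
`P(r < 0)`, November abundance summaries and forward projections. A
nonparametric drift-diffusion-jump analysis (`roosttrend.ddj`) decomposes
the series' increment variance over time into diffusion and jump
components; peaks of the jump intensity localize episodic perturbations.

Because no public dataset accompanies this class of monitoring programme,
the package ships a first-class generative simulator
(`roosttrend.simulate`) whose default scenario mirrors the study
conditions: 154 monthly surveys from May 2004 across 64 camps (~10.5
occupied per month), σ_proc = 0.149, σ_obs = 0.096, μ = 0.017 /month,
c_μ = 5.7, c_R = 0.24, c_ρ = 0.79, and cyclones in March 2006, February
2011 and February 2013.

## Worked example

```python
import numpy as np
import roosttrend as rt

ds = rt.simulate(rt.default_scenario(seed=3))          # study-like data
cfg = rt.McmcConfig(n_chains=3, n_iter=2000, n_burnin=1000, seed=4)
draws = rt.fit(ds.counts, ds.schedule, cfg)

rates = rt.rate_of_increase(draws, cyclone_frequency=3 / (154 / 12))
print(f"r with cyclones: {rates.r_with_cyclone.mean():+.3f} /yr, "
      f"P(r<0) = {100 * rates.p_decline:.0f}%")
```

prints

```
r with cyclones: -0.082 /yr, P(r<0) = 76%
```

i.e. under the fitted posterior, with cyclones recurring at the observed
frequency of 3 per 12.8 years, the population loses about 8% per year in
expectation and the model-based belief that it is declining at all is 76%
(this realisation's cyclone-free rate is near zero — the decline is the
cyclones' doing). The same fit recovers the generating parameters within
their 95% intervals — e.g. `sigma_proc`: truth 0.149, posterior
`0.127 [0.088, 0.178]` — with Gelman–Rubin R̂ ≤ 1.01 throughout; see
`examples/02_fit_and_recover.py`.

The `examples/` directory holds one short narrative script per capability:
simulation, fitting/recovery, trend and decline, early-warning
localization, and projection. A thin CLI mirrors the pipeline stages:

```sh
roosttrend simulate --seed 1 --out sim/
roosttrend fit --data sim/counts.csv --cyclones sim/cyclones.csv \
               --chains 3 --iter 5000 --burnin 2000 --seed 2 --out fit/
roosttrend summarize --draws fit/ --out summary/
roosttrend ddj --data sim/counts.csv --out ddj/
roosttrend project --draws fit/ --horizon 24 --seed 3 --out proj/
```

## Layout

| module | contents |
|---|---|
| `roosttrend.model_core` | model functions, priors, joint log density |
| `roosttrend.synthetic_data` | scenario definitions and the generative simulator |
| `roosttrend.inference` | Kalman/FFBS Metropolis-within-Gibbs sampler, R̂ |
| `roosttrend.derived` | rates of increase, P(r<0), November summaries, projections |
| `roosttrend.early_warning` | drift-diffusion-jump decomposition |
| `roosttrend.io` / `roosttrend.cli` | file formats, run pipeline, CLI |

See `docs/methods.md` for the full model description, estimator choices and
known limitations.
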