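"""Bayesian estimation by MCMC with convergence diagnostics.

Parameters are updated by adaptive random-walk Metropolis against the exact
*marginal* likelihood of the counts (latent states integrated out by the
Kalman filter; the model is linear-Gaussian in the log states conditional on
the parameters).  Latent trajectories are drawn exactly from their full
conditional by forward-filter backward-sampling, so the sampler is a
Metropolis-within-Gibbs scheme targeting the same joint posterior as the
hierarchical log-joint density.  Proposals are componentwise on the natural
scale (all priors have bounded support; out-of-support proposals are simply
rejected), plus one correlated "ridge" move along the recruitment-mortality
direction (3*rho - 12*mu constant), which the trend makes tightly identified
while rho and mu individually are not.  Proposal scales adapt during burn-in
only and are frozen afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._filters import ffbs, kalman_loglik
from .model_core import (DEFAULT_PRIOR, CycloneSchedule, Params, PriorSet,
                         cyclone_ramp, log_joint, model_arrays,
                         recruitment_suppression_mask, seasonal_proportion)
from .series import CountSeries, LatentTrajectory, TimeAxis

__all__ = ["McmcConfig", "PosteriorDraws", "fit", "gelman_rubin",
           "initialize", "sample_prior"]

PARAM_NAMES = Params._FIELDS
_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    ``n_iter`` retained iterations per chain after ``n_burnin`` adaptation
    steps; parameter draws are stored unthinned, latent-state draws every
    ``thin_states`` iterations.  ``fixed`` pins named parameters at given
    values (they are never updated), for controlled recovery experiments.
    """

    n_chains: int = 3
    n_iter: int = 50_000
    n_burnin: int = 10_000
    thin_states: int = 10
    seed: int = 0
    fixed: dict = field(default_factory=dict)
    store_states: bool = True

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.n_burnin < 0:
            raise ValueError("n_iter must be positive, n_burnin non-negative")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        for k in self.fixed:
            if k not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {k!r} in fixed")


@dataclass
class PosteriorDraws:
    """Per-chain posterior samples, acceptance rates and diagnostics."""

    params: np.ndarray                 # (n_chains, n_iter, n_params)
    param_names: tuple[str, ...]
    acceptance: np.ndarray             # (n_chains, n_moves)
    move_names: tuple[str, ...]
    states_total: np.ndarray | None = None   # (n_chains, n_kept, T)
    states_camp: np.ndarray | None = None
    state_iters: np.ndarray | None = None    # iteration index of each state draw
    data: CountSeries | None = None
    schedule: CycloneSchedule | None = None
    config: McmcConfig | None = None

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    def flat(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        return self.params[:, :, self.param_names.index(name)].ravel()

    def param_draws(self) -> pd.DataFrame:
        """Draws as a tidy DataFrame (chain, iteration, one column/parameter)."""
        n_c, n_i, _ = self.params.shape
        df = pd.DataFrame(self.params.reshape(n_c * n_i, -1),
                          columns=list(self.param_names))
        df.insert(0, "iteration", np.tile(np.arange(n_i), n_c))
        df.insert(0, "chain", np.repeat(np.arange(n_c), n_i))
        return df

    def rhat(self) -> dict[str, float]:
        """Gelman-Rubin potential scale reduction factor per parameter."""
        out = {}
        for j, name in enumerate(self.param_names):
            if self.config and name in self.config.fixed:
                out[name] = 1.0
                continue
            out[name] = gelman_rubin(self.params[:, :, j])
        return out

    def summary(self, probs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        rows = []
        rh = self.rhat()
        for name in self.param_names:
            d = self.flat(name)
            qs = np.quantile(d, probs)
            rows.append({"parameter": name, "mean": d.mean(),
                         **{f"q{p}": q for p, q in zip(probs, qs)},
                         "rhat": rh[name]})
        return pd.DataFrame(rows)


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar quantity.

    ``chains`` has shape (n_chains, n_draws).  Computes
    ``sqrt(((n-1)/n * W + B/n) / W)`` with ``W`` the mean within-chain
    variance and ``B/n`` the variance of the chain means.  Values below 1
    (possible from finite-sample noise when the chains agree) carry no
    nonconvergence signal and are reported as exactly 1.0, so identical
    chains give 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    m, n = chains.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = chains.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else math.inf
    var_plus = (n - 1) / n * w + b_over_n
    return float(math.sqrt(max(var_plus / w, 1.0)))


# ---------------------------------------------------------------------------
# Marginal likelihood machinery
# ---------------------------------------------------------------------------

class _MarginalLikelihood:
    """Precomputed per-dataset arrays + fast marginal log-likelihood.

    Caches the drift array (depends on rho, mu, c_rho, c_mu) and the log
    availability array (depends on alpha1, alpha2, c_r) between componentwise
    updates so only the affected block is rebuilt per proposal.
    """

    # parameter index -> which cached array a change invalidates
    _D_SET = frozenset((0, 1, 2, 3))       # rho, mu, c_rho, c_mu
    _P_SET = frozenset((4, 5, 6))          # c_r, alpha1, alpha2

    def __init__(self, data: CountSeries, schedule: CycloneSchedule):
        axis = data.axis
        t = np.arange(axis.n_months)
        self.cos_term = np.cos(2.0 * np.pi * axis.cal / 12.0)
        self.breed = np.isin(axis.cal, (12, 1, 2)).astype(float)
        sup = recruitment_suppression_mask(t, schedule, axis)
        self.sup_breed = (sup & (self.breed > 0)).astype(float)
        self.ramp = np.asarray(cyclone_ramp(t, schedule), dtype=float)
        self.obs = data.observed.astype(np.uint8)
        ly = np.zeros(axis.n_months)
        ly[data.observed] = np.log(data.y[data.observed])
        self.ly = ly
        self.t_first = int(np.flatnonzero(data.observed)[0])
        from .model_core import initial_state_prior
        self.m0, self.v0 = initial_state_prior(data)

    def drift(self, th: np.ndarray) -> np.ndarray:
        rho, mu, c_rho, c_mu = th[0], th[1], th[2], th[3]
        rho_t = rho * (self.breed - (1.0 - c_rho) * self.sup_breed)
        mu_t = mu * (1.0 + (c_mu - 1.0) * self.ramp)
        return rho_t - mu_t

    def log_avail(self, th: np.ndarray) -> np.ndarray:
        c_r, a1, a2 = th[4], th[5], th[6]
        return (np.log(self.cos_term + a1) - np.log(a2)
                + np.log1p(-c_r * self.ramp))

    def loglik(self, th: np.ndarray, d: np.ndarray, logp: np.ndarray) -> float:
        q = th[7] * th[7]
        r = th[8] * th[8] + th[9] * th[9]
        return float(kalman_loglik(self.ly, self.obs, d, logp, q, r,
                                   self.m0, self.v0))

    def sample_states(self, th: np.ndarray, d: np.ndarray, logp: np.ndarray,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Exact joint draw of (log X, log X^C) given parameters and data."""
        T = len(self.ly)
        q = th[7] * th[7]
        r = th[8] * th[8] + th[9] * th[9]
        lx = ffbs(self.ly, self.obs, d, logp, q, r, self.m0, self.v0,
                  rng.standard_normal(T))
        # in-camp layer: conjugate normal given lx and y
        s_c2, s_o2 = th[8] * th[8], th[9] * th[9]
        prior_mean = lx + logp
        post_var = np.full(T, s_c2)
        post_mean = prior_mean.copy()
        ob = self.obs.astype(bool)
        if s_c2 > 0:
            v = s_c2 * s_o2 / (s_c2 + s_o2)
            post_var[ob] = v
            post_mean[ob] = v * (prior_mean[ob] / s_c2 + self.ly[ob] / s_o2)
        lc = post_mean + np.sqrt(post_var) * rng.standard_normal(T)
        return lx, lc


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------

def _run_chain(ml: _MarginalLikelihood | None, prior: PriorSet,
               theta0: np.ndarray, config: McmcConfig,
               rng: np.random.Generator):
    """One chain of the adaptive componentwise RW Metropolis sampler.

    ``ml`` None means prior-only sampling (flat likelihood).  Returns
    (draws, states_total, states_camp, state_iters, acceptance, move_names).
    """
    n_par = len(PARAM_NAMES)
    fixed_idx = {PARAM_NAMES.index(k) for k in config.fixed}
    free = [j for j in range(n_par) if j not in fixed_idx]
    ridge = 0 not in fixed_idx and 1 not in fixed_idx  # rho & mu both free

    # initial proposal scales: a few percent of each prior range
    spans = np.array([prior.rho_max, prior.mu_max, 1.0,
                      prior.c_mu_max - 1.0, 1.0, prior.alpha_max - 2.0,
                      prior.alpha_max - 2.0, prior.sigma_proc_max,
                      prior.sigma_camp_max,
                      prior.sigma_obs_bounds[1] - prior.sigma_obs_bounds[0]])
    scales = 0.05 * spans
    ridge_scale = 0.05 * prior.rho_max

    theta = theta0.copy()
    lp = prior.log_prior(Params.from_array(theta))
    if ml is not None:
        d = ml.drift(theta)
        logp = ml.log_avail(theta)
        ll = ml.loglik(theta, d, logp)
    else:
        d = logp = None
        ll = 0.0
    if not np.isfinite(lp + ll):
        raise RuntimeError("non-finite log density at initialization")

    total_iter = config.n_burnin + config.n_iter
    draws = np.empty((config.n_iter, n_par))
    moves = [PARAM_NAMES[j] for j in free] + (["ridge"] if ridge else [])
    n_moves = len(moves)
    acc = np.zeros(n_moves)
    n_prop = np.zeros(n_moves)

    keep_states = config.store_states and ml is not None
    if keep_states:
        n_kept = (config.n_iter + config.thin_states - 1) // config.thin_states
        T = len(ml.ly)
        st_x = np.empty((n_kept, T))
        st_c = np.empty((n_kept, T))
        st_iters = np.empty(n_kept, dtype=int)
    else:
        st_x = st_c = st_iters = None
    kept = 0

    def attempt(move_i, prop, changed):
        """Metropolis accept/reject; returns updated state tuple."""
        nonlocal theta, lp, ll, d, logp
        lp_new = prior.log_prior(Params.from_array(prop))
        if np.isfinite(lp_new):
            if ml is not None:
                d_new = ml.drift(prop) if changed & ml._D_SET else d
                logp_new = (ml.log_avail(prop) if changed & ml._P_SET
                            else logp)
                ll_new = ml.loglik(prop, d_new, logp_new)
            else:
                d_new = logp_new = None
                ll_new = 0.0
            log_alpha = (lp_new + ll_new) - (lp + ll)
            if log_alpha >= 0 or math.log(rng.uniform()) < log_alpha:
                theta, lp, ll, d, logp = prop, lp_new, ll_new, d_new, logp_new
                return True
        return False

    for it in range(total_iter):
        adapting = it < config.n_burnin
        gamma = (it + 1) ** -0.6 if adapting else 0.0
        for mi, j in enumerate(free):
            prop = theta.copy()
            prop[j] += scales[j] * rng.standard_normal()
            ok = attempt(mi, prop, {j})
            if adapting:
                scales[j] *= math.exp(gamma * ((1.0 if ok else 0.0)
                                               - _TARGET_ACCEPT))
            else:
                n_prop[mi] += 1
                acc[mi] += ok
        if ridge:
            # move along 3*rho - 12*mu = const (d_mu = d_rho / 4)
            step = ridge_scale * rng.standard_normal()
            prop = theta.copy()
            prop[0] += step
            prop[1] += step / 4.0
            ok = attempt(n_moves - 1, prop, {0, 1})
            if adapting:
                ridge_scale *= math.exp(gamma * ((1.0 if ok else 0.0)
                                                 - _TARGET_ACCEPT))
            else:
                n_prop[-1] += 1
                acc[-1] += ok
        if it >= config.n_burnin:
            k = it - config.n_burnin
            draws[k] = theta
            if keep_states and k % config.thin_states == 0:
                lx, lc = ml.sample_states(theta, d, logp, rng)
                st_x[kept] = np.exp(lx)
                st_c[kept] = np.exp(lc)
                st_iters[kept] = k
                kept += 1

    with np.errstate(invalid="ignore"):
        rates = np.where(n_prop > 0, acc / np.maximum(n_prop, 1), np.nan)
    if keep_states:
        st_x, st_c, st_iters = st_x[:kept], st_c[:kept], st_iters[:kept]
    return draws, st_x, st_c, st_iters, rates, tuple(moves)


def initialize(data: CountSeries, schedule: CycloneSchedule,
               rng: np.random.Generator, prior: PriorSet = DEFAULT_PRIOR,
               max_tries: int = 100) -> tuple[Params, LatentTrajectory]:
    """Overdispersed starting point: parameters drawn from the prior, latent
    states at ``Y_t / p_t`` with log-linear interpolation over missing months.

    Retries prior draws until the joint density is finite; raises after
    ``max_tries`` failures.
    """
    if data.n_observed == 0:
        raise ValueError("all months are missing; nothing to fit")
    t = np.arange(data.n_months)
    obs_idx = np.flatnonzero(data.observed)
    for _ in range(max_tries):
        params = prior.sample(rng)
        p_t = seasonal_proportion(t, params, schedule, data.axis)
        lx_obs = np.log(data.y[obs_idx] / p_t[obs_idx])
        lx = np.interp(t, obs_idx, lx_obs)
        lc = lx + np.log(p_t)
        lc[obs_idx] = np.log(data.y[obs_idx])
        states = LatentTrajectory(total=np.exp(lx), in_camp=np.exp(lc))
        if np.isfinite(log_joint(states, params, data, schedule, prior)):
            return params, states
    raise RuntimeError("could not find a finite starting point")


def fit(data: CountSeries, schedule: CycloneSchedule,
        config: McmcConfig = McmcConfig(),
        prior: PriorSet = DEFAULT_PRIOR) -> PosteriorDraws:
    """Sample the joint posterior of parameters and latent states.

    Chains are initialized independently from the prior (overdispersed) and
    run sequentially; results are reproducible given ``config.seed``.
    """
    if data.n_observed == 0:
        raise ValueError("all months are missing; nothing to fit")
    if data.n_months < 24:
        raise ValueError("need at least 24 months of data")
    ml = _MarginalLikelihood(data, schedule)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    all_draws, all_sx, all_sc, all_acc = [], [], [], []
    st_iters = move_names = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        params0, _ = initialize(data, schedule, rng, prior)
        theta0 = params0.to_array()
        for name, val in config.fixed.items():
            theta0[PARAM_NAMES.index(name)] = val
        draws, sx, sc, st_iters, rates, move_names = _run_chain(
            ml, prior, theta0, config, rng)
        all_draws.append(draws)
        all_sx.append(sx)
        all_sc.append(sc)
        all_acc.append(rates)

    return PosteriorDraws(
        params=np.stack(all_draws),
        param_names=PARAM_NAMES,
        acceptance=np.stack(all_acc),
        move_names=move_names,
        states_total=np.stack(all_sx) if config.store_states else None,
        states_camp=np.stack(all_sc) if config.store_states else None,
        state_iters=st_iters,
        data=data,
        schedule=schedule,
        config=config,
    )


def sample_prior(config: McmcConfig, prior: PriorSet = DEFAULT_PRIOR) -> PosteriorDraws:
    """Run the identical kernel with the likelihood term removed.

    The stationary distribution is then the prior itself; used to validate
    detailed balance (the draws must reproduce the prior marginals).
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws, all_acc = [], []
    move_names = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        theta0 = prior.sample(rng).to_array()
        for name, val in config.fixed.items():
            theta0[PARAM_NAMES.index(name)] = val
        draws, _, _, _, rates, move_names = _run_chain(
            None, prior, theta0, config, rng)
        all_draws.append(draws)
        all_acc.append(rates)
    return PosteriorDraws(params=np.stack(all_draws), param_names=PARAM_NAMES,
                          acceptance=np.stack(all_acc), move_names=move_names,
                          config=config)
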