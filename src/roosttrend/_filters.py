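"""Scalar Kalman filter and forward-filter backward-sampler (FFBS).

Conditional on the parameters, the model is linear-Gaussian in the log
states: ``lx_t = lx_{t-1} + d_t + N(0, q)`` with drift ``d_t = rho_t - mu_t``
and, at observed months, ``log Y_t = lx_t + log p_t + N(0, r)`` where
``r = sigma_camp^2 + sigma_obs^2`` (the in-camp layer marginalised).  The
filter therefore yields the exact marginal likelihood of the counts with the
latent states integrated out, and FFBS draws exact joint samples of the
latent log totals.

Functions are written in scalar-loop style so that numba can JIT them when
available; without numba they run as plain Python (identical results).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

_LOG2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def kalman_loglik(ly, obs, d, logp, q, r, m0, v0):
    """Marginal log-likelihood of observed log counts.

    Parameters
    ----------
    ly : float64[T]
        Log observed totals (value ignored where ``obs`` is 0).
    obs : uint8[T]
        Observation indicator.
    d : float64[T]
        Drift of the transition *into* month t (``d[0]`` unused).
    logp : float64[T]
        Log in-camp proportion per month.
    q, r : float
        Process variance and marginal observation-side variance.
    m0, v0 : float
        Initial-state prior mean and variance (log scale).
    """
    T = ly.shape[0]
    m = m0
    v = v0
    ll = 0.0
    for t in range(T):
        if t > 0:
            m = m + d[t]
            v = v + q
        if obs[t] == 1:
            f = v + r
            e = ly[t] - (m + logp[t])
            ll += -0.5 * (_LOG2PI + math.log(f) + e * e / f)
            k = v / f
            m = m + k * e
            v = v * (1.0 - k)
    return ll


@njit(cache=True)
def ffbs(ly, obs, d, logp, q, r, m0, v0, z):
    """Draw one joint sample of the latent log totals by FFBS.

    ``z`` is a length-T array of standard-normal variates (supplied by the
    caller so that reproducibility does not depend on the JIT backend).
    Returns the sampled ``lx`` array.
    """
    T = ly.shape[0]
    fm = np.empty(T)
    fv = np.empty(T)
    m = m0
    v = v0
    for t in range(T):
        if t > 0:
            m = m + d[t]
            v = v + q
        if obs[t] == 1:
            f = v + r
            e = ly[t] - (m + logp[t])
            k = v / f
            m = m + k * e
            v = v * (1.0 - k)
        fm[t] = m
        fv[t] = v
    lx = np.empty(T)
    lx[T - 1] = fm[T - 1] + math.sqrt(fv[T - 1]) * z[T - 1]
    for t in range(T - 2, -1, -1):
        if q > 0.0:
            prec = 1.0 / fv[t] + 1.0 / q
            mean = (fm[t] / fv[t] + (lx[t + 1] - d[t + 1]) / q) / prec
            var = 1.0 / prec
        else:
            mean = lx[t + 1] - d[t + 1]
            var = 0.0
        lx[t] = mean + math.sqrt(var) * z[t]
    return lx
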