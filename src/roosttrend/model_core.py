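"""Deterministic model functions, priors and log-densities.

The population model is a discrete-time state-space model on a monthly axis:

* latent total population
  ``X_t ~ logN(log(X_{t-1} exp(rho_t - mu_t)), sigma_proc^2)``,
  where recruitment ``rho_t`` equals ``rho`` in the December-February breeding
  window (0 otherwise) and mortality ``mu_t`` is ``mu`` inflated by cyclones;
* latent in-camp population
  ``X_t^C ~ logN(log(p_t X_t), sigma_camp^2)`` with seasonal availability
  ``p_t = (cos(2 pi t / 12) + alpha1) / alpha2 * (1 - c_r * I_C(t))``,
  the cosine phased so ``p_t`` peaks in December and troughs in June;
* observed total count ``Y_t ~ logN(log(X_t^C), sigma_obs^2)``.

``logN(m, v)`` denotes the log-normal with *log-scale* location ``m`` and
log-scale variance ``v`` (the location is already a log in the equations
above).  Cyclones act through an indicator/ramp ``I_C``: full effect at the
event month, decaying linearly to zero over ``ramp_length`` months (a pure
12-month year-indicator variant is available as a switch), multiplying
mortality excess (``c_mu``), suppressing the first subsequent breeding season
(``c_rho``) and reducing in-camp availability (``c_r``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .series import CountSeries, LatentTrajectory, TimeAxis

__all__ = [
    "Params",
    "CycloneSchedule",
    "PriorSet",
    "DEFAULT_PRIOR",
    "BREEDING_MONTHS",
    "cyclone_ramp",
    "seasonal_proportion",
    "recruitment_rate",
    "mortality_rate",
    "recruitment_suppression_mask",
    "model_arrays",
    "log_prior",
    "log_joint",
    "initial_state_prior",
]

#: Calendar months of the recruitment (breeding) window: December-February.
BREEDING_MONTHS = (12, 1, 2)


@dataclass(frozen=True)
class Params:
    """Full parameter set of the state-space model.

    Rates are monthly; all SDs are on the natural-log scale.  ``c_mu >= 1``
    multiplies mortality at cyclone impact, ``c_rho`` in (0,1) multiplies
    recruitment in the first post-cyclone breeding season, and ``c_r`` in
    (0,1) is the extra fraction of animals absent from camps after a cyclone.
    ``alpha1 > 1`` and ``alpha2 > alpha1 + 1`` shape the seasonal in-camp
    proportion, guaranteeing ``0 < p_t < 1`` in cyclone-free months.
    """

    rho: float
    mu: float
    c_rho: float
    c_mu: float
    c_r: float
    alpha1: float
    alpha2: float
    sigma_proc: float
    sigma_camp: float
    sigma_obs: float

    def validate(self) -> None:
        if not self.alpha1 > 1:
            raise ValueError("alpha1 must exceed 1")
        if not self.alpha2 > self.alpha1 + 1:
            raise ValueError("alpha2 must exceed alpha1 + 1")
        if self.rho < 0 or self.mu < 0:
            raise ValueError("rates must be non-negative")
        if not (0 < self.c_rho < 1) and self.c_rho != 1.0:
            raise ValueError("c_rho must lie in (0, 1]")
        if self.c_mu < 1:
            raise ValueError("c_mu must be >= 1")
        if not (0 <= self.c_r < 1):
            raise ValueError("c_r must lie in [0, 1)")
        # sigma == 0 is admitted for noise-free simulation skeletons; the
        # prior support (inference) requires strictly positive SDs.
        if min(self.sigma_proc, self.sigma_camp, self.sigma_obs) < 0:
            raise ValueError("SDs must be non-negative")

    def replace(self, **kw) -> "Params":
        return replace(self, **kw)

    _FIELDS = ("rho", "mu", "c_rho", "c_mu", "c_r", "alpha1", "alpha2",
               "sigma_proc", "sigma_camp", "sigma_obs")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Params":
        return cls(**dict(zip(cls._FIELDS, map(float, a))))


@dataclass(frozen=True)
class CycloneSchedule:
    """Cyclone event months (0-based indices on the series' axis) and the
    disturbance profile.

    ``indicator="ramp"`` (default): full effect at the event month, linearly
    decaying to zero ``ramp_length`` months later.  ``indicator="year"``: the
    effect is 1 for the ``ramp_length`` months starting at the event, else 0.
    Overlapping events combine by the pointwise maximum.
    """

    events: tuple[int, ...] = ()
    ramp_length: int = 12
    indicator: str = "ramp"

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(int(e) for e in self.events))
        if any(b <= a for a, b in zip(self.events, self.events[1:])):
            raise ValueError("event months must be strictly increasing")
        if self.ramp_length < 1:
            raise ValueError("ramp_length must be >= 1")
        if self.indicator not in ("ramp", "year"):
            raise ValueError("indicator must be 'ramp' or 'year'")

    @property
    def empty(self) -> bool:
        return len(self.events) == 0

    def without_events(self) -> "CycloneSchedule":
        return CycloneSchedule((), self.ramp_length, self.indicator)

    def shifted(self, offset: int) -> "CycloneSchedule":
        return CycloneSchedule(tuple(e + offset for e in self.events),
                               self.ramp_length, self.indicator)


def cyclone_ramp(t, schedule: CycloneSchedule):
    """Disturbance fraction ``I_C(t)`` in [0, 1] at month index ``t``.

    1 at an event month; under the default linear ramp it reaches 0 exactly
    ``ramp_length`` months after the event.  Months before any event (and any
    out-of-range ``t``) return 0; overlapping events take the maximum.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape)
    for e in schedule.events:
        dt = t - e
        if schedule.indicator == "ramp":
            r = np.where((dt >= 0) & (dt < schedule.ramp_length),
                         1.0 - dt / schedule.ramp_length, 0.0)
        else:
            r = np.where((dt >= 0) & (dt < schedule.ramp_length), 1.0, 0.0)
        out = np.maximum(out, r)
    return out if out.ndim else float(out)


def seasonal_proportion(t, params: Params, schedule: CycloneSchedule,
                        axis: TimeAxis):
    """In-camp proportion ``p_t`` in (0, 1).

    ``p_t = (cos(2 pi c_t / 12) + alpha1)/alpha2 * (1 - c_r I_C(t))`` with
    ``c_t`` the calendar month, so the cosine is +1 in December (maximum
    availability, ``(alpha1+1)/alpha2``) and -1 in June
    (``(alpha1-1)/alpha2``).
    """
    params.validate()
    cal = axis.calendar_month(t)
    base = (np.cos(2.0 * np.pi * cal / 12.0) + params.alpha1) / params.alpha2
    p = base * (1.0 - params.c_r * cyclone_ramp(t, schedule))
    return p if np.ndim(p) else float(p)


def recruitment_suppression_mask(t, schedule: CycloneSchedule,
                                 axis: TimeAxis) -> np.ndarray:
    """True where the post-cyclone recruitment multiplier ``c_rho`` applies.

    Each event suppresses all three months of the first breeding season that
    *starts* (December) at or after the event month.
    """
    t = np.asarray(t)
    mask = np.zeros(t.shape, dtype=bool)
    for e in schedule.events:
        cal_e = int(axis.calendar_month(e))
        season_start = e + (12 - cal_e) % 12  # next December (or e itself)
        mask |= (t >= season_start) & (t < season_start + 3)
    return mask


def recruitment_rate(t, params: Params, schedule: CycloneSchedule,
                     axis: TimeAxis):
    """Monthly recruitment ``rho_t``: ``rho`` in December-February, else 0;
    multiplied by ``c_rho`` through the first breeding season after each
    cyclone."""
    t = np.asarray(t)
    cal = axis.calendar_month(t)
    in_season = np.isin(cal, BREEDING_MONTHS)
    rate = np.where(in_season, params.rho, 0.0)
    sup = recruitment_suppression_mask(t, schedule, axis)
    rate = np.where(sup & in_season, rate * params.c_rho, rate)
    return rate if rate.ndim else float(rate)


def mortality_rate(t, params: Params, schedule: CycloneSchedule):
    """Monthly mortality ``mu_t = mu * (1 + (c_mu - 1) * I_C(t))``.

    The ramp applies to the multiplicative *excess* ``c_mu - 1``, so the rate
    is ``mu * c_mu`` at impact and returns exactly to ``mu`` once the ramp
    has decayed.
    """
    m = params.mu * (1.0 + (params.c_mu - 1.0) * cyclone_ramp(t, schedule))
    return m if np.ndim(m) else float(m)


def model_arrays(params: Params, schedule: CycloneSchedule, axis: TimeAxis,
                 t0: int = 0, n: int | None = None):
    """(rho_t, mu_t, p_t) arrays over ``t0 .. t0+n-1`` (default: whole axis)."""
    if n is None:
        n = axis.n_months - t0
    t = np.arange(t0, t0 + n)
    return (recruitment_rate(t, params, schedule, axis),
            mortality_rate(t, params, schedule),
            seasonal_proportion(t, params, schedule, axis))


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSet:
    """Prior distributions for all parameters.

    Uniform boxes for the rates and SDs, near-flat Beta(1.01, 1.01) for the
    (0,1) cyclone effects (down-weighting the endpoints), and a hierarchical
    uniform pair for the seasonality parameters: ``alpha1 ~ U(1, alpha_max-1)``
    and ``alpha2 | alpha1 ~ U(alpha1+1, alpha_max)``.  The nominally unbounded
    alpha supports are truncated at ``alpha_max`` (default 50, far beyond any
    value compatible with an in-camp proportion in (0,1)).
    """

    rho_max: float = 0.11       # max ~40% increase over a 3-month season
    mu_max: float = 0.1         # max ~70% reduction over 12 months
    c_mu_max: float = 10.0      # 10-fold initial mortality increase at most
    sigma_obs_bounds: tuple[float, float] = (0.05, 0.47)  # counting CV 5-50%
    sigma_proc_max: float = 10.0
    sigma_camp_max: float = 100.0
    alpha_max: float = 50.0
    beta_shape: float = 1.01    # Beta(1.01, 1.01) for c_rho and c_r

    def log_prior(self, params: Params) -> float:
        p = params
        lo_obs, hi_obs = self.sigma_obs_bounds
        if not (0.0 < p.rho < self.rho_max):
            return -math.inf
        if not (0.0 < p.mu < self.mu_max):
            return -math.inf
        if not (1.0 < p.c_mu < self.c_mu_max):
            return -math.inf
        if not (0.0 < p.c_rho < 1.0) or not (0.0 < p.c_r < 1.0):
            return -math.inf
        if not (1.0 < p.alpha1 < self.alpha_max - 1.0):
            return -math.inf
        if not (p.alpha1 + 1.0 < p.alpha2 < self.alpha_max):
            return -math.inf
        if not (0.0 < p.sigma_proc < self.sigma_proc_max):
            return -math.inf
        if not (0.0 < p.sigma_camp < self.sigma_camp_max):
            return -math.inf
        if not (lo_obs < p.sigma_obs < hi_obs):
            return -math.inf
        lp = -(math.log(self.rho_max) + math.log(self.mu_max)
               + math.log(self.c_mu_max - 1.0)
               + math.log(hi_obs - lo_obs)
               + math.log(self.sigma_proc_max) + math.log(self.sigma_camp_max)
               + math.log(self.alpha_max - 2.0)
               + math.log(self.alpha_max - p.alpha1 - 1.0))
        a = self.beta_shape
        lbeta = 2.0 * math.lgamma(a) - math.lgamma(2.0 * a)
        for v in (p.c_rho, p.c_r):
            lp += (a - 1.0) * (math.log(v) + math.log1p(-v)) - lbeta
        return float(lp)

    def sample(self, rng: np.random.Generator) -> Params:
        """One independent draw from the prior."""
        a1 = rng.uniform(1.0, self.alpha_max - 1.0)
        a2 = rng.uniform(a1 + 1.0, self.alpha_max)
        b = self.beta_shape
        return Params(
            rho=rng.uniform(0.0, self.rho_max),
            mu=rng.uniform(0.0, self.mu_max),
            c_rho=float(rng.beta(b, b)),
            c_mu=rng.uniform(1.0, self.c_mu_max),
            c_r=float(rng.beta(b, b)),
            alpha1=a1,
            alpha2=a2,
            sigma_proc=rng.uniform(0.0, self.sigma_proc_max),
            sigma_camp=rng.uniform(0.0, self.sigma_camp_max),
            sigma_obs=rng.uniform(*self.sigma_obs_bounds),
        )


DEFAULT_PRIOR = PriorSet()


def log_prior(params: Params, prior: PriorSet = DEFAULT_PRIOR) -> float:
    """Log prior density; ``-inf`` outside the support."""
    return prior.log_prior(params)


# ---------------------------------------------------------------------------
# Joint density
# ---------------------------------------------------------------------------

#: Nominal availability used to centre the initial-state prior.  Centring on
#: the *parameter-dependent* p_t would cancel the availability level out of
#: the likelihood and leave alpha2 unidentified, so a fixed round value is
#: used; the SD-1 log-scale prior spans a factor of ~7 either way, which
#: dominates any plausible error in this choice.
NOMINAL_AVAILABILITY = 0.5


def initial_state_prior(data: CountSeries) -> tuple[float, float]:
    """(log-scale mean, log-scale SD) of the weakly informative prior on the
    initial total population: centred on the first observed count divided by
    a nominal availability of 0.5, with SD 1."""
    obs_idx = np.flatnonzero(data.observed)
    if len(obs_idx) == 0:
        raise ValueError("series has no observed months")
    t0 = int(obs_idx[0])
    return math.log(data.y[t0] / NOMINAL_AVAILABILITY), 1.0


def _lognorm_logpdf(x, logm, sd):
    """Log-normal log-density with log-scale location ``logm`` and SD ``sd``."""
    lx = np.log(x)
    return stats.norm.logpdf(lx, loc=logm, scale=sd) - lx


def log_joint(states: LatentTrajectory, params: Params, data: CountSeries,
              schedule: CycloneSchedule, prior: PriorSet = DEFAULT_PRIOR) -> float:
    """Log of prior x process x in-camp x observation densities.

    Months with missing ``Y_t`` contribute process and in-camp terms only.
    Returns ``-inf`` for out-of-support parameters or non-positive states;
    raises on shape mismatch.
    """
    if len(states) != data.n_months:
        raise ValueError("trajectory length does not match data")
    lp = prior.log_prior(params)
    if not np.isfinite(lp):
        return -math.inf
    if np.any(states.total <= 0) or np.any(states.in_camp <= 0):
        return -math.inf

    rho_t, mu_t, p_t = model_arrays(params, schedule, data.axis)
    x, xc = states.total, states.in_camp

    m0, s0 = initial_state_prior(data)
    total = lp + float(_lognorm_logpdf(x[0], m0, s0))
    # process: X_t | X_{t-1}, t = 1..T-1
    logm = np.log(x[:-1]) + (rho_t[1:] - mu_t[1:])
    total += float(np.sum(_lognorm_logpdf(x[1:], logm, params.sigma_proc)))
    # in-camp layer, all months
    total += float(np.sum(_lognorm_logpdf(xc, np.log(p_t * x), params.sigma_camp)))
    # observation layer, observed months only
    obs = data.observed
    total += float(np.sum(_lognorm_logpdf(data.y[obs], np.log(xc[obs]),
                                          params.sigma_obs)))
    return total
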