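"""Deterministic model functions: seasonality, cyclone effects, priors and
the joint density."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import lognorm

import roosttrend as rt
from roosttrend.model_core import (DEFAULT_PRIOR, initial_state_prior,
                                   recruitment_suppression_mask)
from roosttrend.series import LatentTrajectory, TimeAxis

from conftest import make_counts

# alpha values solved from the stated December/June in-camp proportions
ALPHA2 = 2.0 / (0.86 - 0.30)
ALPHA1 = 0.86 * ALPHA2 - 1.0


def params(**kw):
    base = dict(rho=0.068, mu=0.017, c_rho=0.79, c_mu=5.7, c_r=0.24,
                alpha1=ALPHA1, alpha2=ALPHA2,
                sigma_proc=0.149, sigma_camp=0.10, sigma_obs=0.096)
    base.update(kw)
    return rt.Params(**base)


class TestCycloneRamp:
    @pytest.mark.parametrize("t,expected", [
        (30, 1.0),        # step down at impact
        (42, 0.0),        # full recovery at event + ramp_length
        (36, 0.5),        # linear midpoint
        (29, 0.0),        # before the event
        (60, 0.0),        # long after
    ])
    def test_single_event(self, t, expected):
        sched = rt.CycloneSchedule((30,))
        assert rt.cyclone_ramp(t, sched) == pytest.approx(expected)

    def test_overlapping_events_take_maximum(self):
        sched = rt.CycloneSchedule((10, 16))
        t = np.arange(10, 30)
        r = rt.cyclone_ramp(t, sched)
        single1 = rt.cyclone_ramp(t, rt.CycloneSchedule((10,)))
        single2 = rt.cyclone_ramp(t, rt.CycloneSchedule((16,)))
        assert np.array_equal(r, np.maximum(single1, single2))

    def test_year_indicator_variant(self):
        sched = rt.CycloneSchedule((30,), indicator="year")
        assert rt.cyclone_ramp(30, sched) == 1.0
        assert rt.cyclone_ramp(41, sched) == 1.0
        assert rt.cyclone_ramp(42, sched) == 0.0


class TestSeasonalProportion:
    def test_december_and_june_levels(self):
        axis = TimeAxis(24, start_month=1)
        p = params()
        dec = rt.seasonal_proportion(11, p, rt.CycloneSchedule(()), axis)
        jun = rt.seasonal_proportion(5, p, rt.CycloneSchedule(()), axis)
        assert dec == pytest.approx(0.86, abs=1e-12)
        assert jun == pytest.approx(0.30, abs=1e-12)

    def test_phase_and_amplitude(self):
        # over a cyclone-free year: max in December, min in June,
        # p_dec - p_jun = 2/alpha2 exactly
        axis = TimeAxis(12, start_month=5)
        p_t = rt.seasonal_proportion(np.arange(12), params(),
                                     rt.CycloneSchedule(()), axis)
        cal = axis.cal
        assert cal[np.argmax(p_t)] == 12
        assert cal[np.argmin(p_t)] == 6
        assert p_t.max() - p_t.min() == pytest.approx(2.0 / ALPHA2, abs=1e-14)

    def test_cyclone_reduction_at_impact(self):
        axis = TimeAxis(48, start_month=1)
        sched = rt.CycloneSchedule((20,))
        p = params(c_r=0.24)
        base = rt.seasonal_proportion(20, p, rt.CycloneSchedule(()), axis)
        hit = rt.seasonal_proportion(20, p, sched, axis)
        assert hit == pytest.approx(base * (1 - 0.24), rel=1e-12)

    def test_invalid_alpha_signals(self):
        with pytest.raises(ValueError):
            rt.seasonal_proportion(0, params(alpha1=0.5),
                                   rt.CycloneSchedule(()), TimeAxis(12))
        with pytest.raises(ValueError):
            rt.seasonal_proportion(0, params(alpha2=ALPHA1 + 0.5),
                                   rt.CycloneSchedule(()), TimeAxis(12))

    @settings(deadline=None, max_examples=50)
    @given(a1=st.floats(1.01, 30.0), gap=st.floats(1.01, 20.0),
           c_r=st.floats(0.0, 0.99), t=st.integers(0, 200))
    def test_bounded_on_unit_interval(self, a1, gap, c_r, t):
        p = params(alpha1=a1, alpha2=a1 + gap, c_r=c_r)
        sched = rt.CycloneSchedule((50,))
        val = rt.seasonal_proportion(t, p, sched, TimeAxis(12))
        assert 0.0 < val < 1.0


class TestRates:
    def test_recruitment_window(self):
        axis = TimeAxis(24, start_month=1)
        p = params(rho=0.07)
        t = np.arange(24)
        r = rt.recruitment_rate(t, p, rt.CycloneSchedule(()), axis)
        cal = axis.cal
        in_season = np.isin(cal, (12, 1, 2))
        assert np.all(r[in_season] == 0.07)
        assert np.all(r[~in_season] == 0.0)

    def test_recruitment_suppressed_first_season_only(self):
        # May start, event at index 22 (a March): the next season starts at
        # the following December and only that season carries c_rho
        axis = TimeAxis(120, start_month=5)
        sched = rt.CycloneSchedule((22,))
        p = params(rho=0.07, c_rho=0.79)
        t = np.arange(120)
        r = rt.recruitment_rate(t, p, sched, axis)
        season_start = 22 + (12 - 3) % 12  # next December
        assert axis.calendar_month(season_start) == 12
        assert np.all(r[season_start:season_start + 3]
                      == pytest.approx(0.07 * 0.79))
        later = season_start + 12
        assert np.all(r[later:later + 3] == pytest.approx(0.07))

    def test_mortality_values(self):
        sched = rt.CycloneSchedule((30,))
        p = params(mu=0.017, c_mu=5.7)
        assert rt.mortality_rate(10, p, sched) == pytest.approx(0.017)
        assert rt.mortality_rate(30, p, sched) == pytest.approx(0.017 * 5.7)
        # ramp applies to the excess: exact return to mu after recovery
        assert rt.mortality_rate(42, p, sched) == 0.017
        # c_mu = 1 is the no-effect lower bound
        assert rt.mortality_rate(30, params(c_mu=1.0), sched) == 0.017

    def test_drift_monotone_in_rates(self):
        axis = TimeAxis(12, start_month=12)
        sched = rt.CycloneSchedule(())
        lo = rt.recruitment_rate(0, params(rho=0.05), sched, axis)
        hi = rt.recruitment_rate(0, params(rho=0.08), sched, axis)
        assert hi > lo
        assert rt.mortality_rate(0, params(mu=0.03), sched) > \
            rt.mortality_rate(0, params(mu=0.01), sched)


def test_no_effect_cyclone_equals_empty_schedule():
    """c_mu=1, c_rho=1, c_r=0 must reproduce the cyclone-free model bitwise."""
    axis = TimeAxis(154, start_month=5)
    neutral = params(c_mu=1.0, c_rho=1.0, c_r=0.0)
    with_events = rt.model_arrays(neutral, rt.CycloneSchedule((22, 81, 105)),
                                  axis)
    without = rt.model_arrays(neutral, rt.CycloneSchedule(()), axis)
    for a, b in zip(with_events, without):
        assert np.array_equal(a, b)


class TestPrior:
    EPS = 1e-9

    @pytest.mark.parametrize("name,lo,hi", [
        ("rho", 0.0, 0.11),
        ("mu", 0.0, 0.1),
        ("c_mu", 1.0, 10.0),
        ("c_rho", 0.0, 1.0),
        ("c_r", 0.0, 1.0),
        ("sigma_obs", 0.05, 0.47),
        ("sigma_proc", 0.0, 10.0),
        ("sigma_camp", 0.0, 100.0),
    ])
    def test_support_boundaries(self, name, lo, hi):
        inside = params(**{name: (lo + hi) / 2})
        assert np.isfinite(rt.log_prior(inside))
        assert rt.log_prior(params(**{name: lo - self.EPS})) == -math.inf
        assert rt.log_prior(params(**{name: hi + self.EPS})) == -math.inf
        assert np.isfinite(rt.log_prior(params(**{name: lo + self.EPS})))
        assert np.isfinite(rt.log_prior(params(**{name: hi - self.EPS})))

    def test_c_mu_below_lower_bound(self):
        assert rt.log_prior(params(c_mu=0.5)) == -math.inf

    def test_alpha_ordering_constraint(self):
        assert np.isfinite(rt.log_prior(params(alpha1=2.0, alpha2=3.5)))
        assert rt.log_prior(params(alpha1=2.0, alpha2=2.9)) == -math.inf
        assert rt.log_prior(params(alpha1=60.0, alpha2=62.0)) == -math.inf

    def test_samples_in_support(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            assert np.isfinite(rt.log_prior(DEFAULT_PRIOR.sample(rng)))


class TestLogJoint:
    def _hand_built(self):
        y = np.array([300.0, np.nan, 410.0, 380.0, 150.0])
        data = make_counts(y, start_month=11)
        sched = rt.CycloneSchedule((2,))
        par = params()
        states = LatentTrajectory(
            total=np.array([900.0, 950.0, 920.0, 870.0, 500.0]),
            in_camp=np.array([310.0, 620.0, 400.0, 385.0, 160.0]))
        return states, par, data, sched

    def test_equals_term_by_term_oracle(self):
        """log_joint must decompose into independently computed univariate
        log-normal densities plus the prior, to 1e-10."""
        states, par, data, sched = self._hand_built()
        rho_t, mu_t, p_t = rt.model_arrays(par, sched, data.axis)
        m0, s0 = initial_state_prior(data)

        def dens(x, logm, sd):
            return lognorm.logpdf(x, s=sd, scale=math.exp(logm))

        x, xc, y = states.total, states.in_camp, data.y
        expected = rt.log_prior(par) + dens(x[0], m0, s0)
        for t in range(1, 5):
            expected += dens(x[t], math.log(x[t - 1]) + rho_t[t] - mu_t[t],
                             par.sigma_proc)
        for t in range(5):
            expected += dens(xc[t], math.log(p_t[t] * x[t]), par.sigma_camp)
        for t in (0, 2, 3, 4):   # month 1 is missing
            expected += dens(y[t], math.log(xc[t]), par.sigma_obs)

        got = rt.log_joint(states, par, data, sched)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_residual_is_local_maximum_and_sd_monotone(self):
        # states on the deterministic skeleton with matching observations:
        # each term sits at its density maximum, and inflating sigma_obs
        # with zero observation residuals strictly lowers the density
        axis = TimeAxis(6, start_month=1)
        par = params()
        sched = rt.CycloneSchedule(())
        rho_t, mu_t, p_t = rt.model_arrays(par, sched, axis)
        x = 1000.0 * np.exp(np.concatenate([[0.0],
                                            np.cumsum(rho_t[1:] - mu_t[1:])]))
        xc = p_t * x
        data = rt.CountSeries(y=xc.copy(), axis=axis)
        states = LatentTrajectory(total=x, in_camp=xc)
        base = rt.log_joint(states, par, data, sched)
        wider = rt.log_joint(states, par.replace(sigma_obs=0.2), data, sched)
        assert wider < base
        # perturbing a state away from the skeleton lowers the density
        bumped = LatentTrajectory(total=x * np.where(np.arange(6) == 3, 1.3, 1.0),
                                  in_camp=xc)
        assert rt.log_joint(bumped, par, data, sched) < base

    def test_error_signals(self):
        states, par, data, sched = self._hand_built()
        short = LatentTrajectory(total=states.total[:4],
                                 in_camp=states.in_camp[:4])
        with pytest.raises(ValueError):
            rt.log_joint(short, par, data, sched)
        neg = LatentTrajectory(total=states.total * -1.0,
                               in_camp=states.in_camp)
        assert rt.log_joint(neg, par, data, sched) == -math.inf

def test_suppression_mask_event_in_december():
    # an event in December suppresses the season that starts that same month
    axis = TimeAxis(40, start_month=12)
    mask = recruitment_suppression_mask(np.arange(40),
                                        rt.CycloneSchedule((0,)), axis)
    assert mask[:3].all() and not mask[3:].any()
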