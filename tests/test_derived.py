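"""Trend summaries: rate of increase, decline probability, November
intervals and projections."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import roosttrend as rt
from roosttrend.derived import skeleton_rate
from roosttrend.inference import PARAM_NAMES, PosteriorDraws
from roosttrend.series import TimeAxis

STUDY_FREQUENCY = 3.0 / (154.0 / 12.0)   # three events over 12.8 years


def _theta(**kw):
    return rt.default_params().replace(**kw).to_array()[None, :]


def long_run_skeleton_oracle(params: rt.Params, frequency: float,
                             n_events: int = 40) -> float:
    """Independent oracle: explicit month-by-month skeleton over a long
    horizon with events placed at the stated frequency."""
    spacing = 12.0 / frequency
    horizon = int(np.ceil((n_events * spacing + 48) / 12.0)) * 12
    axis = TimeAxis(horizon, start_month=1, start_year=None)
    events = tuple(int(round(24 + i * spacing)) for i in range(n_events))
    sched = rt.CycloneSchedule(events)
    rho_t, mu_t, _ = rt.model_arrays(params, sched, axis)
    total_log_change = float(np.sum(rho_t - mu_t))
    # events at exactly n_events over (horizon) months; rescale to the
    # requested frequency by attributing the baseline to the full horizon
    baseline = (3 * params.rho - 12 * params.mu) * horizon / 12.0
    per_event = (baseline - total_log_change) / n_events
    return 3 * params.rho - 12 * params.mu - frequency * per_event


class TestRateOfIncrease:
    def test_zero_frequency_matches_closed_form_exactly(self):
        rng = np.random.default_rng(0)
        prior = rt.DEFAULT_PRIOR
        for _ in range(100):
            p = prior.sample(rng)
            r = skeleton_rate(p, 0.0)[0]
            assert r == pytest.approx(3 * p.rho - 12 * p.mu, abs=1e-12)

    def test_matches_long_run_skeleton_oracle(self):
        for c_mu, c_rho, f in [(5.7, 0.79, STUDY_FREQUENCY),
                               (3.0, 0.5, 0.5), (1.5, 0.9, 0.1)]:
            p = rt.default_params().replace(c_mu=c_mu, c_rho=c_rho)
            got = skeleton_rate(p, f)[0]
            want = long_run_skeleton_oracle(p, f)
            assert got == pytest.approx(want, abs=1e-9)

    def test_monotone_nonincreasing_in_frequency(self):
        p = rt.default_params()
        rates = [skeleton_rate(p, f)[0] for f in (0.0, 0.1, 0.25, 0.5, 1.0)]
        assert all(b <= a + 1e-15 for a, b in zip(rates, rates[1:]))

    def test_with_cyclone_rate_below_no_cyclone_rate_drawwise(self):
        rng = np.random.default_rng(1)
        th = np.stack([rt.DEFAULT_PRIOR.sample(rng).to_array()
                       for _ in range(50)])
        rates = rt.rate_of_increase(th, STUDY_FREQUENCY)
        assert np.all(rates.r_with_cyclone <= rates.r_no_cyclone + 1e-15)

    def test_negative_frequency_signals(self):
        with pytest.raises(ValueError):
            rt.rate_of_increase(_theta(), -0.1)

    def test_trivial_zero(self):
        # effectively no demography, no cyclones: r = 0
        th = _theta(rho=0.0, mu=0.0)
        assert skeleton_rate(th, 0.0)[0] == 0.0


class TestProbDecline:
    def test_all_negative_and_symmetric(self):
        assert rt.prob_decline(np.array([-0.1, -0.2, -0.3])) == 1.0
        sym = np.concatenate([np.linspace(-1, -0.01, 500),
                              np.linspace(0.01, 1, 500)])
        assert rt.prob_decline(sym) == pytest.approx(0.5)

    def test_normal_draws_match_cdf_oracle(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(-0.12, 0.127, 50_000)
        want = norm.cdf(0.0, loc=-0.12, scale=0.127)   # ~0.828
        assert rt.prob_decline(draws) == pytest.approx(want, abs=0.01)

    def test_equals_empirical_cdf_at_zero(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(0.02, 0.1, 5000)
        assert rt.prob_decline(draws) == np.mean(draws < 0)

    def test_empty_signals(self):
        with pytest.raises(ValueError):
            rt.prob_decline(np.array([]))


def _degenerate_draws(data, schedule, value_total=1000.0, value_camp=400.0):
    """PosteriorDraws with identical parameter and state draws."""
    T = data.n_months
    th = rt.default_params().to_array()
    params = np.tile(th, (2, 20, 1))
    st = np.full((2, 4, T), value_total)
    sc = np.full((2, 4, T), value_camp)
    return PosteriorDraws(params=params, param_names=PARAM_NAMES,
                          acceptance=np.full((2, 1), 0.3),
                          move_names=("rho",), states_total=st,
                          states_camp=sc,
                          state_iters=np.array([0, 5, 10, 15]),
                          data=data, schedule=schedule,
                          config=rt.McmcConfig(n_chains=2, n_iter=20,
                                               n_burnin=0, seed=0))


class TestNovemberSummary:
    def test_degenerate_draws_have_zero_width(self, sim_default):
        draws = _degenerate_draws(sim_default.counts, sim_default.schedule)
        nov = rt.november_summary(draws)
        assert len(nov) == 13   # Novembers 2004..2016 in a May-2004 start
        assert (nov["total_q0.025"] == nov["total_q0.975"]).all()
        assert (nov["year"] == np.arange(2004, 2017)).all()

    def test_quantiles_monotone(self, quick_fit):
        nov = rt.november_summary(quick_fit)
        for tag in ("total", "in_camp"):
            assert (nov[f"{tag}_q0.025"] <= nov[f"{tag}_q0.5"]).all()
            assert (nov[f"{tag}_q0.5"] <= nov[f"{tag}_q0.975"]).all()

    def test_no_november_signals(self):
        axis = TimeAxis(5, start_month=1)
        data = rt.CountSeries(y=np.linspace(100, 200, 5), axis=axis)
        draws = _degenerate_draws(data, rt.CycloneSchedule(()))
        with pytest.raises(ValueError, match="November"):
            rt.november_summary(draws)

    def test_state_free_posterior_signals(self, quick_fit):
        bare = PosteriorDraws(params=quick_fit.params,
                              param_names=quick_fit.param_names,
                              acceptance=quick_fit.acceptance,
                              move_names=quick_fit.move_names,
                              data=quick_fit.data)
        with pytest.raises(ValueError, match="state"):
            rt.november_summary(bare)


def test_november_intervals_cover_truth():
    """95% posterior intervals for the November states contain the true
    simulated states in at least 90% of year-layer combinations across
    10 replicate fits."""
    total, inside = 0, 0
    for rep in range(10):
        ds = rt.simulate(rt.default_scenario(seed=500 + rep))
        cfg = rt.McmcConfig(n_chains=3, n_iter=3000, n_burnin=1500,
                            seed=600 + rep)
        dr = rt.fit(ds.counts, ds.schedule, cfg)
        nov = rt.november_summary(dr)
        for _, row in nov.iterrows():
            t = int(row["month_index"])
            for tag, arr in (("total", ds.truth.total),
                             ("in_camp", ds.truth.in_camp)):
                total += 1
                inside += (row[f"{tag}_q0.025"] <= arr[t]
                           <= row[f"{tag}_q0.975"])
    assert inside / total >= 0.90


class TestProject:
    def test_horizon_zero_returns_last_state_quantiles(self, quick_fit):
        p = rt.project(quick_fit, 0, seed=1)
        assert len(p) == 1
        last = quick_fit.states_total[:, :, -1].ravel()
        assert p.loc[0, "total_q0.5"] == pytest.approx(np.median(last))

    def test_zero_noise_projection_is_flat(self, sim_default):
        par = rt.default_params().replace(rho=1e-9, mu=1e-9,
                                          sigma_proc=1e-12, sigma_camp=1e-12)
        draws = _degenerate_draws(sim_default.counts, rt.CycloneSchedule(()))
        draws.params[:] = par.to_array()
        p = rt.project(draws, 12, seed=2)
        assert np.allclose(p["total_q0.5"], 1000.0, rtol=1e-6)
        assert np.allclose(p["total_q0.025"], p["total_q0.975"], rtol=1e-6)

    def test_future_cyclone_depresses_projection(self, quick_fit, sim_default):
        T = sim_default.counts.n_months
        none = rt.project(quick_fit, 24, seed=3)
        hit = rt.project(quick_fit, 24,
                         future_schedule=rt.CycloneSchedule((T,)), seed=3)
        assert (none["total_q0.5"].to_numpy()
                > hit["total_q0.5"].to_numpy()).all()

    def test_empty_posterior_signals(self, quick_fit):
        bare = PosteriorDraws(params=quick_fit.params,
                              param_names=quick_fit.param_names,
                              acceptance=quick_fit.acceptance,
                              move_names=quick_fit.move_names,
                              data=quick_fit.data)
        with pytest.raises(ValueError):
            rt.project(bare, 12, seed=0)


def test_percent_decline_between_novembers(sim_default):
    draws = _degenerate_draws(sim_default.counts, sim_default.schedule)
    draws.states_total[:, :, :] = np.linspace(
        2000, 1000, sim_default.counts.n_months)
    nov = rt.november_summary(draws)
    d = rt.percent_decline(nov, 2004, 2016)
    medians = nov.set_index("year")["total_q0.5"]
    assert d == pytest.approx(
        100 * (1 - medians[2016] / medians[2004]))
    assert 0 < d < 100
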