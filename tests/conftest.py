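import numpy as np
import pytest

import roosttrend as rt


@pytest.fixture(scope="session")
def truth():
    """Default-scenario generating parameters."""
    return rt.default_params()


@pytest.fixture(scope="session")
def sim_default():
    """One 154-month dataset from the default (study-like) scenario."""
    return rt.simulate(rt.default_scenario(seed=11))


@pytest.fixture(scope="session")
def quick_fit(sim_default):
    """A short but converged posterior fit with state draws, shared across
    tests that only need a valid PosteriorDraws object."""
    cfg = rt.McmcConfig(n_chains=2, n_iter=1500, n_burnin=800, seed=21)
    return rt.fit(sim_default.counts, sim_default.schedule, cfg)


def make_counts(y, start_month=5, start_year=2004):
    y = np.asarray(y, dtype=float)
    axis = rt.TimeAxis(len(y), start_month=start_month, start_year=start_year)
    return rt.CountSeries(y=y, axis=axis)
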