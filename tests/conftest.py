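import warnings

import numpy as np
import pytest

from corridorsim.pipeline import RunConfig, run
from corridorsim.synthetic_valley import ValleyConfig, generate_landscape, toy_landscape

ALL_SCENARIOS = ("base", "limited_urban_expansion", "no_informal_trails", "restricted_recreation")


@pytest.fixture(scope="session")
def toy5():
    return toy_landscape(5)


@pytest.fixture(scope="session")
def small_valley():
    """A small but fully structured valley for fast integration tests."""
    cfg = ValleyConfig(n_rows=40, n_cols=60, n_collar_cells=250, rng_seed=11)
    state, activity, collar = generate_landscape(cfg)
    return cfg, state, activity, collar


@pytest.fixture(scope="session")
def default_valley():
    """The default full-size synthetic valley (the study conditions)."""
    cfg = ValleyConfig()
    state, activity, collar = generate_landscape(cfg)
    return cfg, state, activity, collar


@pytest.fixture(scope="session")
def full_run():
    """One full-landscape scenario run shared by the slower acceptance checks.

    Full default grid; the path sampler is run at a reduced ensemble size
    (40 x 40 x 3 per landscape) so the whole timeline-and-scenario sweep
    stays inside a few minutes.
    """
    cfg = RunConfig(rng_seed=1, scenarios=ALL_SCENARIOS, n_start=40, n_end=40, n_iter=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
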