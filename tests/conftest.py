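import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import costedbeads as cb

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    return cb.TaskConfig()


@pytest.fixture(scope="session")
def blocks(config):
    return cb.default_blocks(config)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 3+3-subject cohort with clearly separated cost distributions."""
    return cb.CohortSpec(
        groups=(
            cb.GroupSpec("low", 3, cb.GammaMoments(0.01, 1e-4), cb.GammaMoments(2.0, 1.0)),
            cb.GroupSpec("high", 3, cb.GammaMoments(8.0, 4.0), cb.GammaMoments(2.0, 1.0)),
        ),
        config=cb.TaskConfig(n_trials_per_block=5),
    )


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    data, truth = cb.simulate_dataset(small_cohort, seed=11)
    return data, truth


@pytest.fixture(scope="session")
def small_grid():
    return cb.ParamGrid.default(n_cs=24, n_t=18)
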