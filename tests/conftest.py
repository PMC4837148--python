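import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vestibsim as vs
from vestibsim.population import LEFT, RIGHT, AfferentPopulation

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_toy_population(n_per_side=10, rate=20.0, cv=0.05, seed=None):
    """Deterministic toy population with identical rates and identity ranks."""
    n = 2 * n_per_side
    return AfferentPopulation(
        mean_rest_rate=np.full(n, rate),
        cv=np.full(n, cv),
        side=np.array([LEFT] * n_per_side + [RIGHT] * n_per_side),
        recruitment_rank=np.concatenate([np.arange(n_per_side)] * 2),
        n_per_side=n_per_side,
        seed=seed,
    )


@pytest.fixture(scope="session")
def toy_pop():
    return make_toy_population()


@pytest.fixture(scope="session")
def default_pop():
    return vs.sample_population(seed=11)


@pytest.fixture(scope="session")
def adapted_model():
    """Default three-phase adapted model (200 pps, ratio 2e3), shared."""
    return vs.default_acute_model(seed=11)
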