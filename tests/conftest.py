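import numpy as np
import pytest

from shortform.instrument import InstrumentSpec, default_instrument
from shortform.simulate import (
    SimulationConfig,
    generate_true_parameters,
    simulate_responses,
)


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


@pytest.fixture(scope="session")
def small_instrument():
    ids = tuple(f"I{j:02d}" for j in range(12))
    sub = {i: ("A" if j < 6 else "B") for j, i in enumerate(ids)}
    return InstrumentSpec(ids, sub, {i: 5 for i in ids})


@pytest.fixture(scope="session")
def moderate_config():
    """Generator ranges with identifiable intercepts for recovery checks."""
    return SimulationConfig(
        intercept_top_range=(1.0, 2.5), intercept_bottom_range=(-2.5, -1.0)
    )


@pytest.fixture(scope="session")
def small_dataset(small_instrument, moderate_config):
    params = generate_true_parameters(small_instrument, config=moderate_config, seed=0)
    return params, simulate_responses(params, 400, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
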