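import numpy as np
import pytest

from netflux.synthetic import (
    SyntheticModelSpec,
    generate_model,
    mock_graph,
)


@pytest.fixture(scope="session")
def mock_net():
    return mock_graph().to_network()


@pytest.fixture(scope="session")
def linear_model():
    return generate_model(SyntheticModelSpec(topology="linear", n_reactions=4, seed=0))


@pytest.fixture(scope="session")
def parallel_model():
    return generate_model(SyntheticModelSpec(topology="parallel", n_reactions=3, seed=0))


@pytest.fixture(scope="session")
def branched_model():
    return generate_model(SyntheticModelSpec(topology="branched", n_reactions=3, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
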