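import numpy as np
import pytest
from hypothesis import settings

# deterministic property tests: derandomised, no per-example deadline
settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from insulinit.network import (
    ParameterVector,
    Reaction,
    ReactionNetwork,
    Species,
)
from insulinit.synthetic import build_toy_bundle, build_toy_insulin_network, toy_conditions


@pytest.fixture
def decay_network():
    """dx/dt = -k x: single first-order decay A -> sink."""
    return ReactionNetwork(
        [Species("A", initial_amount=1.0)],
        [Reaction("decay", (("A", 1),), (), rate_constant=1.0)],
    )


@pytest.fixture
def chain_network():
    """Open linear chain 0 -> A -> B -> 0 with known steady state."""
    return ReactionNetwork(
        [Species("A"), Species("B")],
        [
            Reaction("src", (), (("A", 1),), rate_constant=1.0),
            Reaction("ab", (("A", 1),), (("B", 1),), rate_constant=2.0),
            Reaction("deg", (("B", 1),), (), rate_constant=0.5),
        ],
    )


@pytest.fixture(scope="session")
def toy_network():
    return build_toy_insulin_network()


@pytest.fixture(scope="session")
def toy_params(toy_network):
    return toy_network.nominal_parameters()

@pytest.fixture(scope="session")
def conditions():
    return toy_conditions()


@pytest.fixture(scope="session")
def noiseless_bundle():
    return build_toy_bundle(seed=11, noise_cv=0.0)


@pytest.fixture(scope="session")
def noisy_bundle():
    return build_toy_bundle(seed=11, noise_cv=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
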