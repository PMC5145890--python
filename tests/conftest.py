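"""Shared fixtures: the committed synthetic dataset and a trained network.

Expensive artifacts (the reference dataset and the network trained on it) are
built once per session and shared; tests that mutate a network build their
own.
"""

import numpy as np
import pytest

from snnbmi.config import make_fixture
from snnbmi.decoder import train_decoder
from snnbmi.loop import build_workspace, calibrate_field
from snnbmi.network import NetworkConfig, build_network

MASTER = 1  # canonical example seed used throughout the suite


@pytest.fixture(scope="session")
def paper_fixture():
    return make_fixture("paper-like", seed=MASTER)


@pytest.fixture(scope="session")
def trained_network(paper_fixture):
    net = build_network(NetworkConfig(seed=MASTER + 100))
    train_decoder(net, paper_fixture["train"], seed=MASTER + 200)
    return net


@pytest.fixture(scope="session")
def workspace():
    return build_workspace()


@pytest.fixture(scope="session")
def field(workspace):
    return calibrate_field(workspace)


@pytest.fixture
def tiny_config():
    """A 4-ensemble network small enough for brute-force reference checks."""
    return NetworkConfig(
        n_neurons=8, n_ensembles=4, ensemble_size=2,
        n_plastic_synapses_per_neuron=16, seed=5,
    )
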