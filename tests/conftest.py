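"""Shared fixtures: small circuits for unit tests, full-size for acceptance."""

import numpy as np
import pytest

from mbcircuit.circuit_model import TransferParams, build_tuned_circuit
from mbcircuit.plasticity import ModelInstance, make_instances
from mbcircuit.synthetic_data import gen_orn_panel


@pytest.fixture(scope="session")
def small_panel():
    """40-odour, 24-channel panel: fast but structurally faithful."""
    return gen_orn_panel(n_odours=40, n_orns=24, seed=11)


@pytest.fixture(scope="session")
def small_instance(small_panel):
    """One tuned 400-KC instance on the small panel (n_trials=10)."""
    circuit, pn_inputs = build_tuned_circuit(
        small_panel, M=400, seed=5, n_trials=10
    )
    return ModelInstance(circuit=circuit, pn_inputs=pn_inputs)


@pytest.fixture(scope="session")
def full_panel():
    """The default 110x24 synthetic panel used by the acceptance suite."""
    return gen_orn_panel(seed=202)


@pytest.fixture(scope="session")
def tuned_instances(full_panel):
    """Twenty full-size tuned instances (2000 KCs, 30 noisy trials each)."""
    return make_instances(n_instances=20, panel=full_panel, seed=17)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
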