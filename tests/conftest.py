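import numpy as np
import pytest

import rnabc


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale simulation world shared by unit tests (fast to build)."""
    return rnabc.SimulationConfig(
        seed=11,
        n_probesets=60,
        n_signature=24,
        n_train_per_subtype=4,
        n_test_per_subtype=1,
        n_reads_per_sample=4000,
        target_length_range=(250, 400),
    )


@pytest.fixture(scope="session")
def tiny_targets(tiny_config):
    return rnabc.simulate_targets(tiny_config)


@pytest.fixture(scope="session")
def tiny_training(tiny_config, tiny_targets):
    return rnabc.simulate_training_matrix(tiny_config, tiny_targets)


@pytest.fixture(scope="session")
def toy_targets():
    """Hand-written targets with known sequences for exact assertions."""
    return rnabc.ProbeTargetSet(
        {
            "t0": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGG",
            "t1": "TTTTCCCCGGGGAAAATTTTCCCCGGGGAAAATTTTCCCA",
            "t2": "ACGGTCATCGATCGATTACGGATCCGATTACAGCATACGT",
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
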