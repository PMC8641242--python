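import numpy as np
import pytest

from collative.discrete import DiscreteGenerativeModel

SUITE_SEED = 20211119


@pytest.fixture
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture
def coin_model():
    """Two causes, two symbols; observing symbol 0 gives posterior (2/3, 1/3)."""
    return DiscreteGenerativeModel(
        prior=[0.5, 0.5],
        likelihood=[[0.8, 0.2], [0.4, 0.6]],
        cause_labels=("theta1", "theta2"),
        symbol_labels=("s0", "s1"),
    )
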