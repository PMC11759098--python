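import numpy as np
import pytest

from aaderp import SessionSpec, generate_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_session():
    """A short high-contrast session shared by decoder/evaluation tests."""
    return generate_session(SessionSpec(n_trials=10, n_channels=4, seed=7))
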