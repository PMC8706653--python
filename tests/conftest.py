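import numpy as np
import pytest

from harfusion import ProtocolSpec, WindowSet, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_ws(rng):
    """Factory for small random WindowSets."""

    def make(n=12, L=10, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return WindowSet(
            data=r.uniform(-2, 2, size=(n, L, 6)),
            labels=r.integers(0, 6, size=n),
        )

    return make


@pytest.fixture(scope="session")
def sim_small():
    """120-window simulated set (2 participants x 6 activities x 10 windows)."""
    return generate_dataset(
        ProtocolSpec(n_participants=2, windows_per_participant_per_activity=10, seed=7)
    )
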