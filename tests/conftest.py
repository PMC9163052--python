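import numpy as np
import pytest

from stemdish import PatternSpec, SimConfig, build_dish


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Fast-terminating configuration for engine smoke tests."""
    return SimConfig(signals_enabled=False, termination_divisions=2, n_shots=20, seed=3)


@pytest.fixture(scope="session")
def small_dish():
    """Radius-8 circular dish (shared, read-only; copy before mutating)."""
    rng = np.random.default_rng(3)
    return build_dish(PatternSpec("circle", 8, 4), rng)
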