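import numpy as np
import pytest

from scalepgg import GameParameters, PopulationState, SimulationConfig


@pytest.fixture
def fig_params() -> GameParameters:
    """Baseline analytic parameters: weak selection, rare mutation."""
    return GameParameters(M=100, N=5, c=1.0, r=3.0, alpha=1.0, delta=1.0,
                          gamma=0.3, omega=0.1, mu=0.0)


@pytest.fixture
def sim_params() -> GameParameters:
    """Baseline simulation parameters: strong selection, finite mutation."""
    return GameParameters(M=100, N=5, c=1.0, r=3.0, alpha=1.0, delta=1.0,
                          gamma=0.3, omega=0.5, mu=0.001)


@pytest.fixture
def small_params() -> GameParameters:
    """A small population where exhaustive oracles are cheap."""
    return GameParameters(M=10, N=3, c=1.0, r=3.0, alpha=1.8, delta=1.0,
                          gamma=0.3, omega=0.1, mu=0.0)


@pytest.fixture
def mixed_start() -> PopulationState:
    return PopulationState(30, 40, 30)


@pytest.fixture
def short_config(mixed_start) -> SimulationConfig:
    return SimulationConfig(periods=2000, seed=7, initial_state=mixed_start,
                            burn_in=0, record_every=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
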