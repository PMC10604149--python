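import numpy as np
import pytest

from cuttleflow import (
    WATER,
    DualTrace,
    SimulationConfig,
    WashburnModel,
    dual_channel_geometry,
)


@pytest.fixture(scope="session")
def water():
    return WATER


@pytest.fixture(scope="session")
def narrow_gap_model(water):
    """Capillary-rise model in a 100 um gap (crossover time ~10 ms)."""
    return WashburnModel(fluid=water, gap_width=1e-4)


@pytest.fixture(scope="session")
def wavy_pair():
    """Standard dual geometry at the 0.188 mm amplitude preset."""
    return dual_channel_geometry(0.188e-3)


@pytest.fixture(scope="session")
def straight_pair():
    return dual_channel_geometry(0.0)


@pytest.fixture
def quiet_config():
    """Noise-free simulation config (deterministic dynamics)."""
    return SimulationConfig(roughness_sigma=0.0, seed=0)


@pytest.fixture
def exponential_trace():
    """DualTrace whose separation is exactly D0 * exp(lambda0 t)."""

    def make(lambda0: float, d0: float = 1e-4, n: int = 300, dt: float = 0.05):
        t = np.arange(n) * dt
        # one resting front: D = s1 exactly, free of subtraction roundoff
        s2 = np.zeros(n)
        s1 = d0 * np.exp(lambda0 * t)
        return DualTrace(times=t, s1=s1, s2=s2)

    return make
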