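import numpy as np
import pytest

from wavemem.engine import SpikeRaster
from wavemem.network import DriveSpec, NetworkConfig


@pytest.fixture(scope="session")
def tiny_config() -> NetworkConfig:
    return NetworkConfig(n_ex=32, n_inh=8, m_modules=2, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_raster(events, n_neurons, module, is_exc=None, item=None) -> SpikeRaster:
    """Hand-built raster: ``events`` is a list of (time_ms, neuron)."""
    events = sorted(events)
    times = np.array([t for t, _ in events], dtype=float)
    neurons = np.array([i for _, i in events], dtype=np.int64)
    module = np.asarray(module, dtype=np.int32)
    if is_exc is None:
        is_exc = np.ones(n_neurons, dtype=bool)
    if item is None:
        item = np.full(n_neurons, "", dtype=object)
    return SpikeRaster(times, neurons, module, np.asarray(is_exc, bool),
                       np.asarray(item, dtype=object))


@pytest.fixture
def flat_theta_drive() -> DriveSpec:
    """8 Hz theta with no traveling wave (all modules in phase)."""
    return DriveSpec.theta(psi_osc=0.0)
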