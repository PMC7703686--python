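import numpy as np
import pytest

from autoreg import SimulationConfig, ThrtSimSpec, synth_recording


@pytest.fixture(scope="session")
def short_recording():
    """Clean 600-s recording at the default intact-autoregulation config."""
    return synth_recording(SimulationConfig(duration_s=600.0, seed=11))


@pytest.fixture(scope="session")
def passive_recording():
    """Noiseless fully pressure-passive recording (g=1)."""
    cfg = SimulationConfig(duration_s=600.0, coupling_gain=1.0,
                           intrinsic_slow_amp=0.0, noise_sd=0.0, seed=12)
    return synth_recording(cfg)


@pytest.fixture
def default_thrt_spec():
    return ThrtSimSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
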