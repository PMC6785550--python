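import numpy as np
import pytest
from hypothesis import settings

from standscore.simulate import ClassPreset, EvokedKernel, default_presets

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def quiet_preset():
    """Deterministic preset: no noise, no amplitude jitter, constant envelope."""
    return ClassPreset(name="quiet", kernel=EvokedKernel(40.0),
                       amplitude_cv=0.0, envelope=None, gain=1.0,
                       noise_rms_uv=0.0)


@pytest.fixture(scope="session")
def presets():
    return default_presets()
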