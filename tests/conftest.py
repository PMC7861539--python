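import numpy as np
import pytest

import nmprobe as nm


@pytest.fixture(scope="session")
def default_config():
    return nm.CoupledModelConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Deterministic (noise-free) default parameterization."""
    return nm.CoupledModelConfig(noise_1=nm.NoiseSpec(90.0, 0.0),
                                 noise_2=nm.NoiseSpec(90.0, 0.0))


@pytest.fixture(scope="session")
def passive_stim():
    return nm.StimulusProtocol(amplitude=0.0)


@pytest.fixture(scope="session")
def background_run(default_config, passive_stim):
    """100 s passive simulation at default (normal background) parameters."""
    setting = nm.ModelSetting("background", default_config, None, (1, 2))
    return nm.integrate(setting, passive_stim,
                        nm.IntegrationSpec(duration=100.0, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
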