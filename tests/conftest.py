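import numpy as np
import pytest

from uapipe.task_synth import EffectConfig, StimulusConfig, generate_session_design


@pytest.fixture(scope="session")
def stim_config():
    return StimulusConfig()


@pytest.fixture(scope="session")
def effects():
    return EffectConfig()


@pytest.fixture(scope="session")
def default_design():
    return generate_session_design(seed=1)


@pytest.fixture(scope="session")
def small_design():
    return generate_session_design(n_runs=1, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
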