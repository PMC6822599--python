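import numpy as np
import pytest

from stepstab import AnalysisConfig, analyze_trial
from stepstab.synthetic import preset_params, simulate_trial


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def walking_trial():
    """Moderate-size walking trial with default (noisy) preset."""
    params = preset_params("walking", n_steps=60, seed=101)
    trial, truth = simulate_trial(params)
    return params, trial, truth


@pytest.fixture(scope="session")
def running_trial():
    params = preset_params("running", n_steps=60, seed=202)
    trial, truth = simulate_trial(params)
    return params, trial, truth


@pytest.fixture(scope="session")
def clean_walking_trial():
    """Noise-free walking trial: exact chain from law to placements."""
    params = preset_params("walking", n_steps=40, seed=7, marker_noise_sd=0.0,
                           cop_noise_sd=0.0, force_noise_sd=0.0,
                           com_decouple_sd=0.0)
    trial, truth = simulate_trial(params)
    return params, trial, truth


@pytest.fixture(scope="session")
def walking_result(walking_trial, config):
    _, trial, _ = walking_trial
    return analyze_trial(trial, config)


@pytest.fixture(scope="session")
def running_result(running_trial, config):
    _, trial, _ = running_trial
    return analyze_trial(trial, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
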