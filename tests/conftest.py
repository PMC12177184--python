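import numpy as np
import pytest
from hypothesis import settings

from katyjump import StudyConfig, simulate_study
from katyjump.synth import study_variant

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_config() -> StudyConfig:
    return StudyConfig(seed=1)


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """A reduced study (12 jumps, 4 animals) for fast end-to-end tests."""
    return study_variant(
        StudyConfig(seed=7),
        n_animals=4,
        n_males=3,
        jumps_per_height=(4, 4, 4),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def noisefree_study():
    """Zero-variance, zero-noise study: estimates should hit the means."""
    cfg = study_variant(
        StudyConfig(seed=5),
        n_animals=3,
        n_males=2,
        jumps_per_height=(2, 2, 2),
        lv_se=(0.0, 0.0, 0.0),
        av_se=(0.0, 0.0, 0.0),
        ftj_takeoff_se=(0.0, 0.0, 0.0),
        ftj_rest_se=(0.0, 0.0, 0.0),
        tracking_noise_sd=0.0,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
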