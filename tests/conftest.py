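import numpy as np
import pytest

from slskit.config import PipelineConfig
from slskit.kinematics import score_cohort
from slskit.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A small but fully populated cohort configuration."""
    return CohortConfig(
        n_subjects=12,
        sigma2_p=75.0,
        sigma2_o=5.0,
        sigma2_res=20.0,
        mean_angle_down=4.0,
        mean_angle_up=1.0,
        sensor_noise_sd=0.1,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    return score_cohort(small_cohort.trajectories)


@pytest.fixture
def pipeline_config():
    return PipelineConfig(
        cohort=CohortConfig(
            n_subjects=10,
            easy_mode_rate=0.05,
            missing_rate=0.02,
            sensor_noise_sd=0.1,
            seed=7,
        )
    )
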