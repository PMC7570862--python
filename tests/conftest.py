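import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from harsdae.simulate import StudyProtocol, default_activity_models, generate_study
from harsdae.windowing import InstanceSet, segment_all


@pytest.fixture(scope="session")
def models():
    return default_activity_models()


@pytest.fixture(scope="session")
def tiny_protocol():
    """Two subjects, short bouts: fast but structurally complete."""
    return StudyProtocol(
        n_subjects=2,
        continuous_bout_s=40.0,
        transitional_hold_s=15.0,
        continuous_repeats=1,
        transitional_repeats=1,
        sampling_rate=102.4,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_protocol, models):
    return generate_study(tiny_protocol, models)


@pytest.fixture(scope="session")
def tiny_instances(tiny_study) -> InstanceSet:
    return segment_all(tiny_study, window_size=512, overlap=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
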