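import numpy as np
import pytest
from hypothesis import settings

import eogwave as ew

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_recording() -> ew.EOGRecording:
    """The full study protocol: 5 x 6500 samples at 650 Hz, seed 4."""
    return ew.generate_recording()


@pytest.fixture(scope="session")
def small_recording() -> ew.EOGRecording:
    """A shortened session (5 x 1664 samples) for fast end-to-end tests."""
    return ew.generate_recording(ew.SyntheticConfig(samples_per_segment=1664, seed=4))


@pytest.fixture(scope="session")
def default_features(default_recording) -> ew.FeatureMatrix:
    return ew.build_feature_matrix(default_recording, ew.DEFAULT_MOTHER)


@pytest.fixture(scope="session")
def small_features(small_recording) -> ew.FeatureMatrix:
    return ew.build_feature_matrix(small_recording, ew.DEFAULT_MOTHER)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
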