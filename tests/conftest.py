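import numpy as np
import pytest

from gliorad.pipeline import _subject_channels_from_phantom
from gliorad.synthetic import PhantomConfig, generate_subject


@pytest.fixture(scope="session")
def small_config():
    return PhantomConfig(grid_shape=(40, 40, 40), n_subjects=2,
                         tumor_radius_range_mm=(6.0, 9.0), seed=11)


@pytest.fixture(scope="session")
def phantom_subject(small_config):
    return generate_subject(small_config, 0)


@pytest.fixture(scope="session")
def phantom_channels(phantom_subject):
    """Preprocessed channels + mask for the small phantom subject."""
    return _subject_channels_from_phantom(phantom_subject, {})


@pytest.fixture
def rng():
    return np.random.default_rng(123)
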