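import numpy as np
import pytest

from emodraw.color_features import extract_features
from emodraw.palette import ColorPalette
from emodraw.pipeline import features_frame
from emodraw.synthetic_data import default_profiles, generate_cohort


@pytest.fixture(scope="session")
def palette() -> ColorPalette:
    return ColorPalette()


@pytest.fixture(scope="session")
def small_cohort():
    """A small rendered cohort shared across tests (seed fixed up front)."""
    return generate_cohort(default_profiles(), n_per_emotion=6, seed=0,
                           canvas=(128, 128))


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    feats = [extract_features(img) for img in small_cohort.images]
    return features_frame(feats)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
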