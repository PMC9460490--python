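import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mozznet.features import FeatureExtractor
from mozznet.pipeline import dataset_to_arrays, train_with_restarts
from mozznet.synth import DatasetSpec, build_dataset

#: single fixed seed for every session-scoped fixture
FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def extractor():
    return FeatureExtractor()


@pytest.fixture(scope="session")
def dataset_arrays():
    """Featurized synthetic corpus: split -> (uint8 images, labels)."""
    return dataset_to_arrays(build_dataset(DatasetSpec(seed=FIXTURE_SEED)))


@pytest.fixture(scope="session")
def trained_model(dataset_arrays):
    """Default CNN trained once for the whole session (a few minutes)."""
    model, _ = train_with_restarts(dataset_arrays, seed=FIXTURE_SEED)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(FIXTURE_SEED)
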