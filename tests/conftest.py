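import numpy as np
import pytest

from mhsgtr.io import MultiOmicsDataset, OmicsMatrix, SurvivalTable
from mhsgtr.model import TrainConfig
from mhsgtr.simulate import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    return OmicsMatrix("toy", ["s1", "s2", "s3"], ["f1", "f2"],
                       np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]))


@pytest.fixture
def small_dataset():
    """60-sample, 3-cluster, 2-view dataset with survival and clinical tables."""
    spec = SyntheticSpec(n_samples=60, n_clusters=3, view_dims=(50, 30),
                         separation=3.0, seed=7)
    return generate_dataset(spec)


@pytest.fixture
def desk_config():
    """Small, fast training configuration for unit tests."""
    return TrainConfig(hidden_dims=(16, 8), pretrain_epochs=5,
                       train_epochs=12, prox_every=4, target_refresh=4,
                       n_clusters=3, seed=3)
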