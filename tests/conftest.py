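import numpy as np
import pytest

from deeparc import MotifModel, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Quick balanced dataset for trainer/CLI plumbing tests."""
    return generate_dataset(n_pos=60, rng_seed=101)


@pytest.fixture(scope="session")
def tiny_train_kwargs():
    """Estimator settings that train in seconds on the small dataset."""
    return dict(epochs=2, vector_dim=16, sg_epochs=1, cnn_channels=16)


@pytest.fixture
def strong_motif():
    return MotifModel.from_consensus("TGACGTCA")
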