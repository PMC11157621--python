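import numpy as np
import pytest

from mvmanifold import MultiViewDataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_blob_matrix():
    """40 samples in two well-separated Gaussian blobs (10 sigma apart)."""
    g = np.random.default_rng(7)
    X = np.vstack([g.normal(0.0, 1.0, (20, 5)), g.normal(10.0, 1.0, (20, 5))])
    labels = np.repeat([0, 1], 20)
    return X, labels


@pytest.fixture()
def small_two_view_dataset():
    """Two random views on 30 shared samples."""
    g = np.random.default_rng(3)
    return MultiViewDataset(
        views=[g.normal(size=(30, 6)), g.normal(size=(30, 4))],
        labels=np.repeat([0, 1, 2], 10),
    )
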