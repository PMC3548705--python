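import numpy as np
import pytest

import seco


@pytest.fixture(scope="session")
def spec10():
    return seco.table1_spec()


@pytest.fixture(scope="session")
def sample10k(spec10):
    """The canonical large benchmark sample used across heavy tests."""
    X, y = seco.sample_mixture(spec10, 10_000, 1)
    return X, y


@pytest.fixture(scope="session")
def reference10k(sample10k):
    """Best-of-500 k = 10 partition of the large sample."""
    X, _ = sample10k
    return seco.derive_reference_partition(X, 77_000, k=10, n_runs=500)


@pytest.fixture()
def two_blobs():
    """Two well separated 1-D blobs: {0, 0.1} and {10, 10.1}."""
    return np.array([[0.0], [0.1], [10.0], [10.1]])


@pytest.fixture()
def blob_data():
    """Four clean trivariate blobs, 80 points."""
    rng = np.random.default_rng(5)
    centers = np.array(
        [[0, 0, 0], [8, 0, 0], [0, 8, 0], [0, 0, 8]], dtype=float
    )
    X = np.vstack(
        [c + 0.3 * rng.standard_normal((20, 3)) for c in centers]
    )
    y = np.repeat(np.arange(4), 20)
    return X, y
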