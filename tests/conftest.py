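import numpy as np
import pytest

from mdsmc.cohort import FeatureSchema, encode_features
from mdsmc.simulate import preset_mds_like, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """n=200 six-cluster preset cohort, fixed seed."""
    return simulate(preset_mds_like(n_patients=200, seed=5))


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return encode_features(small_cohort.records, FeatureSchema())


@pytest.fixture(scope="session")
def two_blob_embedding():
    """Two far-separated Gaussian blobs in 4-d with ids, as plain arrays."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 0.3, size=(100, 4))
    b = rng.normal(5.0, 0.3, size=(100, 4))
    Z = np.vstack([a, b])
    truth = np.repeat([0, 1], 100)
    return Z, truth
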