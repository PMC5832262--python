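import numpy as np
import pytest

from proxnet.association import AssociationMatrix


def random_symmetric_matrix(seed, n=12, zero_frac=0.0, shape=2.0, scale=5.0):
    """Symmetric nonnegative association matrix with gamma dyad weights."""
    rng = np.random.default_rng(seed)
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    v = rng.gamma(shape, scale, iu.size)
    if zero_frac:
        v[rng.random(iu.size) < zero_frac] = 0.0
    W[iu, ju] = v
    W[ju, iu] = v
    return AssociationMatrix(ids=[f"C{k+1:02d}" for k in range(n)], weights=W,
                             symmetric=True)


@pytest.fixture
def sym12():
    return random_symmetric_matrix(seed=42)


@pytest.fixture
def sym12_sparse():
    return random_symmetric_matrix(seed=43, zero_frac=0.5)
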