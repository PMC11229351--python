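import numpy as np
import pytest
from scipy import sparse

from asemap.data_model import CellTypeWeights, SpatialAllelicCounts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_counts(rng, S=40, G=3, max_n=12, seed_coords=True):
    """Small random valid container for unit tests."""
    N = rng.integers(0, max_n, size=(S, G))
    Y = rng.binomial(N, 0.5)
    coords = rng.uniform(0, 1, size=(S, 2))
    return SpatialAllelicCounts(
        spot_ids=[f"s{i}" for i in range(S)],
        gene_ids=[f"g{j}" for j in range(G)],
        Y=sparse.csr_matrix(Y),
        N=sparse.csr_matrix(N),
        coords=coords,
        sample_id="test",
    )


@pytest.fixture
def small_counts(rng):
    return make_counts(rng)


@pytest.fixture
def two_ct_weights():
    def _make(spot_ids, w1):
        w1 = np.asarray(w1, dtype=float)
        W = np.column_stack([w1, 1 - w1])
        return CellTypeWeights(
            spot_ids=spot_ids, cell_types=["ct1", "ct2"], W=W
        )

    return _make
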