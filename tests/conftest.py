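import numpy as np
import pytest
import scipy.sparse as sp

from scmnmf.dataset import MultiOmicsDataset
from scmnmf.graph import AffinityGraph
from scmnmf.model import FactorModel, Hyperparameters, initialize_factors


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph(rng, n, density=0.3):
    """A random symmetric zero-diagonal affinity with weights in (0, 1]."""
    upper = np.triu(rng.random((n, n)) < density, k=1)
    W = np.zeros((n, n))
    W[upper] = rng.random(upper.sum())
    W = W + W.T
    return AffinityGraph(A=sp.csr_matrix(W), n_neighbors=0, sigma=1.0)


def random_instance(seed, n=20, M=2, feats=(12, 8), k1=3, p=5, **hp_kw):
    """A small random dataset plus matched hyperparameters and init."""
    rng = np.random.default_rng(seed)
    blocks = [rng.random((n, j)) * 5.0 for j in feats]
    data = MultiOmicsDataset(blocks=blocks)
    hp = Hyperparameters(k1=k1, p=p, **hp_kw)
    model = initialize_factors(data.blocks, hp, p, seed)
    return data, hp, model


@pytest.fixture
def small_dataset(rng):
    return MultiOmicsDataset(blocks=[rng.random((15, 6)), rng.random((15, 9))])
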