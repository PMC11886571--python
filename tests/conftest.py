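import numpy as np
import pytest

from maest import SpatialExpressionDataset, SpatialGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_ds():
    """5 spots x 4 genes with hand-set counts and grid coordinates."""
    matrix = np.array(
        [
            [0.0, 0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0, 0.0],
            [1.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 1.0, 0.0],
            [1.0, 1.0, 1.0, 1.0],
        ]
    )
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    return SpatialExpressionDataset(
        matrix=matrix,
        coords=coords,
        spot_ids=[f"s{i}" for i in range(5)],
        gene_ids=[f"g{i}" for i in range(4)],
        labels=np.array([0, 0, 0, 1, 1]),
    )


@pytest.fixture
def path3_graph():
    """3-node path graph 0-1-2 with distinct 2-d features."""
    A = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    return SpatialGraph(adjacency=A, features=X, k=1)
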