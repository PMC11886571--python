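"""Spatial k-nearest-neighbor graph construction.

Each spot is linked to its k nearest neighbors by Euclidean distance on the
slide, and the adjacency is symmetrized by union (an edge exists if either
endpoint selects the other), so every node ends with degree >= k.  k = 3 is
the default; distance ties are broken by ascending node index so the graph is
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .datasets import SpatialExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_K = 3

# above this size the O(N^2) dense construction gives way to a KD-tree
_DENSE_LIMIT = 4096


@dataclass
class SpatialGraph:
    """Undirected spatial graph G = (V, A, X).

    ``adjacency`` is a binary, symmetric, zero-diagonal N×N matrix (dense
    ndarray); ``features`` holds the preprocessed expression matrix X in the
    same row order.
    """

    adjacency: np.ndarray
    features: np.ndarray
    k: int
    spot_ids: list | None = None

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = A
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != A.shape[0]:
            raise ValueError("features row count must equal number of nodes")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def n_components(self) -> int:
        n, _ = connected_components(sp.csr_matrix(self.adjacency), directed=False)
        return int(n)

    def edge_list(self) -> np.ndarray:
        """Upper-triangle (i, j) pairs, i < j."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        on = self.adjacency[iu, ju] > 0
        return np.column_stack([iu[on], ju[on]])


def _knn_indices_dense(coords: np.ndarray, k: int) -> np.ndarray:
    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    # stable argsort on distance: equal distances resolve to the lower index
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def _knn_indices_tree(coords: np.ndarray, k: int) -> np.ndarray:
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    out = np.empty((coords.shape[0], k), dtype=int)
    for i in range(coords.shape[0]):
        row = [j for j in idx[i] if j != i][:k]
        out[i] = row
    return out


def build_knn_graph(coords: np.ndarray, k: int = DEFAULT_K) -> np.ndarray:
    """Binary symmetric k-NN adjacency from 2D coordinates.

    Node i is linked to its k nearest Euclidean neighbors (self excluded);
    the result is the symmetric union, with ties broken by ascending index.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("coords must be 2-dimensional (N x 2)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    N = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if N <= k:
        raise ValueError(f"need more than k={k} points, got N={N}")
    if N <= _DENSE_LIMIT:
        nbrs = _knn_indices_dense(coords, k)
    else:
        nbrs = _knn_indices_tree(coords, k)
    A = np.zeros((N, N))
    rows = np.repeat(np.arange(N), k)
    A[rows, nbrs.ravel()] = 1.0
    A = np.maximum(A, A.T)  # union symmetrization
    np.fill_diagonal(A, 0.0)
    return A


def assemble_graph(ds: SpatialExpressionDataset, k: int = DEFAULT_K) -> SpatialGraph:
    """Build the spatial graph for a (preprocessed) dataset.

    Emits a warning if the k-NN graph is disconnected — clustering still
    proceeds, but multi-hop propagation cannot cross components.
    """
    A = build_knn_graph(ds.coords, k=k)
    graph = SpatialGraph(
        adjacency=A,
        features=ds.dense_matrix(),
        k=k,
        spot_ids=list(ds.spot_ids),
    )
    ncomp = graph.n_components()
    if ncomp > 1:
        logger.warning("spatial k-NN graph has %d connected components", ncomp)
    return graph


def write_edge_list(graph: SpatialGraph, path: str) -> None:
    """Export the adjacency as a TSV edge list (i, j), i < j."""
    np.savetxt(path, graph.edge_list(), fmt="%d", delimiter="\t", header="i\tj")
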