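"""Spatial-domain assignment by clustering the fused embeddings.

The default is a Gaussian-mixture model with a shared (tied) covariance
matrix fit by EM — the in-language analogue of model-based clustering with an
equal-covariance family — initialized from deterministic k-means++ and run as
the best of 10 restarts by likelihood.  k-means and Louvain community
detection are available as alternatives.  The number of clusters is fixed by
the caller (for annotated data, set it to the number of annotated domains).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_GMM_RETRIES = 3


@dataclass
class DomainAssignment:
    """Hard labels plus soft responsibilities for every spot."""

    labels: np.ndarray
    responsibilities: np.ndarray
    n_clusters: int
    method: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.responsibilities = np.asarray(self.responsibilities, dtype=float)
        if self.responsibilities.shape != (len(self.labels), self.n_clusters):
            raise ValueError("responsibilities must be N x n_clusters")
        if not np.allclose(self.responsibilities.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("responsibility rows must sum to 1")


def cluster_gmm(
    H_out: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    covariance_type: str = "tied",
) -> DomainAssignment:
    """EM Gaussian mixture on the embeddings; labels = argmax responsibility."""
    from sklearn.mixture import GaussianMixture

    H_out = np.asarray(H_out, dtype=float)
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if H_out.shape[0] <= n_clusters:
        raise ValueError("need more points than clusters")
    last_err: Exception | None = None
    for attempt in range(_GMM_RETRIES):
        try:
            gmm = GaussianMixture(
                n_components=n_clusters,
                covariance_type=covariance_type,
                n_init=10,
                init_params="kmeans",  # full k-means (k-means++ seeded) start
                random_state=seed + attempt,
                max_iter=300,
                reg_covar=1e-6,
            ).fit(H_out)
            resp = gmm.predict_proba(H_out)
            labels = np.argmax(resp, axis=1)
            if len(np.unique(labels)) < n_clusters:
                raise RuntimeError("EM converged with an empty component")
            return DomainAssignment(labels, resp, n_clusters, "gmm")
        except Exception as err:  # degenerate EM: re-init with a shifted seed
            last_err = err
    raise RuntimeError(
        f"GMM failed after {_GMM_RETRIES} re-initializations: {last_err}"
    )


def cluster_kmeans(H_out: np.ndarray, n_clusters: int, seed: int = 0) -> DomainAssignment:
    """Lloyd iterations with k-means++ init; one-hot responsibilities."""
    from sklearn.cluster import KMeans

    H_out = np.asarray(H_out, dtype=float)
    labels = (
        KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        .fit(H_out)
        .labels_
    )
    resp = np.zeros((len(labels), n_clusters))
    resp[np.arange(len(labels)), labels] = 1.0
    return DomainAssignment(labels, resp, n_clusters, "kmeans")


def cluster_louvain(
    H_out: np.ndarray,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
) -> DomainAssignment:
    """Louvain modularity communities on a k-NN similarity graph of the
    embeddings; the number of domains is emergent."""
    import networkx as nx

    from .graph import build_knn_graph

    H_out = np.asarray(H_out, dtype=float)
    k = min(n_neighbors, H_out.shape[0] - 1)
    A = build_knn_graph(H_out, k=k)
    G = nx.from_numpy_array(A)
    communities = nx.community.louvain_communities(
        G, resolution=resolution, seed=seed
    )
    labels = np.empty(H_out.shape[0], dtype=int)
    for c, members in enumerate(sorted(communities, key=min)):
        labels[list(members)] = c
    n_clusters = len(communities)
    resp = np.zeros((len(labels), n_clusters))
    resp[np.arange(len(labels)), labels] = 1.0
    return DomainAssignment(labels, resp, n_clusters, "louvain")
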