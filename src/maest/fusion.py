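"""Multi-hop propagation and one-hop/multi-hop fusion.

After training, the one-hop embedding H is propagated through n rounds of a
parameter-free GCN-style aggregator (symmetrically normalized adjacency with
self-loops) to capture longer-range structure, then added back to H.  The
plain propagation smooths features toward neighborhood averages (eventually
over-smoothing for large n), while the sum H + H_D keeps node-specific
detail; n = 3 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_HOPS = 3


@dataclass
class EmbeddingSet:
    """One-hop (H), multi-hop (H_D), and fused (H_out = H + H_D) embeddings."""

    H: np.ndarray
    H_D: np.ndarray
    H_out: np.ndarray

    def __post_init__(self):
        for name, v in (("H", self.H), ("H_D", self.H_D), ("H_out", self.H_out)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
        if not np.allclose(self.H_out, self.H + self.H_D):
            raise ValueError("H_out must equal H + H_D")


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """D^{-1/2} (A + I) D^{-1/2} with D the degree matrix of A + I."""
    A_hat = np.asarray(adjacency, dtype=float) + np.eye(adjacency.shape[0])
    d = A_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


def mean_neighbor_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Row-stochastic alternative: D^{-1} (A + I)."""
    A_hat = np.asarray(adjacency, dtype=float) + np.eye(adjacency.shape[0])
    return A_hat / A_hat.sum(axis=1, keepdims=True)


def multi_hop(
    H: np.ndarray,
    adjacency: np.ndarray,
    n: int = DEFAULT_HOPS,
    aggregator: str = "gcn",
) -> np.ndarray:
    """H_D = propagate H for n hops with a parameter-free aggregator."""
    if n < 1:
        raise ValueError("number of hops must be >= 1")
    if aggregator == "gcn":
        P = normalized_adjacency(adjacency)
    elif aggregator == "mean":
        P = mean_neighbor_adjacency(adjacency)
    else:
        raise ValueError(f"unknown aggregator: {aggregator!r}")
    H_D = np.asarray(H, dtype=float)
    for _ in range(n):
        H_D = P @ H_D
    return H_D


def fuse(H: np.ndarray, H_D: np.ndarray) -> np.ndarray:
    """Elementwise sum H_out = H + H_D."""
    H = np.asarray(H, dtype=float)
    H_D = np.asarray(H_D, dtype=float)
    if H.shape != H_D.shape:
        raise ValueError(f"shape mismatch: {H.shape} vs {H_D.shape}")
    return H + H_D


def fused_embeddings(
    H: np.ndarray, adjacency: np.ndarray, n: int = DEFAULT_HOPS, aggregator: str = "gcn"
) -> EmbeddingSet:
    H_D = multi_hop(H, adjacency, n=n, aggregator=aggregator)
    return EmbeddingSet(H=np.asarray(H, dtype=float), H_D=H_D, H_out=fuse(H, H_D))
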