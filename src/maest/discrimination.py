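"""Contrastive node discrimination against a feature-shuffled graph.

A corrupted view G' keeps the spatial topology but randomly permutes the
expression rows across spots.  Both views pass through the shared encoder and
a projection head; each projected node embedding is scored against the global
summary of the *original* graph (sigmoid of the mean projected embedding,
deep-graph-infomax style).  A binary cross-entropy loss pushes original-graph
scores toward 1 and shuffled-graph scores toward 0, which keeps embeddings
informative about graph-level context and prevents feature collapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .nn import sigmoid

SCORE_EPS = 1e-7


@dataclass
class ShuffledGraph:
    """The corrupted view: same adjacency object, row-permuted features."""

    adjacency: np.ndarray
    features: np.ndarray
    permutation: np.ndarray
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class DiscriminationScores:
    """Per-node probabilities of 'comes from the original graph'."""

    g: np.ndarray
    g_prime: np.ndarray

    def __post_init__(self):
        for name, v in (("g", self.g), ("g_prime", self.g_prime)):
            v = np.asarray(v)
            if isinstance(v, np.ndarray) and v.dtype != object:
                if np.any(v <= 0) or np.any(v >= 1):
                    raise ValueError(f"{name} scores must lie strictly in (0, 1)")


def shuffle_graph(graph, seed: int = 0, permutation=None) -> ShuffledGraph:
    """Permute feature rows uniformly at random; topology untouched."""
    n = graph.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes to shuffle")
    if permutation is None:
        permutation = np.random.default_rng(seed).permutation(n)
    else:
        permutation = np.asarray(permutation, dtype=int)
        if sorted(permutation) != list(range(n)):
            raise ValueError("not a permutation of 0..N-1")
    return ShuffledGraph(
        adjacency=graph.adjacency,
        features=np.asarray(graph.features)[permutation],
        permutation=permutation,
        seed=seed,
    )


def summary_scores(Z, Z_prime, clamp: bool = True):
    """Score both views against the original graph's global summary.

    s = sigmoid(mean over rows of Z); g_i = sigmoid(z_i · s) and
    g'_i = sigmoid(z'_i · s).  Using the original summary as the single
    anchor makes positives (original nodes) and negatives (shuffled nodes)
    directly comparable.  Scores are clamped to [eps, 1-eps].
    """
    s = sigmoid(anp.mean(Z, axis=0))
    g = sigmoid(anp.dot(Z, s))
    g_prime = sigmoid(anp.dot(Z_prime, s))
    if clamp:
        g = anp.clip(g, SCORE_EPS, 1.0 - SCORE_EPS)
        g_prime = anp.clip(g_prime, SCORE_EPS, 1.0 - SCORE_EPS)
    if isinstance(g, np.ndarray):
        return DiscriminationScores(g=g, g_prime=g_prime)
    # traced values during training: skip the container's range validation
    scores = DiscriminationScores.__new__(DiscriminationScores)
    scores.g, scores.g_prime = g, g_prime
    return scores


def discrimination_loss(scores: DiscriminationScores):
    """Binary cross-entropy over the two views (natural log):

    L = (1/N) * sum_i [ log(1/g_i) + log(1/(1 - g'_i)) ].

    Equals 2·ln 2 when every score sits at chance level 0.5.
    """
    g, gp = scores.g, scores.g_prime
    return anp.mean(-anp.log(g)) + anp.mean(-anp.log(1.0 - gp))
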