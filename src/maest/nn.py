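"""Neural building blocks: graph-attention encoder/decoder, projector, head.

The representation learner is deliberately shallow: the encoder f_E and the
decoder f_D are each exactly one graph-attention layer, so every node gathers
information only from its one-hop neighborhood (plus itself).  Keeping the
receptive field this small preserves sharp spatial-domain boundaries and
avoids over-smoothing; longer-range structure is added later by a
parameter-free multi-hop aggregator (see :mod:`maest.fusion`).

All forwards are written against ``autograd.numpy`` so the same code serves
both plain evaluation and gradient-based training (full-batch, dense N×N
attention — suitable for desk-scale graphs).
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive

DEFAULT_LATENT_DIM = 64
DEFAULT_HEAD_DIM = 32
LEAKY_SLOPE = 0.2  # attention-score LeakyReLU slope

# ---------------------------------------------------------------------------
# activations
#
# elu/leaky_relu are registered as autograd primitives with closed-form VJPs:
# full-batch training touches dense N×N score matrices every epoch, and
# fusing the elementwise pieces keeps the tape (and the epoch time) small.
# ---------------------------------------------------------------------------


@primitive
def elu(x):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, np.exp(np.minimum(x, 0.0)) - 1.0)


defvjp(elu, lambda ans, x: lambda g: g * np.where(np.asarray(x) > 0, 1.0, ans + 1.0))


@primitive
def leaky_relu(x, slope=LEAKY_SLOPE):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, slope * x)


defvjp(
    leaky_relu,
    lambda ans, x, slope=LEAKY_SLOPE: lambda g: g
    * np.where(np.asarray(x) > 0, 1.0, slope),
)


def identity(x):
    return x


ACTIVATIONS = {"elu": elu, "relu": lambda x: anp.maximum(x, 0.0), "identity": identity}


def sigmoid(x):
    x = anp.clip(x, -60.0, 60.0)
    return 1.0 / (1.0 + anp.exp(-x))


# ---------------------------------------------------------------------------
# fused attention kernels
# ---------------------------------------------------------------------------


@primitive
def _pair_scores(s_src, s_dst, slope=LEAKY_SLOPE):
    """LeakyReLU(s_src_i + s_dst_j) over all ordered pairs (i, j)."""
    x = np.asarray(s_src)[..., :, None] + np.asarray(s_dst)[..., None, :]
    return np.where(x > 0, x, slope * x)


def _pair_scores_vjp_src(ans, s_src, s_dst, slope=LEAKY_SLOPE):
    deriv = np.where(ans > 0, 1.0, slope)  # sign(ans) == sign(x) for slope > 0
    return lambda g: (g * deriv).sum(axis=-1)


def _pair_scores_vjp_dst(ans, s_src, s_dst, slope=LEAKY_SLOPE):
    deriv = np.where(ans > 0, 1.0, slope)
    return lambda g: (g * deriv).sum(axis=-2)


defvjp(_pair_scores, _pair_scores_vjp_src, _pair_scores_vjp_dst)


@primitive
def _attention_softmax(scores, mask):
    """Row-wise softmax restricted to mask > 0 (zero elsewhere)."""
    s = np.where(mask > 0, np.asarray(scores, dtype=float), -1e30)
    s = s - s.max(axis=-1, keepdims=True)
    w = np.exp(s) * mask
    return w / w.sum(axis=-1, keepdims=True)


def _attention_softmax_vjp(ans, scores, mask):
    def vjp(g):
        inner = (g * ans).sum(axis=-1, keepdims=True)
        return ans * (g - inner)

    return vjp


defvjp(_attention_softmax, _attention_softmax_vjp, argnums=[0])


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class EncoderParams:
    """Weights of one graph-attention layer mapping d_in -> d_out.

    ``weights`` holds ``W`` (d_in × d_out) and the per-head attention score
    vectors ``a_src``/``a_dst`` (d_out each).  One attention head.
    """

    weights: dict
    d_in: int
    d_out: int
    nonlinearity: str = "elu"

    def activation(self):
        return ACTIVATIONS[self.nonlinearity]


@dataclass
class ProjectorParams:
    """A 2-layer MLP (ELU hidden activation, linear output)."""

    weights: dict  # W1, b1, W2, b2
    d_in: int
    d_out: int


@dataclass
class ModelParams:
    """Everything trainable: shared encoder, decoder, projector g, head p."""

    encoder: EncoderParams
    decoder: EncoderParams
    projector_g: ProjectorParams
    head_p: ProjectorParams

    def as_dict(self) -> dict:
        return {
            "encoder": self.encoder.weights,
            "decoder": self.decoder.weights,
            "projector_g": self.projector_g.weights,
            "head_p": self.head_p.weights,
        }

    def set_from_dict(self, d: dict) -> None:
        self.encoder.weights = d["encoder"]
        self.decoder.weights = d["decoder"]
        self.projector_g.weights = d["projector_g"]
        self.head_p.weights = d["head_p"]


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + (shape[1] if len(shape) > 1 else 1)))
    return rng.uniform(-limit, limit, size=shape)


def init_gat_params(
    rng: np.random.Generator, d_in: int, d_out: int, nonlinearity: str = "elu"
) -> EncoderParams:
    weights = {
        "W": _glorot(rng, (d_in, d_out)),
        "a_src": _glorot(rng, (d_out,)),
        "a_dst": _glorot(rng, (d_out,)),
    }
    return EncoderParams(weights, d_in, d_out, nonlinearity)


def init_mlp_params(rng: np.random.Generator, d_in: int, d_hidden: int, d_out: int) -> ProjectorParams:
    weights = {
        "W1": _glorot(rng, (d_in, d_hidden)),
        "b1": np.zeros(d_hidden),
        "W2": _glorot(rng, (d_hidden, d_out)),
        "b2": np.zeros(d_out),
    }
    return ProjectorParams(weights, d_in, d_out)


def init_model_params(
    d_in: int,
    latent_dim: int = DEFAULT_LATENT_DIM,
    head_dim: int = DEFAULT_HEAD_DIM,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> ModelParams:
    if head_dim > latent_dim:
        raise ValueError("head output width must not exceed the latent width")
    rng = np.random.default_rng(seed) if rng is None else rng
    return ModelParams(
        encoder=init_gat_params(rng, d_in, latent_dim, "elu"),
        decoder=init_gat_params(rng, latent_dim, d_in, "identity"),
        projector_g=init_mlp_params(rng, latent_dim, latent_dim, latent_dim),
        head_p=init_mlp_params(rng, latent_dim, latent_dim, head_dim),
    )


# ---------------------------------------------------------------------------
# functional forwards (autograd-traceable)
# ---------------------------------------------------------------------------


def attention_mask(adjacency: np.ndarray) -> np.ndarray:
    """Adjacency plus self-loops, as a float {0,1} mask.

    Self-loops are added here so every node attends to itself even though the
    graph adjacency itself has a zero diagonal.
    """
    A = np.asarray(adjacency, dtype=float)
    return np.minimum(A + np.eye(A.shape[0]), 1.0)


def gat_forward(mask: np.ndarray, X, weights: dict, activation=elu):
    """One masked attention aggregation round.

    score(i<-j) = LeakyReLU(a_src·h_i + a_dst·h_j) for j in N(i) ∪ {i},
    softmax-normalized over each row; output_i = act(Σ_j α_ij h_j) with
    h = X W.  ``X`` may carry leading batch dimensions (V, N, d_in) to push
    several feature views through the same weights in one call.
    """
    h = anp.matmul(X, weights["W"])
    s_src = anp.sum(h * weights["a_src"], axis=-1)
    s_dst = anp.sum(h * weights["a_dst"], axis=-1)
    alpha = _attention_softmax(_pair_scores(s_src, s_dst), mask)
    return activation(anp.matmul(alpha, h))


def attention_coefficients(mask: np.ndarray, X: np.ndarray, weights: dict) -> np.ndarray:
    """The row-stochastic attention matrix α (diagnostics / tests)."""
    h = X @ weights["W"]
    s_src = h @ weights["a_src"]
    s_dst = h @ weights["a_dst"]
    return _attention_softmax(_pair_scores(s_src, s_dst), mask)


def mlp_forward(X, weights: dict):
    hidden = elu(anp.dot(X, weights["W1"]) + weights["b1"])
    return anp.dot(hidden, weights["W2"]) + weights["b2"]


# ---------------------------------------------------------------------------
# op-level wrappers on SpatialGraph
# ---------------------------------------------------------------------------


def _check_finite(out: np.ndarray, what: str) -> np.ndarray:
    if isinstance(out, np.ndarray) and not np.all(np.isfinite(out)):
        raise FloatingPointError(f"{what} produced non-finite values")
    return out


def encode(graph, features, params: EncoderParams):
    """One-hop embeddings H = f_E(A, X)."""
    if features.shape[0] != graph.n_nodes:
        raise ValueError("features row count must equal number of nodes")
    out = gat_forward(attention_mask(graph.adjacency), features, params.weights, params.activation())
    return _check_finite(out, "encoder")


def decode(graph, latent, params: EncoderParams):
    """Reconstruction Z = f_D(A, H), same attention mechanism d -> d_in."""
    if latent.shape[1] != params.d_in:
        raise ValueError("latent width does not match decoder input width")
    out = gat_forward(attention_mask(graph.adjacency), latent, params.weights, params.activation())
    return _check_finite(out, "decoder")


def project_regularizer(latent, params: ProjectorParams):
    """Projector g: maps embeddings into the regularization target space."""
    return _check_finite(mlp_forward(latent, params.weights), "projector g")


def project_head(latent, params: ProjectorParams):
    """Projection head p: compresses embeddings to width d' for contrast."""
    return _check_finite(mlp_forward(latent, params.weights), "head p")
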