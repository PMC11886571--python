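"""Full-batch self-supervised training of the shared encoder.

Every epoch draws a fresh corruption plan (input mask, K latent re-masks, a
feature permutation for the contrastive view), runs the masked-reconstruction
and node-discrimination branches through the shared encoder, and takes one
Adam step on the combined objective

    L = L_recon + lambda1 * L_reg + lambda2 * L_discri

with defaults lambda1 = 0.2, lambda2 = 0.02, learning rate 1e-3 and 900
epochs.  All randomness flows from ``TrainingConfig.seed``, so runs are
bit-reproducible.  Gradients come from reverse-mode autodiff over the numpy
forwards (autograd); graphs of a few thousand spots train in minutes on one
CPU core.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.tracer import getval

from . import masking
from .discrimination import discrimination_loss, summary_scores
from .masking import MaskPlan, draw_mask_plan, mask_features
from .nn import (
    DEFAULT_HEAD_DIM,
    DEFAULT_LATENT_DIM,
    ModelParams,
    attention_mask,
    gat_forward,
    init_model_params,
    mlp_forward,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """All hyperparameters of the representation learner."""

    lambda1: float = 0.2
    lambda2: float = 0.02
    learning_rate: float = 0.001
    epochs: int = 900
    mask_rate: float = 0.5
    remask_rate: float | None = None  # defaults to mask_rate
    remask_views: int = 3
    gamma: float = 2.0
    latent_dim: int = DEFAULT_LATENT_DIM
    head_dim: int = DEFAULT_HEAD_DIM
    seed: int = 0
    device: str = "cpu"
    weight_decay: float = 0.0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda coefficients must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must lie in [0, 1]")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.device != "cpu":
            raise ValueError("only device='cpu' is supported")

    @property
    def effective_remask_rate(self) -> float:
        return self.mask_rate if self.remask_rate is None else self.remask_rate

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown training config key(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class TrainingTrace:
    """Per-epoch loss components."""

    total: list = field(default_factory=list)
    recon: list = field(default_factory=list)
    reg: list = field(default_factory=list)
    discri: list = field(default_factory=list)

    def append(self, total, recon, reg, discri):
        for name, v in (("total", total), ("recon", recon), ("reg", reg), ("discri", discri)):
            if not np.isfinite(v):
                raise FloatingPointError(f"non-finite {name} loss recorded")
        self.total.append(float(total))
        self.recon.append(float(recon))
        self.reg.append(float(reg))
        self.discri.append(float(discri))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.total) + 1),
                "total": self.total,
                "recon": self.recon,
                "reg": self.reg,
                "discri": self.discri,
            }
        )


def total_loss(l_recon, l_reg, l_discri, cfg: TrainingConfig):
    """Combined objective: L_recon + lambda1 * L_reg + lambda2 * L_discri."""
    return l_recon + cfg.lambda1 * l_reg + cfg.lambda2 * l_discri


# ---------------------------------------------------------------------------
# loss assembly (works on plain arrays and on autograd-traced weight dicts)
# ---------------------------------------------------------------------------


def _forward_losses(weights, model: ModelParams, mask, X, plan: MaskPlan, perm, cfg):
    enc_act = model.encoder.activation()
    dec_act = model.decoder.activation()

    # one batched encoder pass over the three feature views
    X_tilde = mask_features(X, plan)
    H_all = gat_forward(mask, np.stack([X_tilde, X, X[perm]]), weights["encoder"], enc_act)
    H_masked, H_full, H_prime = H_all[0], H_all[1], H_all[2]

    # reconstruction over K re-masked views of the masked-graph latent
    recon_plan = plan
    if plan.masked_nodes.size == 0:
        # no input masking: plain autoencoder arm, reconstruct every node
        recon_plan = MaskPlan(
            0.0, np.arange(X.shape[0]), plan.remask_views, plan.remask_sets, plan.seed
        )
    keep = np.ones((plan.remask_views, X.shape[0], 1))
    for j, idx in enumerate(plan.remask_sets):
        keep[j, np.asarray(idx, dtype=int), 0] = 0.0
    Z_all = gat_forward(mask, H_masked[None, :, :] * keep, weights["decoder"], dec_act)
    ridx = recon_plan.masked_nodes
    l_recon = (
        anp.sum(masking._row_sce(X[ridx], Z_all[:, ridx, :], cfg.gamma)) / ridx.size
    )

    # regularization toward the clean-graph target (target branch detached)
    proj = type(model.projector_g)(
        weights["projector_g"], model.projector_g.d_in, model.projector_g.d_out
    )
    l_reg = masking.regularization_loss(H_masked, H_full, proj, cfg.gamma)

    # node discrimination against the feature-shuffled view
    Z = mlp_forward(H_full, weights["head_p"])
    Z_prime = mlp_forward(H_prime, weights["head_p"])
    l_discri = discrimination_loss(summary_scores(Z, Z_prime))

    return l_recon, l_reg, l_discri


def _adam_step(params, grads, state, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    state["t"] += 1
    t = state["t"]
    for group, g in grads.items():
        for key, gval in g.items():
            m = state["m"][group][key]
            v = state["v"][group][key]
            m *= beta1
            m += (1 - beta1) * gval
            v *= beta2
            v += (1 - beta2) * gval**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            params[group][key] = params[group][key] - lr * mhat / (np.sqrt(vhat) + eps)
    return params


def train(graph, cfg: TrainingConfig, model: ModelParams | None = None):
    """Optimize the model on one spatial graph.

    Returns ``(model, trace, H)`` where H = f_E(A, X) is the final one-hop
    embedding of the clean graph.  Deterministic given ``cfg.seed``.
    """
    X = np.asarray(graph.features, dtype=float)
    N, d_in = X.shape
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = init_model_params(
            d_in, latent_dim=cfg.latent_dim, head_dim=cfg.head_dim, rng=rng
        )
    mask = attention_mask(graph.adjacency)
    params = model.as_dict()
    adam_state = {
        "t": 0,
        "m": {g: {k: np.zeros_like(v) for k, v in w.items()} for g, w in params.items()},
        "v": {g: {k: np.zeros_like(v) for k, v in w.items()} for g, w in params.items()},
    }
    trace = TrainingTrace()

    parts_sink: list = []

    def objective(weights, plan, perm):
        l_recon, l_reg, l_discri = _forward_losses(weights, model, mask, X, plan, perm, cfg)
        parts_sink.append((getval(l_recon), getval(l_reg), getval(l_discri)))
        return total_loss(l_recon, l_reg, l_discri, cfg)

    grad_fn = value_and_grad(objective)

    for epoch in range(cfg.epochs):
        plan = draw_mask_plan(
            N, cfg.mask_rate, cfg.remask_views, rng, cfg.effective_remask_rate
        )
        perm = rng.permutation(N)
        parts_sink.clear()
        loss_val, grads = grad_fn(params, plan, perm)
        if not np.isfinite(loss_val):
            logger.error("non-finite loss at epoch %d; aborting", epoch + 1)
            logger.error("trace so far:\n%s", trace.to_frame().tail(10))
            raise FloatingPointError(f"training diverged at epoch {epoch + 1}")
        trace.append(loss_val, *parts_sink[-1])
        if cfg.weight_decay:
            for g, w in params.items():
                for k in w:
                    grads[g][k] = grads[g][k] + cfg.weight_decay * w[k]
        params = _adam_step(params, grads, adam_state, cfg.learning_rate)

    model.set_from_dict(params)
    H = gat_forward(mask, X, params["encoder"], model.encoder.activation())
    return model, trace, np.asarray(H)
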