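"""Masked feature reconstruction: mask plans, re-masking, scaled cosine losses.

Self-supervision works by hiding a fraction of spots (their whole expression
row is replaced by zeros), encoding the corrupted graph, and asking the
decoder to recover the hidden rows.  Before each decode the latent matrix is
corrupted again with K independent random re-masks, so the decoder must
reconstruct from diverse partial views.  Reconstruction quality is measured
with the scaled cosine error (1 - cos(x, z))^gamma, which down-weights rows
that are already easy once gamma > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive


@dataclass
class ReconLossConfig:
    """Loss coefficients: gamma (>= 1) scales the cosine error; lambda1 and
    lambda2 weight the regularization and discrimination terms."""

    gamma: float = 2.0
    lambda1: float = 0.2
    lambda2: float = 0.02

    def __post_init__(self):
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda coefficients must be non-negative")


@dataclass
class MaskPlan:
    """One epoch's corruption: the masked node set and K re-mask sets.

    ``masked_nodes`` has exactly round(mask_rate * N) entries.  Each re-mask
    set is drawn independently and uniformly — every node is equally likely
    regardless of whether it was masked at the input.
    """

    mask_rate: float
    masked_nodes: np.ndarray
    remask_views: int
    remask_sets: list = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must lie in [0, 1]")
        if len(self.remask_sets) != self.remask_views:
            raise ValueError("need one re-mask set per view")
        self.masked_nodes = np.asarray(self.masked_nodes, dtype=int)


def n_masked(mask_rate: float, n_nodes: int) -> int:
    return int(np.rint(mask_rate * n_nodes))


def draw_mask_plan(
    n_nodes: int,
    mask_rate: float,
    remask_views: int,
    rng: np.random.Generator,
    remask_rate: float | None = None,
    seed: int | None = None,
) -> MaskPlan:
    """Sample a fresh :class:`MaskPlan` (uniform without replacement)."""
    if remask_rate is None:
        remask_rate = mask_rate
    masked = rng.choice(n_nodes, size=n_masked(mask_rate, n_nodes), replace=False)
    remasks = [
        rng.choice(n_nodes, size=n_masked(remask_rate, n_nodes), replace=False)
        for _ in range(remask_views)
    ]
    return MaskPlan(mask_rate, np.sort(masked), remask_views, remasks, seed)


def mask_features(X: np.ndarray, plan: MaskPlan) -> np.ndarray:
    """Zero out the full feature row of every masked node."""
    if plan.masked_nodes.size and (
        plan.masked_nodes.min() < 0 or plan.masked_nodes.max() >= X.shape[0]
    ):
        raise ValueError("masked_nodes out of range")
    Xt = np.array(X, copy=True)
    Xt[plan.masked_nodes] = 0.0
    return Xt


def remask_latent(H, plan: MaskPlan, view: int):
    """Zero the latent rows of re-mask set ``view`` (1-based)."""
    if not 1 <= view <= plan.remask_views:
        raise ValueError(f"view must be in 1..{plan.remask_views}")
    idx = np.asarray(plan.remask_sets[view - 1], dtype=int)
    keep = np.ones(H.shape[0])
    keep[idx] = 0.0
    return H * keep[:, None]  # autograd-safe row zeroing


# ---------------------------------------------------------------------------
# scaled cosine error
# ---------------------------------------------------------------------------


@primitive
def _row_sce(X, Z, gamma: float):
    """Per-row scaled cosine error (fused autograd primitive).

    Supports leading batch dimensions (views).  Rows where either vector has
    zero norm contribute 1^gamma (the cosine is taken as 0), keeping the
    loss and its gradient finite on degenerate inputs.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    cos, _ = _row_cosine(X, Z)
    return (1.0 - cos) ** gamma


def _row_cosine(X, Z):
    xsq = (X * X).sum(axis=-1)
    zsq = (Z * Z).sum(axis=-1)
    ok = (xsq > 0) & (zsq > 0)
    inv = 1.0 / np.sqrt(np.where(ok, xsq * zsq, 1.0))
    cos = np.where(ok, (X * Z).sum(axis=-1) * inv, 0.0)
    return cos, (ok, inv, xsq, zsq)


def _row_sce_vjp(wrt_second):
    def vjp_maker(ans, X, Z, gamma):
        X = np.asarray(X, dtype=float)
        Z = np.asarray(Z, dtype=float)
        cos, (ok, inv, xsq, zsq) = _row_cosine(X, Z)
        a, b, bsq = (X, Z, zsq) if wrt_second else (Z, X, xsq)
        # d(1-cos)^g / db = -g (1-cos)^(g-1) * (a*inv - cos*b/bsq)
        scale = -gamma * (1.0 - cos) ** (gamma - 1.0)
        dcos_db = np.where(
            ok[..., None],
            a * inv[..., None] - cos[..., None] * b / np.where(ok, bsq, 1.0)[..., None],
            0.0,
        )
        return lambda g: (g * scale)[..., None] * dcos_db

    return vjp_maker


defvjp(_row_sce, _row_sce_vjp(False), _row_sce_vjp(True))


def scaled_cosine_error(x: np.ndarray, z: np.ndarray, gamma: float = 2.0) -> float:
    """(1 - x·z / (||x|| ||z||))^gamma for a single pair of vectors."""
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.shape != z.shape:
        raise ValueError("x and z must have the same length")
    if np.linalg.norm(x) == 0 or np.linalg.norm(z) == 0:
        warnings.warn("zero-norm vector in scaled cosine error; contributing 1^gamma")
        return 1.0
    return float(_row_sce(x[None, :], z[None, :], gamma)[0])


def reconstruction_loss(X, Z_views: list, plan: MaskPlan, gamma: float = 2.0):
    """Masked-node reconstruction error aggregated over K re-mask views.

    L_recon = (1/|V~|) * sum_j sum_{i in V~} (1 - cos(x_i, z_i^(j)))^gamma.
    The sum runs only over the originally masked set; normalization is by
    |V~| alone, so the loss grows linearly with the number of views K.
    """
    idx = plan.masked_nodes
    if idx.size == 0:
        raise ValueError("mask plan has no masked nodes: nothing to reconstruct")
    total = 0.0
    for Z in Z_views:
        total = total + anp.sum(_row_sce(X[idx], Z[idx], gamma))
    return total / idx.size


def regularization_loss(H_masked, H_full, projector, gamma: float = 2.0):
    """Early-training stabilizer: make the projected masked-graph embedding
    predict the projected clean-graph embedding.

    Z_bar = g(H_masked) is compared with the target X_bar = g(H_full) using
    the mean scaled cosine error.  The target branch is detached: no
    gradient flows through H_full or through g's weights on that side, so
    X_bar acts as a fixed target for the current step.
    """
    from autograd.tracer import getval

    from .nn import mlp_forward, project_regularizer

    z_bar = project_regularizer(H_masked, projector)
    frozen = {k: getval(v) for k, v in projector.weights.items()}
    x_bar = mlp_forward(getval(H_full), frozen)
    return anp.mean(_row_sce(x_bar, z_bar, gamma))
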