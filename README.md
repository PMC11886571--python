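# maest

Spatial-domain identification for spatial transcriptomics (ST) with a graph
masked autoencoder and contrastive node discrimination.

A core task in ST analysis is partitioning the capture spots of a tissue
section into *spatial domains* — coherent regions whose spots share
expression programs.  Methods that cluster expression alone produce spatially
fragmented domains; this package embeds each spot with a self-supervised
graph neural model that combines expression with spatial context, then
clusters the embeddings.  It is aimed at analysts working with spot- or
cell-resolved ST data (Visium, Stereo-seq, Slide-seq and similar) at desk
scale, and at methods developers who want a compact, fully deterministic
reference implementation with a built-in synthetic test-bed.

## The model

Spots form a graph `G = (V, A, X)`: `A` is the union-symmetrized k-nearest-
neighbor adjacency over spot coordinates (Euclidean, `k = 3` by default) and
`X` the preprocessed expression matrix (outlier-spot removal, per-spot
total-count normalization, `log1p`, top highly variable genes).  A shared
single-layer graph-attention encoder `f_E` is trained on two tasks:

**Masked feature reconstruction.**  A random subset `Ṽ ⊂ V` of spots
(default 50%) has its feature rows zeroed; the corrupted graph is encoded to
`H = f_E(A, X̃)`.  Before decoding, `H` is re-masked `K` times (default
`K = 3`) with fresh uniform row subsets, and a single-layer attention decoder
`f_D` must recover the original features from each partial view:

    L_recon = (1/|Ṽ|) Σ_{j=1..K} Σ_{i∈Ṽ} (1 − cos(x_i, z_i^(j)))^γ,

the *scaled cosine error* with `γ = 2`.  A regularization head stabilizes
early training: an MLP projector `g` maps both the masked-graph embedding
and the clean-graph embedding into a common space, and

    L_reg = (1/N) Σ_i (1 − cos(x̄_i, z̄_i))^γ

pulls the former toward the latter (the clean-graph target is treated as a
constant; no gradient flows through it).

**Node discrimination.**  A corrupted view `G′` keeps `A` but permutes the
rows of `X`.  Both views pass through `f_E` and a projection head `p`; each
projected embedding is scored against the clean graph's global summary
`s = σ(mean_i z_i)` as `g_i = σ(z_i·s)`, `g′_i = σ(z′_i·s)`, and a binary
cross-entropy separates the two views:

    L_discri = (1/N) Σ_i [ log 1/g_i + log 1/(1 − g′_i) ].

The combined objective is

    L = L_recon + λ1·L_reg + λ2·L_discri,   λ1 = 0.2, λ2 = 0.02,

optimized full-batch with Adam (learning rate 0.001, 900 epochs by default).

**Fusion and clustering.**  After training, the one-hop embedding
`H = f_E(A, X)` is propagated `n = 3` steps through the parameter-free
GCN-style operator `Â = D̂^{-1/2}(A+I)D̂^{-1/2}` and fused by an elementwise
sum, `H_out = H + Â^n H`, combining local detail with longer-range context.
Spatial domains come from an EM Gaussian mixture with shared (tied)
covariance on `H_out` (k-means initialized, best of 10 restarts), with
k-means and Louvain as alternatives.  Partition agreement is scored with
ACC (Hungarian-matched accuracy), ARI and NMI.

The neural core is implemented on numpy with reverse-mode autodiff
(`autograd`) and a few fused custom gradients; there is no GPU dependency
and every run is bit-reproducible from its seed.

## Worked example

```python
from maest import SyntheticSpec, TrainingConfig, apply_dropout, fit_predict, generate

spec = SyntheticSpec(grid_shape=(20, 20), n_domains=5, n_genes=200, seed=0)
dataset = generate(spec)                          # 400 spots, 5 banded domains
noisy = apply_dropout(dataset, rate=0.3, seed=1)  # zero 30% of entries

result = fit_predict(noisy, TrainingConfig(epochs=500, seed=0), n_clusters=5)
print("domains found:", sorted(set(result.labels.tolist())))
print("agreement with planted labels:",
      {k: round(v, 3) for k, v in result.metrics.items()})
print("final losses:", {"recon": round(result.trace.recon[-1], 3),
                        "reg": round(result.trace.reg[-1], 6),
                        "discri": round(result.trace.discri[-1], 3)})
```

Output:

```
domains found: [0, 1, 2, 3, 4]
agreement with planted labels: {'acc': 1.0, 'ari': 1.0, 'nmi': 1.0}
final losses: {'recon': 0.386, 'reg': 8e-06, 'discri': 0.44}
```

The generator plants five horizontal expression bands on a 20×20 grid, each
with ten negative-binomial marker genes; after randomly zeroing 30% of the
count matrix, the trained model still recovers the planted partition exactly
(ARI 1.0).  The regularization loss has collapsed to ~1e-5, its intended
early-training-only role.

The same pipeline is available from the shell:

```bash
maest synth --out data/          # planted-domain fixture (MTX + coords + labels)
maest run --input data/ --out results/
maest eval --pred results/domains.csv --truth data/labels.tsv
```

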