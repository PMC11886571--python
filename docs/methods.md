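# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical decisions, and what the synthetic test-bed does and
does not demonstrate.

## Graph construction and preprocessing

Spots are nodes; node `i` is linked to its `k = 3` nearest neighbors by
Euclidean distance on the slide coordinates, and the adjacency is
symmetrized by union (an edge exists if either endpoint selects the other),
which can only raise degrees above `k`.  Distance ties are broken by
ascending node index, so the graph is a deterministic function of the
coordinates.  k-NN graphs need not be connected; a disconnected graph is
reported with a warning and processing continues (multi-hop propagation then
acts per component).

Preprocessing follows the standard single-cell convention: spots with total
count below `min_counts` (default 1) are dropped; each remaining spot is
scaled to a common total and `log1p`-transformed; the top `n_top` genes
(default 3000) by seurat-flavor normalized dispersion are kept, with score
ties broken by gene id.  The normalization target defaults to the *median*
per-spot total rather than a fixed constant: a fixed target (e.g. 1e4) is
only meaningful when matrices have transcriptome-scale totals, and on
smaller gene panels it inflates every entry by a large factor, letting
technical zeros dominate log-space distances.  An explicit
`scale_total=1e4` is available for users who want the CP10K convention.

## Representation learner

Encoder and decoder are each exactly one graph-attention layer (one head,
LeakyReLU slope 0.2 on attention scores; ELU on the encoder output, linear
decoder output).  Depth is deliberately not configurable: with a single
layer each node aggregates only its one-hop neighborhood plus itself
(self-loops are added inside the layer), which keeps domain boundaries sharp
and leaves longer-range context to the explicit multi-hop stage.  Latent
width `d = 64`; the regularization projector `g` is a 2-layer MLP
`d → d → d` and the discrimination head `p` a 2-layer MLP `d → d → d′` with
`d′ = 32` — halving the width before scoring keeps the discrimination task
from being overwhelmed by high-dimensional features.

### Masked reconstruction

Each epoch draws a fresh mask: `round(mask_rate · N)` spots (default rate
0.5) have their whole feature row replaced by literal zeros, not a learned
token.  The latent matrix of the corrupted graph is then re-masked `K = 3`
times — every node equally likely each draw, independent of the input mask —
and each view is decoded and scored with the scaled cosine error at
`γ = 2`.  The loss normalizes by `|Ṽ|` only, so it grows linearly with `K`;
`K` therefore doubles as a task weight, which is intended.  The re-mask rate
defaults to the input mask rate but is an independent knob.  When
`mask_rate = 0` the loop reconstructs every node — the plain-autoencoder
configuration used as the ablation baseline.

### Regularization

`L_reg` compares projections of the masked-graph and clean-graph embeddings
through the same projector `g`, with a stop-gradient on the clean-graph
branch: the target is a constant within each step, so the term corrects the
masked-graph encoder early without letting the model minimize it by moving
the target.  Because the projector fits quickly, `L_reg` decays by several
orders of magnitude over training — its final/initial ratio is asserted
below 0.1 in the acceptance suite — and acts only as an early-epoch
stabilizer, weighted by `λ1 = 0.2`.

### Node discrimination

The corrupted view permutes feature rows uniformly (topology untouched).
Both views are projected by `p` and scored against a single anchor, the
clean graph's summary `s = σ(mean of projected embeddings)`, with an
identity bilinear form (`g_i = σ(z_i·s)`); a learnable bilinear weight was
considered and rejected as unnecessary for this readout.  Scoring both views
against the *original* summary makes positive and negative terms directly
comparable; scoring each view against its own summary would make the
negative term nearly constant.  Scores are clamped to `[1e-7, 1 − 1e-7]`
so the binary cross-entropy stays finite.  Weight `λ2 = 0.02`.

### Optimization

Full-batch Adam (β = 0.9/0.999, ε = 1e-8, weight decay 0) at learning rate
0.001 for 900 epochs by default.  A fresh mask plan and permutation are
drawn every epoch — static corruption would defeat the denoising rationale.
Both tasks are summed into one objective per step (joint, not alternating).
All random draws (parameter init, masks, re-masks, permutations) come from
one generator seeded by `TrainingConfig.seed`, so traces, embeddings and
labels are bit-reproducible.  Gradients are reverse-mode `autograd` over the
numpy forwards; the dense attention softmax, pairwise score kernel and
scaled-cosine row error carry hand-written vector-Jacobian products (each
verified against finite differences in the test suite) to keep the tape
small.  Dense `N×N` attention bounds practical graph sizes to a few
thousand nodes on one CPU core; this implementation targets desk-scale
analyses and the synthetic test-bed, not atlas-scale sections.  Degenerate
rows (a node whose entire closed neighborhood was re-masked decodes to an
exact zero row) contribute `1^γ` to the loss with a zero subgradient.

## Fusion and clustering

`H_out = H + Â^n H` with `Â = D̂^{-1/2}(A+I)D̂^{-1/2}` and `n = 3`
(a row-stochastic mean-neighbor operator is available behind a switch).
Propagation is parameter-free; more hops smooth more aggressively, and the
row variance of `Â^n H` is non-increasing in `n` — the sum with the one-hop
term is what preserves node-specific detail.  `n` around 3–4 works best;
beyond that over-smoothing erodes the gain.

Clustering defaults to an EM Gaussian mixture with a single shared (tied)
covariance matrix — the in-language analogue of equal-covariance model-based
clustering — initialized from a full k-means solution (itself k-means++
seeded), best of 10 restarts by likelihood, `reg_covar = 1e-6`.  Seeding EM
with converged k-means rather than bare k-means++ centers matters in
practice: embeddings concentrate near a low-dimensional manifold, and EM
started from raw centers can slide into slivers along near-degenerate
directions.  An EM failure or empty component triggers up to 3
re-initializations with shifted seeds before raising.  The cluster count is
supplied by the caller (set it to the annotated domain count when labels
exist); no automatic model selection is attempted.  k-means (one-hot
responsibilities) and Louvain on a k-NN similarity graph of the embeddings
(emergent cluster count) are the alternatives.

ACC is defined by optimal one-to-one cluster matching (Hungarian algorithm
on the contingency table); NMI normalizes by the arithmetic mean of the two
entropies.

## Synthetic test-bed

The generator plants `D` contiguous domains (horizontal bands by default;
rectangular blocks and Voronoi cells as alternatives) on a rows × cols grid.
Every domain owns a disjoint block of marker genes whose negative-binomial
mean is `baseline_mean × marker_fold_change` inside the domain and
`baseline_mean` outside; all counts share one dispersion (NB size) `θ`, with
variance `μ + μ²/θ`.  Defaults: 20×20 grid, 5 bands, 200 genes, 10 markers
per domain, baseline mean 2.0, fold change 4.0, `θ = 3.0` — marker contrast
and overdispersion in the range typical of spot-level ST counts, scaled down
to a 200-gene panel.  Dropout corruption zeroes each entry independently at
a given rate, applied to the raw counts before preprocessing (as sequencing
dropout would be); the Bernoulli draws for a row depend only on
`(seed, spot id)`, so corruption commutes with spot subsetting.

What the test-bed does not emulate: spatially smooth within-domain expression
gradients, irregular domain shapes with thin processes, segmentation noise,
batch effects, or any histology signal.  Passing its checks demonstrates
that the implementation recovers planted, contiguous, marker-driven
domains under heavy random zeroing — not performance on real tissue.

## Problem sizes in the shipped checks

The acceptance experiments run the full pipeline on the 400-spot default
fixture at 500 training epochs (the loss plateaus well before the 900-epoch
default at this size; 200 epochs is the floor below which seed-to-seed
variation becomes visible), three seeds per condition; the
component-ablation ladder uses a low-contrast fixture (fold change 2.0) at
200 epochs, where the arms separate most clearly, with one-hop embeddings
for the ablated arms and fused embeddings for the full model.  The
dropout-robustness curve is sampled at rates 0.0/0.3/0.6/0.9; the sweep API
accepts any rate grid in [0, 1].

## Known limitations

- Dense adjacency and attention: memory grows as `N²`; intended for desk
  scale (≲ 4–5k spots), not for 50k+ cell sections.
- Single attention head and fixed one-layer depth; no edge features or
  histology integration.
- No batch/slice integration: one section at a time.
- GMM cluster count must be supplied; no BIC-style selection.
- At heavy dropout (around 60% and beyond) on small gene panels, the
  Gaussian-mixture likelihood can prefer a low-agreement partition even
  though the embeddings remain separable by k-means; robustness at such
  corruption levels depends on transcriptome-scale redundancy that a
  200-gene panel does not provide.
- CPU only; `device="accelerator"` is rejected rather than silently ignored.
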