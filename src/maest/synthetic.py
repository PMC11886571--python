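"""Planted-domain synthetic spatial transcriptomics fixtures.

The generator lays spots on a regular grid, partitions them into contiguous
spatial domains (layered bands by default, mimicking cortex-like laminar
tissue), gives every domain a block of marker genes with elevated mean
expression, and draws counts from a negative binomial so the matrix shows the
overdispersion typical of sequencing data.  A separate corruption step zeroes
entries at a chosen dropout rate to emulate technical zeros.

This is a test-bed for the pipeline, not a simulator of any real tissue: all
parameters are explicit and every draw is deterministic per seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import SpatialExpressionDataset


@dataclass
class SyntheticSpec:
    """Parameters of the planted-domain generator.

    ``dispersion`` is the negative-binomial size (shape) parameter theta:
    variance = mu + mu^2 / theta, so smaller theta means noisier counts.
    ``marker_fold_change`` multiplies the baseline mean inside a marker's
    own domain.
    """

    grid_shape: tuple = (20, 20)
    n_domains: int = 5
    layout: str = "bands"  # {"bands", "blocks", "voronoi"}
    n_genes: int = 200
    n_marker_genes_per_domain: int = 10
    baseline_mean: float = 2.0
    marker_fold_change: float = 4.0
    dispersion: float = 3.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.grid_shape
        if self.n_domains < 2:
            raise ValueError("need at least 2 domains")
        if self.layout == "bands" and rows < self.n_domains:
            raise ValueError("bands layout needs at least one grid row per domain")
        if self.n_marker_genes_per_domain * self.n_domains > self.n_genes:
            raise ValueError("marker genes exceed total genes")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _domain_layout(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-spot integer domain label on the grid, contiguous by construction."""
    rows, cols = spec.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if spec.layout == "bands":
        # horizontal bands of (near-)equal height
        edges = np.linspace(0, rows, spec.n_domains + 1)
        labels = np.searchsorted(edges, rr.ravel(), side="right") - 1
        return np.clip(labels, 0, spec.n_domains - 1)
    if spec.layout == "blocks":
        # split rows into nr strips and columns into nc strips, nr*nc >= D
        nr = int(np.floor(np.sqrt(spec.n_domains)))
        while spec.n_domains % nr:
            nr -= 1
        nc = spec.n_domains // nr
        r_edges = np.linspace(0, rows, nr + 1)
        c_edges = np.linspace(0, cols, nc + 1)
        ri = np.clip(np.searchsorted(r_edges, rr.ravel(), side="right") - 1, 0, nr - 1)
        ci = np.clip(np.searchsorted(c_edges, cc.ravel(), side="right") - 1, 0, nc - 1)
        return ri * nc + ci
    if spec.layout == "voronoi":
        centers = np.column_stack(
            [rng.uniform(0, rows, spec.n_domains), rng.uniform(0, cols, spec.n_domains)]
        )
        pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)
    raise ValueError(f"unknown layout: {spec.layout!r}")


def _nb_counts(mean: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial with mean mu and size theta (var = mu + mu^2/theta)."""
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def generate(spec: SyntheticSpec) -> SpatialExpressionDataset:
    """Draw one planted-domain dataset (labels included)."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    labels = _domain_layout(spec, rng)
    n_spots = rows * cols

    mean = np.full((n_spots, spec.n_genes), float(spec.baseline_mean))
    m = spec.n_marker_genes_per_domain
    for d in range(spec.n_domains):
        genes = slice(d * m, (d + 1) * m)
        mean[labels == d, genes] *= spec.marker_fold_change
    counts = _nb_counts(mean, spec.dispersion, rng).astype(float)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)  # (x, y)
    spot_ids = [f"spot_{r}_{c}" for r, c in zip(rr.ravel(), cc.ravel())]
    gene_ids = [f"gene_{i:04d}" for i in range(spec.n_genes)]

    ds = SpatialExpressionDataset(counts, coords, spot_ids, gene_ids, labels)
    if spec.dropout_rate > 0:
        ds = apply_dropout(ds, spec.dropout_rate, spec.seed)
    return ds


def apply_dropout(
    ds: SpatialExpressionDataset, rate: float, seed: int = 0
) -> SpatialExpressionDataset:
    """Zero each matrix entry independently with probability ``rate``.

    The Bernoulli draws for a spot depend only on (seed, spot id), so
    corrupting then subsetting rows gives the same matrix as subsetting
    then corrupting.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0.0:
        return ds.with_matrix(np.array(ds.dense_matrix(), copy=True))
    X = ds.dense_matrix().copy()
    for i, sid in enumerate(ds.spot_ids):
        row_rng = np.random.default_rng([int(seed), zlib.crc32(sid.encode())])
        X[i, row_rng.random(X.shape[1]) < rate] = 0.0
    return ds.with_matrix(X)


def dropout_sweep(
    spec: SyntheticSpec,
    rates,
    cfg=None,
    n_clusters: int | None = None,
    seeds=(0,),
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Robustness curve: corrupt -> full pipeline -> ARI, per dropout rate.

    Returns a tidy frame with one row per (rate, seed) and the achieved ARI
    against the planted labels.
    """
    from .pipeline import fit_predict
    from .training import TrainingConfig

    rates = list(rates)
    if any(r < 0 or r > 1 for r in rates):
        raise ValueError("rates must lie in [0, 1]")
    if cfg is None:
        cfg = TrainingConfig()
    if n_clusters is None:
        n_clusters = spec.n_domains
    records = []
    for rate in rates:
        for seed in seeds:
            run_cfg = TrainingConfig(**{**cfg.to_dict(), "seed": int(seed)})
            ds = generate(spec)
            corrupted = apply_dropout(ds, rate, seed=spec.seed + 1)
            result = fit_predict(
                corrupted, run_cfg, n_clusters=n_clusters, **pipeline_kwargs
            )
            records.append({"rate": rate, "seed": int(seed), "ari": result.metrics["ari"]})
    return pd.DataFrame.from_records(records)
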