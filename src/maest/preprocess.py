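"""Expression preprocessing: outlier-spot removal, log-normalization, HVG selection.

The conventional pipeline order is: remove low-count spots, scale each spot to
a common total (default 1e4), apply log(1 + x), then keep the top highly
variable genes (default 3000) ranked by seurat-flavor normalized dispersion.
The HVG ranking is made fully deterministic by breaking score ties on gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .datasets import SpatialExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_SCALE_TOTAL = 1e4
DEFAULT_N_TOP_GENES = 3000


@dataclass
class PreprocessReport:
    """What the preprocessing pipeline did, for structured logging."""

    n_spots_removed: int = 0
    n_genes_input: int = 0
    n_hvg_selected: int = 0
    transform_applied: str = "passthrough"  # {"lognorm", "passthrough"}

    def __post_init__(self):
        if self.n_hvg_selected > self.n_genes_input:
            raise ValueError("n_hvg_selected cannot exceed n_genes_input")


def remove_outlier_spots(
    ds: SpatialExpressionDataset, min_counts: int = 1
) -> tuple[SpatialExpressionDataset, PreprocessReport]:
    """Drop spots whose total count falls below ``min_counts``.

    Coordinates and labels are filtered consistently; surviving rows keep
    their values untouched.  Raises if every spot would be removed.
    """
    if min_counts < 0:
        raise ValueError("min_counts must be >= 0")
    totals = ds.total_counts()
    keep = np.flatnonzero(totals >= min_counts)
    if keep.size == 0:
        raise ValueError(
            f"min_counts={min_counts} removes all {ds.n_spots} spots"
        )
    report = PreprocessReport(
        n_spots_removed=int(ds.n_spots - keep.size),
        n_genes_input=ds.n_genes,
    )
    out = ds if keep.size == ds.n_spots else ds.subset_spots(keep)
    return out, report


def lognormalize(
    ds: SpatialExpressionDataset, scale_total: float | None = DEFAULT_SCALE_TOTAL
) -> SpatialExpressionDataset:
    """Scale each spot to ``scale_total`` total counts, then log(1 + x).

    ``scale_total=None`` scales to the median of the per-spot totals (the
    scanpy convention), which keeps the transformed values on the natural
    scale of the data regardless of how many genes the matrix has.  Rows
    with zero total are left as zeros.  Output is dense and finite.
    """
    X = ds.dense_matrix()
    totals = X.sum(axis=1, keepdims=True)
    if scale_total is None:
        positive = totals[totals > 0]
        scale_total = float(np.median(positive)) if positive.size else 1.0
    scale = np.divide(
        scale_total, totals, out=np.zeros_like(totals), where=totals > 0
    )
    return ds.with_matrix(np.log1p(X * scale))


def hvg_scores(ds: SpatialExpressionDataset) -> np.ndarray:
    """Normalized-dispersion variability score per gene (seurat flavor).

    Thin wrapper over scanpy's binned dispersion statistic so that ranking
    and tie-breaking stay in this package's hands.
    """
    import scanpy as sc

    ad = ds.to_anndata()
    if sp.issparse(ad.X):
        ad.X = ad.X.astype(np.float64)
    else:
        ad.X = np.asarray(ad.X, dtype=np.float64)
    n_top = min(max(ds.n_genes - 1, 1), ds.n_genes)
    try:
        sc.pp.highly_variable_genes(ad, flavor="seurat", n_top_genes=None)
        scores = np.asarray(ad.var["dispersions_norm"], dtype=float)
    except Exception:  # degenerate inputs (e.g. all-constant genes)
        scores = np.full(ds.n_genes, np.nan)
    # constant genes come back NaN: rank them last
    return np.where(np.isfinite(scores), scores, -np.inf)


def select_hvg(
    ds: SpatialExpressionDataset, n_top: int = DEFAULT_N_TOP_GENES
) -> SpatialExpressionDataset:
    """Keep the ``n_top`` most variable genes.

    Ranking is by normalized dispersion (descending) with ties broken by
    gene id (ascending), so the selection is deterministic.  If ``n_top``
    is at least the number of genes, the dataset is returned unchanged.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top >= ds.n_genes:
        return ds
    scores = hvg_scores(ds)
    order = sorted(range(ds.n_genes), key=lambda i: (-scores[i], ds.gene_ids[i]))
    keep = sorted(order[:n_top])
    return ds.subset_genes(np.asarray(keep, dtype=int))


def preprocess(
    ds: SpatialExpressionDataset,
    min_counts: int = 1,
    scale_total: float | None = None,
    n_top: int = DEFAULT_N_TOP_GENES,
) -> tuple[SpatialExpressionDataset, PreprocessReport]:
    """Full pipeline: outlier removal -> total-count norm -> log1p -> HVG."""
    ds, report = remove_outlier_spots(ds, min_counts=min_counts)
    ds = lognormalize(ds, scale_total=scale_total)
    ds = select_hvg(ds, n_top=n_top)
    report.n_hvg_selected = ds.n_genes
    report.transform_applied = "lognorm"
    logger.info(
        "preprocess: removed %d spots, kept %d/%d genes, transform=%s",
        report.n_spots_removed,
        report.n_hvg_selected,
        report.n_genes_input,
        report.transform_applied,
    )
    return ds, report
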