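"""Spot-by-gene expression datasets with spatial coordinates.

The :class:`SpatialExpressionDataset` is the universal input container of the
package: a non-negative spots × genes matrix, per-spot 2D coordinates in the
same row order, string spot/gene identifiers and optional ground-truth domain
labels for evaluation.  Readers exist for the three formats practitioners
actually have on disk: a 10x-style MTX directory plus a coordinates table, a
dense CSV table, and an ``.h5ad`` container.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def _as_dense(matrix) -> np.ndarray:
    if sp.issparse(matrix):
        return np.asarray(matrix.todense(), dtype=float)
    return np.asarray(matrix, dtype=float)


@dataclass
class SpatialExpressionDataset:
    """Expression matrix + spatial coordinates for one tissue section.

    Parameters
    ----------
    matrix
        Non-negative ``(n_spots, n_genes)`` expression values (counts or
        normalized).  Dense ndarray or scipy sparse; stored as given.
    coords
        ``(n_spots, 2)`` spatial positions, same row order as ``matrix``.
    spot_ids, gene_ids
        Unique string identifiers for rows and columns.
    labels
        Optional per-spot ground-truth domain labels (int or str).
    """

    matrix: np.ndarray
    coords: np.ndarray
    spot_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, g = self.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{n} spots x 2"
            )
        if len(self.spot_ids) != n:
            raise ValueError("spot_ids length does not match matrix rows")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match matrix columns")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids are not unique")
        vals = self.matrix.data if sp.issparse(self.matrix) else np.asarray(self.matrix)
        if not np.all(np.isfinite(vals)):
            raise ValueError("matrix contains non-finite entries")
        if vals.size and np.min(vals) < 0:
            raise ValueError("matrix contains negative entries")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite entries")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match matrix rows")

    @property
    def shape(self):
        return self.matrix.shape

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def dense_matrix(self) -> np.ndarray:
        return _as_dense(self.matrix)

    def total_counts(self) -> np.ndarray:
        """Per-spot total over genes."""
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.sum(axis=1)).ravel()
        return np.asarray(self.matrix).sum(axis=1)

    def subset_spots(self, idx: np.ndarray) -> "SpatialExpressionDataset":
        idx = np.asarray(idx)
        return SpatialExpressionDataset(
            matrix=self.matrix[idx],
            coords=self.coords[idx],
            spot_ids=[self.spot_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            labels=None if self.labels is None else self.labels[idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "SpatialExpressionDataset":
        idx = np.asarray(idx)
        return SpatialExpressionDataset(
            matrix=self.matrix[:, idx],
            coords=self.coords.copy(),
            spot_ids=list(self.spot_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels.copy(),
        )

    def with_matrix(self, matrix) -> "SpatialExpressionDataset":
        return SpatialExpressionDataset(
            matrix=matrix,
            coords=self.coords.copy(),
            spot_ids=list(self.spot_ids),
            gene_ids=list(self.gene_ids),
            labels=None if self.labels is None else self.labels.copy(),
        )

    # -- conversion ------------------------------------------------------
    def to_anndata(self):
        import anndata

        ad = anndata.AnnData(
            X=self.matrix if sp.issparse(self.matrix) else np.asarray(self.matrix, dtype=float),
            obs=pd.DataFrame(index=self.spot_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )
        ad.obsm["spatial"] = self.coords.copy()
        if self.labels is not None:
            ad.obs["domain"] = pd.Categorical([str(x) for x in self.labels])
        return ad

    @classmethod
    def from_anndata(cls, ad) -> "SpatialExpressionDataset":
        if "spatial" not in ad.obsm:
            raise ValueError("AnnData lacks obsm['spatial'] coordinates")
        labels = None
        if "domain" in ad.obs:
            labels = np.asarray(ad.obs["domain"].astype(str))
        X = ad.X
        if sp.issparse(X):
            X = X.tocsr()
        else:
            X = np.asarray(X, dtype=float)
        return cls(
            matrix=X,
            coords=np.asarray(ad.obsm["spatial"], dtype=float)[:, :2],
            spot_ids=list(map(str, ad.obs_names)),
            gene_ids=list(map(str, ad.var_names)),
            labels=labels,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_COORD_FILES = ("coordinates.tsv", "coordinates.csv", "positions.tsv", "positions.csv")


def _read_coord_table(path: str) -> pd.DataFrame:
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    for need in ("spot_id", "x", "y"):
        if need not in cols:
            raise ValueError(f"coordinate table {path} lacks column '{need}'")
    df = df[[cols["spot_id"], cols["x"], cols["y"]]]
    df.columns = ["spot_id", "x", "y"]
    df["spot_id"] = df["spot_id"].astype(str)
    if not (
        np.issubdtype(df["x"].dtype, np.number)
        and np.issubdtype(df["y"].dtype, np.number)
    ):
        raise ValueError(f"coordinate table {path} has non-numeric x/y entries")
    return df


def _align_coords(spot_ids: Sequence[str], coord_df: pd.DataFrame):
    table = coord_df.set_index("spot_id")
    missing = [s for s in spot_ids if s not in table.index]
    if missing:
        raise ValueError(
            "coordinates missing for spot id(s): " + ", ".join(missing[:10])
        )
    sub = table.loc[list(spot_ids)]
    return np.asarray(sub[["x", "y"]], dtype=float)


def read_dataset(path: str, format: str = "mtx_dir") -> SpatialExpressionDataset:
    """Read a :class:`SpatialExpressionDataset` from disk.

    ``mtx_dir`` expects ``matrix.mtx`` (spots × genes), ``barcodes.tsv``,
    ``features.tsv`` and a coordinates table (``coordinates.tsv``/``.csv``
    with columns spot_id, x, y) in one directory, plus an optional
    ``labels.tsv`` (spot_id, domain).  ``table`` expects a dense CSV with
    spot ids as the index and genes as columns, next to a coordinates table
    ``<stem>.coords.csv``.  ``h5ad`` expects coordinates in
    ``obsm['spatial']`` and optional labels in ``obs['domain']``.
    """
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format == "table":
        return _read_table(path)
    if format == "h5ad":
        import anndata

        return SpatialExpressionDataset.from_anndata(anndata.read_h5ad(path))
    raise ValueError(f"unknown format: {format!r}")


def _read_mtx_dir(path: str) -> SpatialExpressionDataset:
    mtx_path = os.path.join(path, "matrix.mtx")
    if not os.path.exists(mtx_path):
        raise FileNotFoundError(f"{mtx_path} not found")
    matrix = sp.csr_matrix(scipy.io.mmread(mtx_path))
    spot_ids = (
        pd.read_csv(os.path.join(path, "barcodes.tsv"), header=None, sep="\t")[0]
        .astype(str)
        .tolist()
    )
    gene_ids = (
        pd.read_csv(os.path.join(path, "features.tsv"), header=None, sep="\t")[0]
        .astype(str)
        .tolist()
    )
    coord_path = None
    for cand in _COORD_FILES:
        if os.path.exists(os.path.join(path, cand)):
            coord_path = os.path.join(path, cand)
            break
    if coord_path is None:
        raise FileNotFoundError(f"no coordinates table found in {path}")
    coords = _align_coords(spot_ids, _read_coord_table(coord_path))
    labels = None
    lab_path = os.path.join(path, "labels.tsv")
    if os.path.exists(lab_path):
        lab = pd.read_csv(lab_path, sep="\t").set_index("spot_id")
        labels = np.asarray(lab.loc[spot_ids, "domain"])
    return SpatialExpressionDataset(matrix, coords, spot_ids, gene_ids, labels)


def _read_table(path: str) -> SpatialExpressionDataset:
    df = pd.read_csv(path, index_col=0)
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValueError(f"expression table {path} has non-numeric entries")
    stem = path[:-4] if path.endswith(".csv") else path
    coord_path = stem + ".coords.csv"
    if not os.path.exists(coord_path):
        raise FileNotFoundError(f"coordinates table {coord_path} not found")
    spot_ids = df.index.astype(str).tolist()
    coords = _align_coords(spot_ids, _read_coord_table(coord_path))
    return SpatialExpressionDataset(
        np.asarray(df, dtype=float), coords, spot_ids, df.columns.astype(str).tolist()
    )


def write_dataset(ds: SpatialExpressionDataset, path: str, format: str = "mtx_dir") -> None:
    """Write a dataset in the formats understood by :func:`read_dataset`."""
    if format == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sp.coo_matrix(ds.matrix))
        pd.Series(ds.spot_ids).to_csv(
            os.path.join(path, "barcodes.tsv"), index=False, header=False
        )
        pd.Series(ds.gene_ids).to_csv(
            os.path.join(path, "features.tsv"), index=False, header=False
        )
        pd.DataFrame(
            {"spot_id": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
        ).to_csv(os.path.join(path, "coordinates.tsv"), sep="\t", index=False)
        if ds.labels is not None:
            pd.DataFrame({"spot_id": ds.spot_ids, "domain": ds.labels}).to_csv(
                os.path.join(path, "labels.tsv"), sep="\t", index=False
            )
    elif format == "table":
        pd.DataFrame(ds.dense_matrix(), index=ds.spot_ids, columns=ds.gene_ids).to_csv(path)
        stem = path[:-4] if path.endswith(".csv") else path
        pd.DataFrame(
            {"spot_id": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
        ).to_csv(stem + ".coords.csv", index=False)
    elif format == "h5ad":
        ds.to_anndata().write_h5ad(path)
    else:
        raise ValueError(f"unknown format: {format!r}")
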