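"""End-to-end pipeline: read -> preprocess -> graph -> train -> fuse -> cluster.

``fit_predict`` is the library entry point used by the CLI, the synthetic
sweeps, and the tests.  ``run_pipeline`` is the file-to-file wrapper: it reads
a dataset, executes the pipeline under a YAML config, and writes labels,
embeddings, the loss trace, a resolved-config snapshot, and a log — enough to
reproduce the run bit-for-bit.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cluster import DomainAssignment, cluster_gmm, cluster_kmeans, cluster_louvain
from .datasets import SpatialExpressionDataset, read_dataset
from .fusion import DEFAULT_HOPS, EmbeddingSet, fused_embeddings
from .graph import DEFAULT_K, assemble_graph
from .metrics import evaluate
from .preprocess import DEFAULT_N_TOP_GENES, preprocess
from .training import TrainingConfig, TrainingTrace, train

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one run."""

    training: TrainingConfig = field(default_factory=TrainingConfig)
    min_counts: int = 1
    scale_total: float | None = None  # None = median of per-spot totals
    n_top_genes: int = DEFAULT_N_TOP_GENES
    k_neighbors: int = DEFAULT_K
    hops: int = DEFAULT_HOPS
    aggregator: str = "gcn"
    use_fusion: bool = True
    n_clusters: int = 5
    cluster_method: str = "gmm"  # {"gmm", "kmeans", "louvain"}
    louvain_resolution: float = 1.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["training"] = self.training.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        training = TrainingConfig.from_dict(d.pop("training", {}))
        known = set(cls.__dataclass_fields__) - {"training"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config key(s): {sorted(unknown)}")
        return cls(training=training, **d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    labels: np.ndarray
    assignment: DomainAssignment
    embeddings: EmbeddingSet
    trace: TrainingTrace
    spot_ids: list
    metrics: dict = field(default_factory=dict)
    labels_true: Optional[np.ndarray] = None


def _cluster(H_out, cfg: PipelineConfig, seed: int) -> DomainAssignment:
    if cfg.cluster_method == "gmm":
        return cluster_gmm(H_out, cfg.n_clusters, seed=seed)
    if cfg.cluster_method == "kmeans":
        return cluster_kmeans(H_out, cfg.n_clusters, seed=seed)
    if cfg.cluster_method == "louvain":
        return cluster_louvain(H_out, resolution=cfg.louvain_resolution, seed=seed)
    raise ValueError(f"unknown cluster method: {cfg.cluster_method!r}")


def fit_predict(
    ds: SpatialExpressionDataset,
    training: TrainingConfig | None = None,
    n_clusters: int | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on an in-memory dataset.

    If the dataset carries ground-truth labels, ACC/ARI/NMI against them are
    computed on the spots surviving preprocessing.
    """
    if config is None:
        config = PipelineConfig()
    if training is not None:
        config = PipelineConfig.from_dict({**config.to_dict(), "training": training.to_dict()})
    if n_clusters is not None:
        config.n_clusters = int(n_clusters)

    pp, report = preprocess(
        ds,
        min_counts=config.min_counts,
        scale_total=config.scale_total,
        n_top=config.n_top_genes,
    )
    graph = assemble_graph(pp, k=config.k_neighbors)
    model, trace, H = train(graph, config.training)
    if config.use_fusion:
        emb = fused_embeddings(H, graph.adjacency, n=config.hops, aggregator=config.aggregator)
        H_cluster = emb.H_out
    else:
        emb = EmbeddingSet(H=H, H_D=np.zeros_like(H), H_out=H)
        H_cluster = H
    assignment = _cluster(H_cluster, config, seed=config.training.seed)

    result = PipelineResult(
        labels=assignment.labels,
        assignment=assignment,
        embeddings=emb,
        trace=trace,
        spot_ids=list(pp.spot_ids),
        labels_true=pp.labels,
    )
    if pp.labels is not None:
        result.metrics = evaluate(pp.labels, assignment.labels)
        logger.info("clustering agreement: %s", result.metrics)
    return result


def run_pipeline(input_path: str, config_path: str | None, out_dir: str,
                 fmt: str = "mtx_dir") -> int:
    """File-to-file pipeline execution; returns a process exit status."""
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "run.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("maest")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "read"
    try:
        config = PipelineConfig.from_yaml(config_path) if config_path else PipelineConfig()
        logger.info("resolved config: %s", config.to_dict())
        logger.info("rng seed: %d", config.training.seed)
        ds = read_dataset(input_path, format=fmt)
        stage = "pipeline"
        result = fit_predict(ds, config=config)
        stage = "write"
        pd.DataFrame({"spot_id": result.spot_ids, "domain": result.labels}).to_csv(
            os.path.join(out_dir, "domains.csv"), index=False
        )
        for name, arr in (
            ("H", result.embeddings.H),
            ("H_D", result.embeddings.H_D),
            ("H_out", result.embeddings.H_out),
        ):
            pd.DataFrame(arr, index=result.spot_ids).to_csv(
                os.path.join(out_dir, f"embeddings_{name}.csv")
            )
        result.trace.to_frame().to_csv(os.path.join(out_dir, "trace.csv"), index=False)
        config.to_yaml(os.path.join(out_dir, "config_resolved.yaml"))
        if result.metrics:
            pd.Series(result.metrics).to_csv(os.path.join(out_dir, "metrics.csv"))
        return 0
    except Exception:
        logger.exception("pipeline failed during stage %r", stage)
        return 1
    finally:
        root.removeHandler(handler)
        handler.close()
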