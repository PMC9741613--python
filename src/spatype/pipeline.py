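"""High-level three-stage annotation pipeline.

Wires the modules together the way the method is meant to be run:

1. **Transfer** — align gene sets, normalize both datasets, train the
   reference classifier, predict per-cell distributions on the spatial
   data and soften them into pseudo-labels.
2. **Spatial embedding** — build the spatial neighbour graph and train the
   joint autoencoder / VGAE / classifier on the pseudo-labels.
3. **Inference** — reload the optimal checkpoint and annotate every cell;
   optionally run new-type discovery and evaluation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datasets import AnnotationResult, ExpressionDataset, align_gene_sets
from .discovery import DiscoveryReport, discover_new_types
from .embedding import GcnConfig, JointModel, annotate, latent_features, train_stage2
from .graph import SpatialGraph, build_spatial_graph
from .preprocess import normalize_cells, reduce_pca
from .transfer import DnnConfig, DnnModel, generate_pseudo_labels, predict_probabilities, train_dnn

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Aggregated configuration for a full annotation run."""

    use_log1p: bool = True
    pca_components: int = 200
    pca_gene_threshold: int = 1000
    n_neighbors: int = 30
    theta: Optional[float] = None      # decay coefficient (µm); None = adaptive
    temperature: float = 2.0
    dnn: DnnConfig = field(default_factory=DnnConfig)
    gcn: GcnConfig = field(default_factory=GcnConfig)
    discovery_threshold: Optional[float] = None   # None disables discovery
    discovery_k: Optional[int] = None
    radius_quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        # a single pipeline seed drives both training stages unless the
        # sub-configs were seeded explicitly
        self.dnn.seed = self.dnn.seed or self.seed
        self.gcn.seed = self.gcn.seed or self.seed


@dataclass
class PipelineResult:
    """Everything a run produces, for inspection or saving."""

    annotation: AnnotationResult
    stage1_annotation: AnnotationResult
    dnn_model: DnnModel
    joint_model: JointModel
    graph: SpatialGraph
    latent: np.ndarray
    discovery_report: Optional[DiscoveryReport] = None
    timings: dict[str, float] = field(default_factory=dict)


def _preprocess(ds: ExpressionDataset, cfg: PipelineConfig) -> ExpressionDataset:
    out = normalize_cells(ds, use_log1p=cfg.use_log1p)
    return reduce_pca(out, cfg.pca_components, cfg.pca_gene_threshold)


def run_pipeline(
    reference: ExpressionDataset,
    srt: ExpressionDataset,
    config: Optional[PipelineConfig] = None,
    markers: Optional[list[str]] = None,
) -> PipelineResult:
    """Run stages 1–3 (and optional discovery) end to end."""
    cfg = config or PipelineConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    ref, tgt = align_gene_sets(reference, srt, markers)
    ref_n = _preprocess(ref, cfg)
    tgt_n = _preprocess(tgt, cfg)
    timings["preprocess"] = time.perf_counter() - t0

    # stage 1: transfer
    t0 = time.perf_counter()
    dnn = train_dnn(ref_n, cfg.dnn)
    dist = predict_probabilities(dnn, tgt_n)
    pseudo = generate_pseudo_labels(dist, T=cfg.temperature)
    stage1 = AnnotationResult(
        cells=list(tgt_n.cells),
        types=list(dist.types),
        predicted=[dist.types[i] for i in dist.probs.argmax(axis=1)],
        max_probability=dist.probs.max(axis=1),
        status=["assigned"] * tgt_n.n_cells,
        probs=dist.probs,
    )
    timings["stage1"] = time.perf_counter() - t0
    log.info("stage 1 done in %.1fs", timings["stage1"])

    # stage 2: spatial embedding
    t0 = time.perf_counter()
    if tgt_n.coords is None:
        raise ValueError("spatial dataset has no coordinates")
    graph = build_spatial_graph(tgt_n.coords, n_neighbors=cfg.n_neighbors, theta=cfg.theta)
    cfg.gcn.temperature = cfg.temperature
    joint = train_stage2(tgt_n, graph, pseudo, cfg.gcn)
    timings["stage2"] = time.perf_counter() - t0
    log.info("stage 2 done in %.1fs", timings["stage2"])

    # stage 3: inference
    t0 = time.perf_counter()
    result = annotate(joint, tgt_n, graph)
    Z = latent_features(joint, tgt_n, graph)
    timings["stage3"] = time.perf_counter() - t0

    report = None
    if cfg.discovery_threshold is not None:
        result, report = discover_new_types(
            result, Z,
            threshold=cfg.discovery_threshold,
            k=cfg.discovery_k,
            radius_quantile=cfg.radius_quantile,
            seed=cfg.seed,
        )
    return PipelineResult(
        annotation=result,
        stage1_annotation=stage1,
        dnn_model=dnn,
        joint_model=joint,
        graph=graph,
        latent=Z,
        discovery_report=report,
        timings=timings,
    )
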