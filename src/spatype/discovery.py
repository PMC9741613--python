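"""New-cell-type discovery: thresholding, clustering, mapping, filtering.

Cells whose maximum classifier probability c_s falls below a confidence
threshold (empirically 0.5–0.9) are tagged *unassigned*.  Unassigned cells
are clustered in the model's combined latent space (k-means, with k
defaulting to half the taxonomy size); each cluster's centroid is then
compared against the latent-space footprint of every confidently predicted
type.  A cluster lying within the radius of some type is folded back into
the nearest such type; a cluster outside every radius is declared a new
cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil
from typing import Optional

import numpy as np
import pandas as pd

from .datasets import AnnotationResult

__all__ = [
    "flag_unassigned",
    "cluster_unassigned",
    "resolve_new_types",
    "discover_new_types",
    "DiscoveryReport",
]


def flag_unassigned(result: AnnotationResult, threshold: float) -> tuple[AnnotationResult, np.ndarray]:
    """Mark cells with c_s below ``threshold`` as unassigned.

    Returns the updated annotation and the boolean mask of unassigned cells.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    mask = result.max_probability < threshold
    status = ["unassigned" if m else "assigned" for m in mask]
    updated = AnnotationResult(
        cells=list(result.cells),
        types=list(result.types),
        predicted=list(result.predicted),
        max_probability=result.max_probability.copy(),
        status=status,
        probs=result.probs,
    )
    return updated, mask


def cluster_unassigned(features: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means over the latent vectors of unassigned cells.

    ``k`` defaults (at the pipeline level) to ceil(#types / 2).  Raises when
    fewer cells than clusters are available.
    """
    features = np.asarray(features, dtype=np.float64)
    if k < 1:
        raise ValueError("k must be positive")
    if features.shape[0] < k:
        raise ValueError(
            f"only {features.shape[0]} unassigned cells for k={k}; use a smaller k")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(features)


@dataclass
class DiscoveryReport:
    """Per-cluster decisions: nearest type, distances, and the verdict."""

    table: pd.DataFrame

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def resolve_new_types(
    clusters: np.ndarray,
    result: AnnotationResult,
    features_all: np.ndarray,
    unassigned_mask: np.ndarray,
    radius_quantile: float = 0.95,
) -> tuple[AnnotationResult, DiscoveryReport]:
    """Map unassigned clusters onto predicted types or declare new types.

    For every predicted type, the centroid is the mean latent vector of its
    *assigned* cells and the radius is the ``radius_quantile`` quantile of
    member distances to that centroid.  A cluster whose centroid lies
    within at least one type radius is relabeled to the nearest such type;
    otherwise its cells get status ``new_type:<k>``.  Assigned cells are
    never touched.
    """
    features_all = np.asarray(features_all, dtype=np.float64)
    if features_all.shape[0] != result.n_cells:
        raise ValueError("features must cover every cell")
    unassigned_idx = np.flatnonzero(unassigned_mask)
    if len(clusters) != len(unassigned_idx):
        raise ValueError("one cluster id per unassigned cell required")

    # type footprints from confidently assigned cells
    centroids: dict[str, np.ndarray] = {}
    radii: dict[str, float] = {}
    assigned_mask = ~np.asarray(unassigned_mask)
    for t in result.types:
        members = [i for i in np.flatnonzero(assigned_mask) if result.predicted[i] == t]
        if len(members) < 2:
            continue  # too few members to define a footprint
        feats = features_all[members]
        c = feats.mean(axis=0)
        d = np.linalg.norm(feats - c, axis=1)
        centroids[t] = c
        radii[t] = float(np.quantile(d, radius_quantile))

    predicted = list(result.predicted)
    status = list(result.status)
    rows = []
    new_counter = 0
    for cid in sorted(set(int(c) for c in clusters)):
        cells = unassigned_idx[clusters == cid]
        centroid = features_all[cells].mean(axis=0)
        best_t, best_d = None, np.inf
        containing = []
        for t, c in centroids.items():
            d = float(np.linalg.norm(centroid - c))
            if d < radii[t]:
                containing.append((d, t))
            if d < best_d:
                best_t, best_d = t, d
        if containing:
            d, t = min(containing)
            for i in cells:
                predicted[i] = t
                status[i] = "assigned"
            decision = f"merged:{t}"
        else:
            new_counter += 1
            tag = f"new_type:{new_counter}"
            for i in cells:
                status[i] = tag
            decision = tag
        rows.append({
            "cluster": cid,
            "size": len(cells),
            "nearest_type": best_t,
            "centroid_distance": best_d,
            "type_radius": radii.get(best_t, np.nan),
            "decision": decision,
        })
    updated = AnnotationResult(
        cells=list(result.cells),
        types=list(result.types),
        predicted=predicted,
        max_probability=result.max_probability.copy(),
        status=status,
        probs=result.probs,
    )
    return updated, DiscoveryReport(pd.DataFrame(rows))


def discover_new_types(
    result: AnnotationResult,
    features_all: np.ndarray,
    threshold: float = 0.7,
    k: Optional[int] = None,
    radius_quantile: float = 0.95,
    seed: int = 0,
) -> tuple[AnnotationResult, DiscoveryReport]:
    """Full discovery postprocess on an annotation.

    With no unassigned cells (every c_s >= threshold) the annotation is
    returned unchanged.
    """
    flagged, mask = flag_unassigned(result, threshold)
    if not mask.any():
        return flagged, DiscoveryReport(pd.DataFrame(
            columns=["cluster", "size", "nearest_type", "centroid_distance",
                     "type_radius", "decision"]))
    if k is None:
        k = ceil(len(result.types) / 2)
    k = min(k, int(mask.sum()))
    clusters = cluster_unassigned(np.asarray(features_all)[mask], k, seed=seed)
    return resolve_new_types(clusters, flagged, features_all, mask, radius_quantile)
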