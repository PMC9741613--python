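"""Normalization, PCA reduction, Gaussian smoothing and quality control.

The preprocessing contract mirrors what the annotation pipeline expects:
raw counts are optionally log1p-transformed, then each cell's expression
vector is rescaled to unit Euclidean length so the classifier sees
library-size-free profiles.  For panels with very many genes the matrix is
reduced to a few hundred principal components before the autoencoder.
Imaging-based platforms with heavy dropout can additionally be denoised by
Gaussian smoothing over nearest neighbours in PCA feature space.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .datasets import ExpressionDataset, ValidationError

__all__ = ["normalize_cells", "reduce_pca", "gaussian_smooth", "qc_filter", "StateError"]

log = logging.getLogger(__name__)


class StateError(ValueError):
    """Raised when an operation receives data in the wrong processing state."""


def normalize_cells(ds: ExpressionDataset, use_log1p: bool = False) -> ExpressionDataset:
    """Scale every cell's expression vector to unit L2 norm.

    With ``use_log1p`` each entry is first replaced by ``log(1 + value)``,
    damping the influence of very highly expressed genes.  All-zero cells
    are left all-zero (they are expected to be removed by QC upstream).
    """
    if ds.state != "raw":
        raise StateError(f"normalize_cells expects raw counts, got state {ds.state!r}")
    X = ds.counts
    if use_log1p:
        X = np.log1p(X)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return ds.with_counts(X / safe, "normalized")


def reduce_pca(
    ds: ExpressionDataset,
    n_components: int = 200,
    gene_threshold: int = 1000,
) -> ExpressionDataset:
    """Project cells onto the top principal components.

    Applied only when the gene panel exceeds ``gene_threshold`` genes
    (wide panels make the downstream autoencoder input unwieldy); narrow
    panels are returned unchanged.  Columns are mean-centered before the
    decomposition.
    """
    if ds.state not in ("normalized", "smoothed"):
        raise StateError(f"reduce_pca expects normalized/smoothed data, got {ds.state!r}")
    if ds.n_genes <= gene_threshold:
        return ds
    bound = min(ds.n_cells, ds.n_genes)
    if not (0 < n_components <= bound):
        raise ValueError(f"n_components must be in [1, {bound}], got {n_components}")
    from sklearn.decomposition import PCA

    scores = PCA(n_components=n_components, svd_solver="auto", random_state=0).fit_transform(ds.counts)
    out = ExpressionDataset(
        cells=list(ds.cells),
        genes=[f"PC{i + 1}" for i in range(n_components)],
        counts=scores,
        coords=ds.coords,
        labels=ds.labels,
        taxonomy=list(ds.taxonomy),
        state="pca",
    )
    return out


def gaussian_smooth(
    ds: ExpressionDataset,
    k_neighbors: int = 10,
    n_feature_dims: int = 50,
    bandwidth: Optional[float] = None,
) -> ExpressionDataset:
    """Replace each cell's expression by a Gaussian-weighted neighbour average.

    Neighbours are found in a PCA feature space of ``n_feature_dims``
    dimensions computed from the expression matrix itself; the kernel acts
    on feature-space distance.  The focal cell participates with weight 1.
    ``bandwidth=None`` uses an adaptive per-cell bandwidth equal to the mean
    distance to the k nearest neighbours.

    With ``k_neighbors=0`` the data passes through unchanged.
    """
    if ds.state not in ("raw", "normalized"):
        raise StateError(f"gaussian_smooth expects raw/normalized data, got {ds.state!r}")
    if k_neighbors < 0:
        raise ValueError("k_neighbors must be non-negative")
    if k_neighbors >= ds.n_cells:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of cells ({ds.n_cells})")
    if k_neighbors == 0:
        return ds.with_counts(ds.counts.copy(), "smoothed")

    X = ds.counts
    ncomp = min(n_feature_dims, ds.n_cells, ds.n_genes)
    centered = X - X.mean(axis=0, keepdims=True)
    if ncomp < min(X.shape):
        from sklearn.decomposition import PCA

        feats = PCA(n_components=ncomp, random_state=0).fit_transform(X)
    else:
        feats = centered
    tree = cKDTree(feats)
    # +1: the query set contains each point itself
    dist, idx = tree.query(feats, k=k_neighbors + 1)
    out = np.empty_like(X)
    for i in range(ds.n_cells):
        d, j = dist[i], idx[i]
        h = bandwidth if bandwidth is not None else max(float(d[1:].mean()), 1e-12)
        w = np.exp(-(d ** 2) / (2.0 * h ** 2))
        w[0] = 1.0  # self weight
        w = w / w.sum()
        out[i] = w @ X[j]
    return ds.with_counts(out, "smoothed")


def qc_filter(
    ds: ExpressionDataset,
    min_counts: int = 300,
    max_count_quantile: float = 0.98,
    max_mito_fraction: float = 0.10,
    min_cells_per_gene: int = 10,
    mito_prefix: str = "mt-",
) -> ExpressionDataset:
    """Remove low-quality cells and rarely detected genes.

    Cells are dropped when their total count falls below ``min_counts`` or
    above the ``max_count_quantile`` quantile of per-cell totals, or when
    mitochondrial genes (case-insensitive prefix match on ``mito_prefix``)
    contribute more than ``max_mito_fraction`` of the total.  Genes detected
    (count > 0) in fewer than ``min_cells_per_gene`` of the surviving cells
    are then dropped.
    """
    if ds.state != "raw":
        raise StateError(f"qc_filter expects raw counts, got state {ds.state!r}")
    if not (0 < max_count_quantile <= 1):
        raise ValueError("max_count_quantile must lie in (0, 1]")
    totals = ds.counts.sum(axis=1)
    upper = np.quantile(totals, max_count_quantile)
    keep = (totals >= min_counts) & (totals <= upper)
    mito = np.array([g.lower().startswith(mito_prefix.lower()) for g in ds.genes])
    if mito.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, ds.counts[:, mito].sum(axis=1) / totals, 0.0)
        keep &= frac <= max_mito_fraction
    if not keep.any():
        raise ValidationError("qc_filter removed every cell")
    filtered = ds.subset_cells(np.flatnonzero(keep))
    detected = (filtered.counts > 0).sum(axis=0)
    gene_keep = detected >= min_cells_per_gene
    result = filtered.subset_genes(np.flatnonzero(gene_keep))
    log.info(
        "qc_filter: %d -> %d cells, %d -> %d genes",
        ds.n_cells, result.n_cells, ds.n_genes, result.n_genes,
    )
    return result
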