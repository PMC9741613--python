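"""Core domain types and dataset I/O.

The package operates on two kinds of expression datasets that share one
container type:

* a *reference* dataset — dissociated scRNA-seq counts with a curated
  cell-type label per cell, used as the source domain for label transfer;
* a *target* (spatially resolved) dataset — cell x gene counts plus per-cell
  2D or 3D spatial coordinates in micrometres.

Supported on-disk formats are the HDF5-backed single-cell container
(``.h5ad``, via :mod:`anndata`), delimited text with a header row, and
MatrixMarket sparse triplets with plain-text id sidecar files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "AnnotationResult",
    "ValidationError",
    "FormatError",
    "AlignmentError",
    "load_expression_dataset",
    "align_gene_sets",
    "save_annotations",
    "load_annotations",
]


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the declared dialect."""


class AlignmentError(ValueError):
    """Raised when two datasets share no genes."""


#: Valid processing states for the count matrix.
STATES = ("raw", "normalized", "smoothed", "pca")


@dataclass
class ExpressionDataset:
    """A cell x gene expression matrix with optional coordinates and labels.

    Parameters
    ----------
    cells
        Unique cell identifiers, one per matrix row.
    genes
        Unique gene identifiers, one per matrix column.  When ``state`` is
        ``"pca"`` these are component names instead.
    counts
        Dense ``(n_cells, n_genes)`` float array.  Raw counts must be
        non-negative; processed states may hold arbitrary reals.
    coords
        Optional ``(n_cells, 2)`` or ``(n_cells, 3)`` physical coordinates
        in micrometres.
    labels
        Optional per-cell categorical cell type; ``None`` entries mean
        unlabeled.
    taxonomy
        Ordered list of type names; every non-missing label must appear here.
    state
        Processing-state flag: ``raw`` | ``normalized`` | ``smoothed`` |
        ``pca``.
    """

    cells: list[str]
    genes: list[str]
    counts: np.ndarray
    coords: Optional[np.ndarray] = None
    labels: Optional[list[Optional[str]]] = None
    taxonomy: list[str] = field(default_factory=list)
    state: str = "raw"

    def __post_init__(self) -> None:
        self.cells = [str(c) for c in self.cells]
        self.genes = [str(g) for g in self.genes]
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2D matrix")
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("duplicate cell identifiers")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers")
        if self.state not in STATES:
            raise ValidationError(f"unknown processing state {self.state!r}")
        if self.state == "raw" and self.counts.size and self.counts.min() < 0:
            raise ValidationError("raw counts must be non-negative")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.ndim != 2 or self.coords.shape[0] != len(self.cells):
                raise ValidationError("coords must have one row per cell")
            if self.coords.shape[1] not in (2, 3):
                raise ValidationError("coords must have 2 or 3 components")
            if not np.all(np.isfinite(self.coords)):
                raise ValidationError("coords contain non-finite entries")
        if self.labels is not None:
            if len(self.labels) != len(self.cells):
                raise ValidationError("labels must have one entry per cell")
            self.labels = [None if l is None else str(l) for l in self.labels]
            if not self.taxonomy:
                seen: list[str] = []
                for l in self.labels:
                    if l is not None and l not in seen:
                        seen.append(l)
                self.taxonomy = sorted(seen)
            missing = {l for l in self.labels if l is not None} - set(self.taxonomy)
            if missing:
                raise ValidationError(f"labels outside taxonomy: {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def with_counts(self, counts: np.ndarray, state: str) -> "ExpressionDataset":
        """Return a copy holding a new matrix and processing state."""
        return replace(self, counts=np.asarray(counts, dtype=np.float64), state=state)

    def subset_cells(self, index: np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        return ExpressionDataset(
            cells=[self.cells[i] for i in index],
            genes=list(self.genes),
            counts=self.counts[index],
            coords=None if self.coords is None else self.coords[index],
            labels=None if self.labels is None else [self.labels[i] for i in index],
            taxonomy=list(self.taxonomy),
            state=self.state,
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        return replace(
            self,
            genes=[self.genes[i] for i in index],
            counts=self.counts[:, index],
        )

    def label_indices(self) -> np.ndarray:
        """Integer label per cell (index into ``taxonomy``; -1 for missing)."""
        if self.labels is None:
            raise ValidationError("dataset has no labels")
        lut = {t: i for i, t in enumerate(self.taxonomy)}
        return np.array([-1 if l is None else lut[l] for l in self.labels])


@dataclass
class AnnotationResult:
    """Per-cell predicted types with confidence and provenance.

    ``status`` is ``assigned``, ``unassigned`` or ``new_type:<k>``; the
    latter two are produced by the new-type discovery postprocess.
    ``probs`` keeps the full per-type probability table (cells x types).
    """

    cells: list[str]
    types: list[str]
    predicted: list[str]
    max_probability: np.ndarray
    status: list[str]
    probs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.cells)
        self.max_probability = np.asarray(self.max_probability, dtype=np.float64)
        if not (len(self.predicted) == len(self.status) == self.max_probability.shape[0] == n):
            raise ValidationError("annotation fields must all have one entry per cell")
        if self.max_probability.size and (
            self.max_probability.min() < 0 or self.max_probability.max() > 1 + 1e-9
        ):
            raise ValidationError("max probabilities must lie in [0, 1]")
        valid = set(self.types)
        for p, s in zip(self.predicted, self.status):
            if not (p in valid or s.startswith("new_type:")):
                raise ValidationError(f"predicted type {p!r} outside taxonomy")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# readers


def _load_h5(path: str, coord_fields: Optional[Sequence[str]]) -> ExpressionDataset:
    import anndata as ad

    try:
        adata = ad.read_h5ad(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"cannot read HDF5 container {path}: {exc}") from exc
    X = adata.X
    if not isinstance(X, np.ndarray):
        X = X.toarray()
    coords = None
    if "spatial" in adata.obsm:
        coords = np.asarray(adata.obsm["spatial"])
    elif coord_fields:
        missing = [c for c in coord_fields if c not in adata.obs.columns]
        if missing:
            raise FormatError(f"coordinate fields {missing} not present in obs")
        coords = adata.obs[list(coord_fields)].to_numpy(dtype=float)
    labels = None
    if "cell_type" in adata.obs.columns:
        col = adata.obs["cell_type"]
        labels = [None if pd.isna(v) else str(v) for v in col]
    return ExpressionDataset(
        cells=list(map(str, adata.obs_names)),
        genes=list(map(str, adata.var_names)),
        counts=np.asarray(X, dtype=np.float64),
        coords=coords,
        labels=labels,
    )


def _load_delimited(path: str, coord_fields: Optional[Sequence[str]]) -> ExpressionDataset:
    sep = "\t" if path.endswith((".tsv", ".tab", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse delimited file {path}: {exc}") from exc
    coords = None
    labels = None
    if coord_fields:
        missing = [c for c in coord_fields if c not in df.columns]
        if missing:
            raise FormatError(
                f"declared coordinate columns {missing} missing from {path}"
            )
        coords = df[list(coord_fields)].to_numpy(dtype=float)
        df = df.drop(columns=list(coord_fields))
    if "cell_type" in df.columns:
        labels = [None if pd.isna(v) else str(v) for v in df["cell_type"]]
        df = df.drop(columns=["cell_type"])
    return ExpressionDataset(
        cells=list(map(str, df.index)),
        genes=list(map(str, df.columns)),
        counts=df.to_numpy(dtype=np.float64),
        coords=coords,
        labels=labels,
    )


def _load_triplet(path: str, coord_fields: Optional[Sequence[str]]) -> ExpressionDataset:
    """MatrixMarket matrix (cells x genes) with ``<stem>.cells.txt`` /
    ``<stem>.genes.txt`` sidecars and an optional ``<stem>.coords.tsv``."""
    from scipy.io import mmread

    stem = path
    for suffix in (".mtx", ".mm"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    try:
        m = mmread(path)
    except Exception as exc:
        raise FormatError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
    mat = np.asarray(m.todense(), dtype=np.float64) if hasattr(m, "todense") else np.asarray(m, dtype=np.float64)

    def _read_ids(p: str) -> list[str]:
        if not os.path.exists(p):
            raise FormatError(f"missing sidecar file {p}")
        with open(p) as fh:
            return [line.strip() for line in fh if line.strip()]

    cells = _read_ids(stem + ".cells.txt")
    genes = _read_ids(stem + ".genes.txt")
    coords = None
    coord_path = stem + ".coords.tsv"
    if os.path.exists(coord_path):
        cdf = pd.read_csv(coord_path, sep="\t", index_col=0)
        cols = list(coord_fields) if coord_fields else list(cdf.columns)
        missing = [c for c in cols if c not in cdf.columns]
        if missing:
            raise FormatError(f"coordinate fields {missing} missing from {coord_path}")
        coords = cdf.loc[cells, cols].to_numpy(dtype=float)
    elif coord_fields:
        raise FormatError(f"coordinate sidecar {coord_path} not found")
    return ExpressionDataset(cells=cells, genes=genes, counts=mat, coords=coords)


_READERS = {
    "h5-container": _load_h5,
    "delimited": _load_delimited,
    "sparse-triplet": _load_triplet,
}


def load_expression_dataset(
    path: str,
    format: str,
    coord_fields: Optional[Sequence[str]] = None,
) -> ExpressionDataset:
    """Load an :class:`ExpressionDataset` from disk.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``h5-container`` (``.h5ad``), ``delimited`` (CSV/TSV, cells
        as rows), ``sparse-triplet`` (MatrixMarket + id sidecars).
    coord_fields
        Column names holding spatial coordinates, in axis order.
    """
    if format not in _READERS:
        raise FormatError(f"unknown format {format!r}; choose from {sorted(_READERS)}")
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    return _READERS[format](path, coord_fields)


def save_expression_dataset(ds: ExpressionDataset, path: str) -> None:
    """Write a dataset as delimited text (round-trips with ``delimited``)."""
    df = pd.DataFrame(ds.counts, index=ds.cells, columns=ds.genes)
    if ds.coords is not None:
        for i, name in enumerate(("x", "y", "z")[: ds.coords.shape[1]]):
            df[name] = ds.coords[:, i]
    if ds.labels is not None:
        df["cell_type"] = [l if l is not None else "" for l in ds.labels]
    sep = "\t" if path.endswith((".tsv", ".tab", ".txt")) else ","
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# gene alignment


def align_gene_sets(
    reference: ExpressionDataset,
    srt: ExpressionDataset,
    markers: Optional[Sequence[str]] = None,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict both datasets to their common gene set, in a shared order.

    The common set is the exact-string intersection of the two gene lists,
    further intersected with ``markers`` when a marker-gene list is given.
    The surviving genes are ordered lexicographically so the result does not
    depend on input gene order.  Matching is case-sensitive.
    """
    common = set(reference.genes) & set(srt.genes)
    if markers is not None:
        common &= set(map(str, markers))
    if not common:
        raise AlignmentError(
            f"no shared genes between reference ({reference.n_genes} genes) "
            f"and target ({srt.n_genes} genes)"
        )
    order = sorted(common)
    ref_idx = np.array([reference.genes.index(g) for g in order])
    srt_idx = np.array([srt.genes.index(g) for g in order])
    return reference.subset_genes(ref_idx), srt.subset_genes(srt_idx)


# ---------------------------------------------------------------------------
# annotation I/O


def save_annotations(result: AnnotationResult, path: str, include_probs: bool = True) -> None:
    """Write annotations as CSV: cell_id, predicted_type, max_probability,
    status, plus one probability column per type when available."""
    data = {
        "cell_id": result.cells,
        "predicted_type": result.predicted,
        "max_probability": result.max_probability,
        "status": result.status,
    }
    df = pd.DataFrame(data)
    if include_probs and result.probs is not None:
        for j, t in enumerate(result.types):
            df[f"prob_{t}"] = result.probs[:, j]
    df.to_csv(path, index=False)


def load_annotations(path: str) -> AnnotationResult:
    df = pd.read_csv(path, dtype={"cell_id": str, "predicted_type": str, "status": str})
    prob_cols = [c for c in df.columns if c.startswith("prob_")]
    probs = df[prob_cols].to_numpy(dtype=float) if prob_cols else None
    types = [c[len("prob_"):] for c in prob_cols]
    if not types:
        types = sorted({p for p, s in zip(df["predicted_type"], df["status"]) if not s.startswith("new_type:")})
    return AnnotationResult(
        cells=list(df["cell_id"]),
        types=types,
        predicted=list(df["predicted_type"]),
        max_probability=df["max_probability"].to_numpy(dtype=float),
        status=list(df["status"]),
        probs=probs,
    )
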