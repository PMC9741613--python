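"""Evaluation metrics for spatial cell-type annotation.

Covers the quantities used to benchmark annotation quality: accuracy and
support-weighted F1 against ground truth, per-type confusion fractions,
the spatial organisation statistics *neighbourhood complexity* (distinct
types within a radius) and *neighbourhood purity* (fraction held by the
most abundant type), and the Jensen–Shannon distance between predicted and
ground-truth distributions of those statistics.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import jensenshannon

__all__ = [
    "accuracy_and_weighted_f1",
    "confusion_fractions",
    "neighborhood_metrics",
    "js_distance",
    "histogram_js",
]


def accuracy_and_weighted_f1(
    truth: Sequence[str],
    pred: Sequence[str],
    excluded_types: Optional[set[str]] = None,
) -> tuple[float, float, pd.DataFrame]:
    """Accuracy, support-weighted F1 and the per-type F1 table.

    Cells whose ground-truth type is in ``excluded_types`` are removed
    before scoring (types absent from the reference taxonomy cannot be
    predicted and would only deflate the score).  Types with zero truth
    support contribute zero weight.
    """
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must have equal length")
    if excluded_types:
        keep = ~np.isin(truth, list(excluded_types))
        truth, pred = truth[keep], pred[keep]
    if truth.size == 0:
        raise ValueError("no cells left to score after exclusion")
    from sklearn.metrics import f1_score

    acc = float(np.mean(truth == pred))
    types = sorted(set(truth) | set(pred))
    per_type = f1_score(truth, pred, labels=types, average=None, zero_division=0)
    support = np.array([(truth == t).sum() for t in types], dtype=float)
    weighted = float((per_type * support).sum() / support.sum())
    table = pd.DataFrame({"type": types, "f1": per_type, "support": support.astype(int)})
    return acc, weighted, table


def confusion_fractions(truth: Sequence[str], pred: Sequence[str]) -> pd.DataFrame:
    """Row-normalized confusion matrix: entry (t, p) is the fraction of
    truth-t cells predicted as p.  Rows with zero support are omitted."""
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    t_types = sorted(t for t in set(truth))
    p_types = sorted(set(truth) | set(pred))
    mat = np.zeros((len(t_types), len(p_types)))
    pidx = {t: j for j, t in enumerate(p_types)}
    for i, t in enumerate(t_types):
        rows = truth == t
        n = rows.sum()
        for p in pred[rows]:
            mat[i, pidx[p]] += 1
        mat[i] /= n
    return pd.DataFrame(mat, index=t_types, columns=p_types)


def neighborhood_metrics(
    coords: np.ndarray,
    labels: Sequence[str],
    radius: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell neighbourhood complexity and purity within ``radius`` µm.

    The neighbourhood of a cell is every cell (itself included) within
    Euclidean distance ``radius``.  Complexity counts distinct types
    present; purity is the share of the most abundant type.  An isolated
    cell therefore has complexity 1 and purity 1.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    codes = pd.factorize(labels)[0]
    n_types = codes.max() + 1
    tree = cKDTree(coords)
    neighbors = tree.query_ball_point(coords, r=radius)
    complexity = np.empty(len(labels), dtype=np.int64)
    purity = np.empty(len(labels))
    for i, idx in enumerate(neighbors):
        counts = np.bincount(codes[idx], minlength=n_types)
        complexity[i] = int((counts > 0).sum())
        purity[i] = counts.max() / len(idx)
    return complexity, purity


def js_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon distance (base-2 logs) between two distributions.

    The square root of the JS divergence; lies in [0, 1] and is a metric.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("distributions must share support")
    for name, d in (("p", p), ("q", q)):
        if abs(d.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} does not sum to 1")
    return float(jensenshannon(p, q, base=2))


def histogram_js(
    values_a: np.ndarray,
    values_b: np.ndarray,
    kind: str = "purity",
) -> float:
    """JS distance between histograms of a neighbourhood statistic.

    ``kind='complexity'`` uses shared integer bins; ``kind='purity'`` uses
    20 equal bins on [0, 1].
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if kind == "complexity":
        hi = int(max(a.max(), b.max()))
        bins = np.arange(0.5, hi + 1.5)
    elif kind == "purity":
        bins = np.linspace(0.0, 1.0, 21)
    else:
        raise ValueError("kind must be 'complexity' or 'purity'")
    ha, _ = np.histogram(a, bins=bins)
    hb, _ = np.histogram(b, bins=bins)
    return js_distance(ha / ha.sum(), hb / hb.sum())
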