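"""Stage 1: reference-trained classifier and pseudo-label generation.

A feed-forward network (four hidden blocks of affine -> GELU -> dropout,
then an affine output head) is trained on the labeled scRNA-seq reference
with focal loss, which down-weights easy examples and so tempers cell-type
class imbalance.  Applied to the spatial dataset, the network yields a
probability distribution ``D`` over reference types per cell; softening the
logits ``Y`` with a temperature ``T > 1``,

    l_i = exp(y_i / T) / sum_j exp(y_j / T),

produces pseudo-labels ``L`` that retain inter-class similarity structure
(``L = D`` at ``T = 1``).  These soft targets supervise the stage-2 graph
model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import _nn
from .datasets import ExpressionDataset, ValidationError

__all__ = [
    "DnnConfig",
    "ProbabilityTable",
    "DnnModel",
    "focal_loss",
    "train_dnn",
    "predict_probabilities",
    "generate_pseudo_labels",
]


@dataclass
class ProbabilityTable:
    """Per-cell probability distribution over the reference taxonomy.

    ``kind`` distinguishes the raw classifier distribution ``D`` from
    temperature-softened pseudo-labels ``L``; ``logits`` keeps the
    pre-softmax scores ``Y`` when available so re-softening is exact.
    """

    cells: list[str]
    types: list[str]
    probs: np.ndarray
    logits: Optional[np.ndarray] = None
    temperature: float = 1.0
    kind: str = "distribution"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (len(self.cells), len(self.types)):
            raise ValidationError("probability table shape mismatch")
        rows = self.probs.sum(axis=1)
        if self.probs.size and (
            self.probs.min() < -1e-12 or np.abs(rows - 1).max() > 1e-6
        ):
            raise ValidationError("probability rows must be distributions summing to 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class DnnConfig:
    """Hyper-parameters of the stage-1 classifier.

    ``input_dropout`` drives a training-time augmentation that mimics the
    gene dropout of spatial platforms: per batch, a random fraction of
    features (drawn uniformly from [0, 2 * input_dropout]) is zeroed and
    each row re-normalized to unit length — the same transform
    preprocessing applies to a dropout-thinned count vector.  Without it
    the reference-trained classifier faces a domain shift on sparse target
    data and tends to collapse whole types onto a sink class.
    """

    hidden: tuple[int, int, int, int] = (1024, 512, 256, 128)
    dropout: float = 0.2
    input_dropout: float = 0.3
    gamma: float = 2.0          # focal-loss focusing exponent
    alpha: float = 1.0          # focal-loss scale
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden) != 4 or any(h <= 0 for h in self.hidden):
            raise ValueError("hidden must be 4 positive layer widths")
        if not 0 <= self.dropout < 1 or not 0 <= self.input_dropout < 1:
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def focal_loss(probs: np.ndarray, labels: np.ndarray, gamma: float = 2.0,
               alpha: float = 1.0) -> float:
    """Mean focal loss  -alpha * (1 - p_t)^gamma * log(p_t)  over samples.

    ``probs`` holds one predicted distribution per row; ``labels`` the true
    class index per row.  At ``gamma = 0, alpha = 1`` this reduces to plain
    cross-entropy.  ``p_t`` is clamped at 1e-12 for numerical safety.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    pt = np.clip(probs[np.arange(len(labels)), labels], 1e-12, 1.0)
    return float(np.mean(-alpha * (1.0 - pt) ** gamma * np.log(pt)))


def _focal_grad(logits: np.ndarray, labels: np.ndarray, gamma: float,
                alpha: float) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. logits, chained through the softmax."""
    n = logits.shape[0]
    p = _nn.softmax(logits)
    rows = np.arange(n)
    pt = np.clip(p[rows, labels], 1e-12, 1.0)
    one_m = 1.0 - pt
    loss = float(np.mean(-alpha * one_m ** gamma * np.log(pt)))
    # dL/dp_t; other entries of dL/dp are zero
    dpt = -alpha * (one_m ** gamma / pt
                    - gamma * np.where(one_m > 0, one_m ** np.maximum(gamma - 1, 0), 0.0) * np.log(pt))
    if gamma == 0:
        dpt = -alpha / pt
    # softmax Jacobian: dL/dy_j = dpt * p_t * (delta_tj - p_j)
    g = -(dpt * pt)[:, None] * p
    g[rows, labels] += dpt * pt
    return loss, g / n


@dataclass
class DnnModel:
    """Trained stage-1 classifier plus the metadata stage 3 needs to verify
    compatibility: gene list, taxonomy and the preprocessing recipe."""

    net: _nn.Sequential
    config: DnnConfig
    genes: list[str]
    taxonomy: list[str]
    preprocessing: dict = field(default_factory=dict)
    loss_history: list[float] = field(default_factory=list)

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.genes):
            raise ValidationError(
                f"input has {X.shape[1]} features, model expects {len(self.genes)}"
            )
        return self.net.forward(np.asarray(X, dtype=np.float64), train=False, rng=None)

    def save(self, path: str) -> None:
        arrays = _nn.state_dict([self.net])
        meta = {
            "config": asdict(self.config),
            "genes": self.genes,
            "taxonomy": self.taxonomy,
            "preprocessing": self.preprocessing,
            "loss_history": self.loss_history,
        }
        np.savez(path, meta=json.dumps(meta), n_arrays=len(arrays),
                 **{f"arr{i}": a for i, a in enumerate(arrays)})

    @classmethod
    def load(cls, path: str) -> "DnnModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            arrays = [z[f"arr{i}"] for i in range(int(z["n_arrays"]))]
        cfg = DnnConfig(**{**meta["config"], "hidden": tuple(meta["config"]["hidden"])})
        model = cls(
            net=_build_net(len(meta["genes"]), len(meta["taxonomy"]), cfg),
            config=cfg,
            genes=meta["genes"],
            taxonomy=meta["taxonomy"],
            preprocessing=meta["preprocessing"],
            loss_history=list(meta["loss_history"]),
        )
        _nn.load_state([model.net], arrays)
        return model


def _augment_gene_dropout(X: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Training-time augmentation reproducing the target-domain transform:
    zero a random subset of features, then re-normalize each row to unit L2
    (exactly what preprocessing does to a dropout-thinned count vector)."""
    mask = rng.random(X.shape) >= rate
    out = X * mask
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    return out / np.where(norms == 0, 1.0, norms)


def _build_net(n_in: int, n_classes: int, cfg: DnnConfig) -> _nn.Sequential:
    rng = np.random.default_rng(cfg.seed)
    layers: list[_nn.Layer] = []
    prev = n_in
    for width in cfg.hidden:
        layers += [_nn.Linear(prev, width, rng), _nn.GELU(), _nn.Dropout(cfg.dropout)]
        prev = width
    layers.append(_nn.Linear(prev, n_classes, rng))
    return _nn.Sequential(*layers)


def train_dnn(reference: ExpressionDataset, config: Optional[DnnConfig] = None) -> DnnModel:
    """Train the stage-1 classifier on the labeled reference.

    Mini-batched Adam with focal loss; the loss trajectory is recorded and
    training is exactly reproducible for a given ``config.seed``.  With
    ``epochs = 0`` the returned state is the (seeded) initialization.
    """
    config = config or DnnConfig()
    if reference.labels is None or len(reference.taxonomy) < 2:
        raise ValidationError("reference must carry labels with at least 2 classes")
    if reference.state not in ("normalized", "pca", "smoothed"):
        raise ValidationError(
            f"reference must be preprocessed before training (state {reference.state!r})"
        )
    X = reference.counts
    y = reference.label_indices()
    if (y < 0).any():
        keep = y >= 0
        X, y = X[keep], y[keep]
    n_classes = len(reference.taxonomy)
    net = _build_net(X.shape[1], n_classes, config)
    model = DnnModel(
        net=net,
        config=config,
        genes=list(reference.genes),
        taxonomy=list(reference.taxonomy),
        preprocessing={"state": reference.state},
    )
    if config.epochs == 0:
        return model
    rng = np.random.default_rng(config.seed + 1)
    opt = _nn.Adam(net.params(), lr=config.lr)
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            Xb = X[idx]
            if config.input_dropout > 0:
                # rate varies per batch so the classifier tolerates a range
                # of platform dropout levels, not one calibrated value
                rate = rng.uniform(0.0, 2.0 * config.input_dropout)
                Xb = _augment_gene_dropout(Xb, rate, rng)
            logits = net.forward(Xb, train=True, rng=rng)
            loss, g = _focal_grad(logits, y[idx], config.gamma, config.alpha)
            if not np.isfinite(loss):
                raise FloatingPointError(f"focal loss diverged at epoch {epoch}")
            net.backward(g)
            opt.step(net.grads())
            epoch_loss += loss * len(idx)
        model.loss_history.append(epoch_loss / n)
    return model


def predict_probabilities(model: DnnModel, srt: ExpressionDataset) -> ProbabilityTable:
    """Classifier distribution ``D`` (with logits ``Y``) for every cell.

    Runs in evaluation mode (dropout disabled), so repeated calls are
    identical.  The target's gene list must match the model's exactly.
    """
    if list(srt.genes) != list(model.genes):
        raise ValidationError(
            f"gene space mismatch: model expects {len(model.genes)} genes, "
            f"target provides {srt.n_genes}; align gene sets first"
        )
    logits = model.predict_logits(srt.counts)
    return ProbabilityTable(
        cells=list(srt.cells),
        types=list(model.taxonomy),
        probs=_nn.softmax(logits),
        logits=logits,
        temperature=1.0,
        kind="distribution",
    )


def generate_pseudo_labels(table: ProbabilityTable, T: float = 2.0) -> ProbabilityTable:
    """Soften a classifier distribution into pseudo-labels at temperature T.

    Uses the stored logits when present; otherwise recovers them as
    ``log D`` (re-softmaxing log D at T = 1 returns D exactly).  Computed
    with the max-subtraction trick for stability.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    logits = table.logits
    if logits is None:
        logits = np.log(np.clip(table.probs, 1e-300, None))
    z = logits / T
    return ProbabilityTable(
        cells=list(table.cells),
        types=list(table.types),
        probs=_nn.softmax(z),
        logits=logits,
        temperature=T,
        kind="pseudo-labels",
    )
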