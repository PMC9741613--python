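"""Stages 2–3: joint autoencoder + variational graph autoencoder + classifier.

The spatial dataset's expression matrix ``I`` is encoded by a two-layer
autoencoder into a gene representation ``X``.  A variational graph
autoencoder (VGAE) over the spatial neighbour graph embeds each cell's
neighbourhood: two graph convolutions produce variational parameters
``mu`` and ``log sigma^2``, and the spatial embedding is sampled by the
reparameterization trick

    S = mu + sigma * tau,   tau ~ N(0, 1).

The combined latent is ``Z = X + S``.  ``Z`` drives three reconstruction /
supervision signals optimized jointly with Adam:

* expression: MSE between ``I`` and the decoded ``I'``;
* graph: weighted binary cross-entropy between the binarized adjacency and
  the inner-product decoder ``A' = logistic(Z Z^T)``;
* prior: KL divergence pulling ``q(S | X, A)`` toward ``N(0, 1)``;
* labels: soft-target cross-entropy between the classifier output ``Q``
  (one affine layer + softmax on ``Z``) and the stage-1 pseudo-labels ``L``.

Stage 3 reloads the checkpoint with the lowest total training loss and
annotates with ``tau = 0`` (so ``S = mu``), making inference deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import scipy.sparse as sp

from . import _nn
from .datasets import AnnotationResult, ExpressionDataset, ValidationError
from .graph import SpatialGraph
from .transfer import ProbabilityTable

__all__ = [
    "GcnConfig",
    "LatentState",
    "JointModel",
    "autoencoder_forward",
    "vgae_encode",
    "reconstruct_adjacency",
    "total_loss",
    "train_stage2",
    "annotate",
    "latent_features",
]


@dataclass
class GcnConfig:
    """Hyper-parameters of the joint stage-2 model.

    ``ae_hidden`` are the two encoder widths; the second one is the shared
    latent width of ``X``, ``S`` and ``Z`` (they must match for the sum
    ``Z = X + S``).  ``vgae_hidden`` is the width of the first graph
    convolution.  ``weights`` are the four loss weights
    (w_ae, w_graph, w_kl, w_cls).  ``spatial=False`` ablates the VGAE
    branch entirely (S = 0, graph and KL terms dropped), leaving a
    pseudo-label-supervised classifier on ``X``.
    """

    ae_hidden: tuple[int, int] = (256, 64)
    vgae_hidden: int = 32
    dropout: float = 0.0
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    temperature: float = 2.0
    lr: float = 1e-3
    epochs: int = 200
    seed: int = 0
    spatial: bool = True

    def __post_init__(self) -> None:
        if len(self.ae_hidden) != 2 or any(h <= 0 for h in self.ae_hidden):
            raise ValueError("ae_hidden must be 2 positive widths")
        if self.vgae_hidden <= 0:
            raise ValueError("vgae_hidden must be positive")
        if any(w < 0 for w in self.weights):
            raise ValueError("loss weights must be non-negative")

    @property
    def latent(self) -> int:
        return self.ae_hidden[1]


@dataclass
class LatentState:
    """All per-cell latent arrays from one forward pass (shared shape)."""

    X: np.ndarray
    S: np.ndarray
    Z: np.ndarray
    mu: np.ndarray
    log_var: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.X, self.S, self.Z, self.mu, self.log_var, self.tau)}
        if len(shapes) != 1:
            raise ValidationError(f"latent arrays disagree in shape: {shapes}")


class _GraphConv(_nn.Layer):
    """Sparse graph convolution H' = A_hat (H W) + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.A: Optional[sp.csr_matrix] = None  # set before forward

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train, rng):
        self._x = x
        return self.A @ (x @ self.W) + self.b

    def backward(self, g):
        ag = self.A.T @ g
        self.dW[...] = self._x.T @ ag
        self.db[...] = g.sum(axis=0)
        return ag @ self.W.T


def reconstruct_adjacency(Z: np.ndarray) -> np.ndarray:
    """Inner-product decoder: A' = logistic(Z Z^T), entries in (0, 1)."""
    Z = np.asarray(Z, dtype=np.float64)
    if not np.all(np.isfinite(Z)):
        raise ValueError("latent matrix contains non-finite values")
    from scipy.special import expit

    return expit(Z @ Z.T)


def _kl_term(mu: np.ndarray, log_var: np.ndarray) -> float:
    """Gaussian KL to the standard-normal prior, averaged over cells:
    (-0.5 / n) * sum(1 + log sigma^2 - mu^2 - sigma^2)."""
    n = mu.shape[0]
    return float(-0.5 / n * np.sum(1.0 + log_var - mu ** 2 - np.exp(log_var)))


def _bce_weighted(target: np.ndarray, probs: np.ndarray) -> float:
    """Mean binary cross-entropy with positive-class reweighting.

    ``target`` is the binarized adjacency (1 where an edge exists); the
    positive class is up-weighted by #non-edges / #edges so the sparse
    edge set is not swamped.
    """
    n_pos = target.sum()
    n_tot = target.size
    pos_w = (n_tot - n_pos) / max(n_pos, 1.0)
    p = np.clip(probs, 1e-12, 1 - 1e-12)
    terms = pos_w * target * (-np.log(p)) + (1.0 - target) * (-np.log(1.0 - p))
    return float(terms.mean())


def total_loss(
    I: np.ndarray,
    I_prime: np.ndarray,
    A: sp.spmatrix | np.ndarray,
    A_prime: np.ndarray,
    mu: np.ndarray,
    log_var: np.ndarray,
    pseudo_labels: np.ndarray,
    classifier_probs: np.ndarray,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> tuple[float, dict[str, float]]:
    """Total stage-2 loss and its per-term breakdown.

    total = w_ae * MSE(I, I') + w_graph * BCE(binarize(A), A')
          + w_kl * KL(q || N(0,1)) + w_cls * CE(L, Q)
    """
    w_ae, w_graph, w_kl, w_cls = weights
    A_dense = A.toarray() if sp.issparse(A) else np.asarray(A)
    target = (A_dense > 0).astype(np.float64)
    n = I.shape[0]
    mse = float(np.mean((I - I_prime) ** 2))
    bce = _bce_weighted(target, A_prime)
    kl = _kl_term(mu, log_var)
    q = np.clip(classifier_probs, 1e-12, None)
    ce = float(-np.sum(pseudo_labels * np.log(q)) / n)
    terms = {"ae": mse, "graph": bce, "kl": kl, "cls": ce}
    total = w_ae * mse + w_graph * bce + w_kl * kl + w_cls * ce
    for name, val in terms.items():
        if not np.isfinite(val):
            raise FloatingPointError(f"loss term {name!r} is non-finite")
    return float(total), terms


class JointModel:
    """Autoencoder + VGAE + classifier with manually wired backprop."""

    def __init__(self, n_genes: int, n_classes: int, config: GcnConfig):
        self.config = config
        self.n_genes = n_genes
        self.n_classes = n_classes
        rng = np.random.default_rng(config.seed)
        h1, latent = config.ae_hidden
        d = config.dropout
        self.encoder = _nn.Sequential(
            _nn.Linear(n_genes, h1, rng), _nn.BatchNorm(h1), _nn.ELU(), _nn.Dropout(d),
            _nn.Linear(h1, latent, rng), _nn.BatchNorm(latent), _nn.ELU(), _nn.Dropout(d),
        )
        self.decoder = _nn.Linear(latent, n_genes, rng)
        self.gc1 = _GraphConv(latent, config.vgae_hidden, rng)
        self.gc_relu = _nn.ReLU()
        self.gc_drop = _nn.Dropout(d)
        self.gc_mu = _GraphConv(config.vgae_hidden, latent, rng)
        self.gc_lv = _GraphConv(config.vgae_hidden, latent, rng)
        self.cls = _nn.Linear(latent, n_classes, rng)
        # metadata filled by train_stage2 for checkpoint compatibility checks
        self.genes: list[str] = []
        self.taxonomy: list[str] = []
        self.graph_params: dict = {}
        self.loss_log: list[dict[str, float]] = []

    # -- plumbing ----------------------------------------------------------

    def _modules(self) -> list[_nn.Layer]:
        return [self.encoder, self.decoder, self.gc1, self.gc_mu, self.gc_lv, self.cls]

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def grads(self):
        return [g for m in self._modules() for g in m.grads()]

    def snapshot(self):
        return _nn.state_dict(self._modules())

    def restore(self, state):
        _nn.load_state(self._modules(), state)

    # -- forward -----------------------------------------------------------

    def encode_expression(self, I: np.ndarray, train: bool = False,
                          rng: Optional[np.random.Generator] = None) -> np.ndarray:
        if I.shape[1] != self.n_genes:
            raise ValidationError(
                f"input has {I.shape[1]} features, model expects {self.n_genes}")
        return self.encoder.forward(np.asarray(I, dtype=np.float64), train, rng)

    def encode_graph(self, X: np.ndarray, graph: SpatialGraph,
                     tau: Optional[np.ndarray] = None, train: bool = False,
                     rng: Optional[np.random.Generator] = None) -> LatentState:
        if graph.n_cells != X.shape[0]:
            raise ValidationError(
                f"graph has {graph.n_cells} cells but X has {X.shape[0]} rows")
        A_hat = graph.normalized()
        self.gc1.A = self.gc_mu.A = self.gc_lv.A = A_hat
        h = self.gc1.forward(X, train, rng)
        h = self.gc_relu.forward(h, train, rng)
        h = self.gc_drop.forward(h, train, rng)
        mu = self.gc_mu.forward(h, train, rng)
        log_var = self.gc_lv.forward(h, train, rng)
        if tau is None:
            tau = np.zeros_like(mu)
        S = mu + np.exp(0.5 * log_var) * tau
        return LatentState(X=X, S=S, Z=X + S, mu=mu, log_var=log_var, tau=tau)

    def classify(self, Z: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.cls.forward(Z, False, None))

    # -- training ----------------------------------------------------------

    def _train_epoch(self, I, target_adj, L, opt, rng, pos_w):
        """One full-graph optimization step; returns the loss breakdown."""
        cfg = self.config
        w_ae, w_graph, w_kl, w_cls = cfg.weights
        n, d = I.shape[0], cfg.latent
        X = self.encoder.forward(I, True, rng)
        if cfg.spatial:
            tau = rng.standard_normal((n, d))
            h = self.gc1.forward(X, True, rng)
            h = self.gc_relu.forward(h, True, rng)
            h = self.gc_drop.forward(h, True, rng)
            mu = self.gc_mu.forward(h, True, rng)
            log_var = self.gc_lv.forward(h, True, rng)
            sig = np.exp(0.5 * log_var)
            S = mu + sig * tau
            Z = X + S
        else:
            mu = np.zeros((n, d)); log_var = np.zeros((n, d)); S = np.zeros((n, d))
            Z = X
        I_prime = self.decoder.forward(Z, True, rng)
        logits_q = self.cls.forward(Z, True, rng)
        log_q = _nn.log_softmax(logits_q)
        Q = np.exp(log_q)

        mse = float(np.mean((I - I_prime) ** 2))
        ce = float(-np.sum(L * log_q) / n)
        dZ = np.zeros_like(Z)
        # expression branch
        dIp = w_ae * 2.0 * (I_prime - I) / I.size
        dZ += self.decoder.backward(dIp)
        # classifier branch
        dlogits = w_cls * (Q - L) / n
        dZ += self.cls.backward(dlogits)
        terms = {"ae": mse, "cls": ce, "graph": 0.0, "kl": 0.0}
        if cfg.spatial:
            if w_graph > 0:
                # graph branch via logits P = Z Z^T, BCE-with-logits computed
                # densely in float32 with a sparse correction on the edge set
                # (softplus(x) = max(x,0) + log1p(exp(-|x|)))
                ei, ej = target_adj  # precomputed edge index arrays
                Z32 = Z.astype(np.float32)
                P = Z32 @ Z32.T
                with np.errstate(over="ignore"):
                    sig_p = 1.0 / (1.0 + np.exp(-P))
                softplus = np.maximum(P, 0.0) + np.log1p(np.exp(-np.abs(P)))
                size = float(P.size)
                pe = P[ei, ej]
                spe = softplus[ei, ej]
                bce = float(softplus.sum() - spe.sum()
                            + pos_w * (spe - pe).sum()) / size
                G = sig_p
                G[ei, ej] = pos_w * (sig_p[ei, ej] - 1.0)
                dZ += (w_graph / size) * ((G + G.T) @ Z32).astype(np.float64)
                terms["graph"] = bce
            terms["kl"] = _kl_term(mu, log_var)
            dS = dZ
            dmu = dS + w_kl * mu / n
            dlv = dS * tau * 0.5 * sig + w_kl * (-0.5 / n) * (1.0 - np.exp(log_var))
            dh = self.gc_mu.backward(dmu) + self.gc_lv.backward(dlv)
            dh = self.gc_drop.backward(dh)
            dh = self.gc_relu.backward(dh)
            dX = dZ + self.gc1.backward(dh)
        else:
            dX = dZ
        self.encoder.backward(dX)
        total = (w_ae * terms["ae"] + w_graph * terms["graph"]
                 + w_kl * terms["kl"] + w_cls * terms["cls"])
        if not np.isfinite(total):
            bad = [k for k, v in terms.items() if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite loss terms {bad}")
        opt.step(self.grads())
        terms["total"] = total
        return terms

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        arrays = self.snapshot()
        meta = {
            "config": asdict(self.config),
            "n_genes": self.n_genes,
            "n_classes": self.n_classes,
            "genes": self.genes,
            "taxonomy": self.taxonomy,
            "graph_params": self.graph_params,
        }
        np.savez(path, meta=json.dumps(meta), n_arrays=len(arrays),
                 **{f"arr{i}": a for i, a in enumerate(arrays)})

    @classmethod
    def load(cls, path: str) -> "JointModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            arrays = [z[f"arr{i}"] for i in range(int(z["n_arrays"]))]
        c = meta["config"]
        cfg = GcnConfig(**{**c, "ae_hidden": tuple(c["ae_hidden"]),
                           "weights": tuple(c["weights"])})
        model = cls(meta["n_genes"], meta["n_classes"], cfg)
        model.restore(arrays)
        model.genes = meta["genes"]
        model.taxonomy = meta["taxonomy"]
        model.graph_params = meta["graph_params"]
        return model


# ---------------------------------------------------------------------------
# functional surface


def autoencoder_forward(I: np.ndarray, model: JointModel) -> tuple[np.ndarray, np.ndarray]:
    """Standalone autoencoder pass: X from the encoder, I' decoded from X.

    Evaluation mode (deterministic).  During joint training the decoder
    instead reconstructs from the combined latent Z.
    """
    X = model.encode_expression(I, train=False)
    I_prime = model.decoder.forward(X, False, None)
    return X, I_prime


def vgae_encode(X: np.ndarray, graph: SpatialGraph, model: JointModel,
                tau: Optional[np.ndarray] = None,
                rng: Optional[np.random.Generator] = None) -> LatentState:
    """VGAE pass: mu / log sigma^2 heads and the reparameterized S.

    ``tau=None`` with an ``rng`` samples fresh standard-normal noise;
    ``tau=None`` without an rng uses tau = 0 (deterministic mean embedding).
    """
    if tau is None and rng is not None:
        tau = rng.standard_normal((X.shape[0], model.config.latent))
    return model.encode_graph(X, graph, tau=tau, train=False)


def train_stage2(
    srt: ExpressionDataset,
    graph: SpatialGraph,
    pseudo_labels: ProbabilityTable,
    config: Optional[GcnConfig] = None,
    log_path: Optional[str] = None,
) -> JointModel:
    """Full-graph joint training; keeps the checkpoint with minimum loss.

    All cells participate in every optimization step (the graph convolution
    is sparse).  Per-epoch loss breakdowns are recorded (optionally to a
    TSV) and the parameter snapshot with the lowest total loss is restored
    before returning, so the caller receives the optimal model.
    """
    config = config or GcnConfig()
    if len(pseudo_labels.cells) != srt.n_cells:
        raise ValidationError(
            f"pseudo-labels cover {len(pseudo_labels.cells)} cells, "
            f"dataset has {srt.n_cells}")
    if graph.n_cells != srt.n_cells:
        raise ValidationError("graph size does not match dataset")
    model = JointModel(srt.n_genes, len(pseudo_labels.types), config)
    model.genes = list(srt.genes)
    model.taxonomy = list(pseudo_labels.types)
    model.graph_params = {"n_neighbors": graph.n_neighbors, "theta": graph.theta}
    if config.epochs == 0:
        return model
    I = np.asarray(srt.counts, dtype=np.float64)
    L = pseudo_labels.probs
    A_hat = graph.normalized()
    model.gc1.A = model.gc_mu.A = model.gc_lv.A = A_hat
    coo = graph.adjacency.tocoo()
    edges = (coo.row.copy(), coo.col.copy())
    n_pos = coo.nnz
    pos_w = (srt.n_cells ** 2 - n_pos) / max(n_pos, 1.0)
    rng = np.random.default_rng(config.seed + 1)
    opt = _nn.Adam(model.params(), lr=config.lr)
    best = (np.inf, None)
    for epoch in range(config.epochs):
        terms = model._train_epoch(I, edges, L, opt, rng, pos_w)
        model.loss_log.append(terms)
        if terms["total"] < best[0]:
            best = (terms["total"], model.snapshot())
    if best[1] is not None:
        model.restore(best[1])
    if log_path:
        import pandas as pd

        pd.DataFrame(model.loss_log).to_csv(log_path, sep="\t", index_label="epoch")
    return model


def annotate(model: JointModel, srt: ExpressionDataset, graph: SpatialGraph) -> AnnotationResult:
    """Stage-3 inference: deterministic annotation of every cell.

    Runs the joint model in evaluation mode with tau = 0 (S = mu), takes
    the classifier's argmax as the predicted type and records the maximum
    probability c_s per cell.
    """
    if model.genes and list(srt.genes) != list(model.genes):
        raise ValidationError(
            f"checkpoint incompatible: expects genes {model.genes[:5]}..., "
            f"got {srt.genes[:5]}...")
    X = model.encode_expression(srt.counts, train=False)
    if model.config.spatial:
        state = model.encode_graph(X, graph, tau=None, train=False)
        Z = state.Z
    else:
        Z = X
    Q = model.classify(Z)
    pred_idx = Q.argmax(axis=1)
    c_s = Q[np.arange(len(pred_idx)), pred_idx]
    types = model.taxonomy or [str(i) for i in range(model.n_classes)]
    return AnnotationResult(
        cells=list(srt.cells),
        types=list(types),
        predicted=[types[i] for i in pred_idx],
        max_probability=c_s,
        status=["assigned"] * srt.n_cells,
        probs=Q,
    )


def latent_features(model: JointModel, srt: ExpressionDataset, graph: SpatialGraph) -> np.ndarray:
    """Deterministic combined latent Z used by discovery (tau = 0)."""
    X = model.encode_expression(srt.counts, train=False)
    if model.config.spatial:
        return model.encode_graph(X, graph, tau=None, train=False).Z
    return X
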