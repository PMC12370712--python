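"""Decoupled hypergraph classifier with adaptive retention of underlying features.

The model separates feature propagation from feature transformation.  Node
features ``X0`` (the fused multimodal table) are first smoothed by ``L``
applications of the aggregator ``G``; a learnable per-node gate then adds back
a sigmoid-scaled copy of the raw features to counter oversmoothing:

    H = G^L X0 + diag(sigmoid(R)) X0

``H`` feeds a two-layer fully connected head (hidden width 128, ReLU, dropout
0.5 before each layer) whose output width equals the number of classes.
Training is transductive and full-batch: the hypergraph and propagation cover
all nodes, the cross-entropy loss is computed on train-mask nodes only, and
``R``, both weight matrices and biases are optimized jointly with Adam
(lr 1e-3, weight decay 5e-4, lr multiplied by 0.7 every 200 epochs, 600
epochs).  Gradients are computed in closed form; everything is NumPy, so a
fixed seed makes training bit-reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .construction import (
    ModalityFeatureTable,
    MultimodalDataset,
    TRAIN,
    fuse_modalities,
)
from .convolution import PropagationOperator, propagate, spectral_operator, spatial_operator
from .hypergraph import Hypergraph, clique_expand

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "HGCNModel",
    "adaptive_combine",
    "forward",
    "train",
    "predict",
    "build_operator",
    "gcn_operator",
    "save_model",
    "load_model",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule and architecture hyperparameters."""

    lr: float = 0.001
    epochs: int = 600
    weight_decay: float = 0.0005
    lr_decay_factor: float = 0.7
    lr_decay_every: int = 200
    hidden_dim: int = 128
    dropout: float = 0.5
    n_propagation_layers: int = 2
    operator_kind: str = "spectral"
    adaptive_gate: bool = True
    static_gate_value: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.lr, self.weight_decay, self.lr_decay_factor) < 0:
            raise ValueError("rates must be nonnegative")
        if self.operator_kind not in ("spectral", "spatial", "gcn"):
            raise ValueError(f"unknown operator kind {self.operator_kind!r}")


@dataclass
class TrainHistory:
    loss: np.ndarray
    final_train_accuracy: float
    wallclock_seconds: float


@dataclass
class HGCNModel:
    """Trained parameters: per-node gate R, two FC layers, and the run config."""

    R: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    config: TrainConfig
    node_ids: tuple[str, ...]
    n_classes: int
    trained: bool = False

    def gate(self) -> np.ndarray:
        """Per-node retention weight: sigmoid(R), or the static constant."""
        if self.config.adaptive_gate:
            return _sigmoid(self.R)
        return np.full(self.R.shape, self.config.static_gate_value)


def adaptive_combine(
    op: PropagationOperator,
    X0: np.ndarray,
    L: int,
    R: np.ndarray,
    sigma2=_sigmoid,
) -> np.ndarray:
    """``G^L X0 + diag(sigma2(R)) X0`` — propagated plus gated raw features."""
    X0 = np.asarray(X0, dtype=float)
    R = np.asarray(R, dtype=float)
    if X0.shape[0] != op.n_nodes or R.shape != (op.n_nodes,):
        raise ValueError("X0 rows and R length must equal operator size")
    return propagate(op, X0, L) + sigma2(R)[:, None] * X0


def _head(model: HGCNModel, H, training, rng):
    p = model.config.dropout
    if training and p > 0:
        if rng is None:
            raise ValueError("training-mode forward requires an rng")
        H = H * (rng.random(H.shape) >= p) / (1.0 - p)
    Z1 = H @ model.W1 + model.b1
    A1 = np.maximum(Z1, 0.0)
    if training and p > 0:
        A1 = A1 * (rng.random(A1.shape) >= p) / (1.0 - p)
    return A1 @ model.W2 + model.b2


def forward(
    model: HGCNModel,
    op: PropagationOperator,
    X0: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class-score matrix ``|Q| x C``; evaluation mode is deterministic."""
    if model.config.adaptive_gate:
        gate = _sigmoid(model.R)
    else:
        gate = np.full(model.R.shape, model.config.static_gate_value)
    H = propagate(op, np.asarray(X0, dtype=float), model.config.n_propagation_layers)
    H = H + gate[:, None] * np.asarray(X0, dtype=float)
    return _head(model, H, training, rng)


def build_operator(h: Hypergraph, kind: str) -> PropagationOperator:
    if kind == "spectral":
        return spectral_operator(h)
    if kind == "spatial":
        return spatial_operator(h)
    if kind == "gcn":
        return gcn_operator(h)
    raise ValueError(f"unknown operator kind {kind!r}")


def gcn_operator(h: Hypergraph) -> PropagationOperator:
    """Clique-expansion baseline: ``D^{-1/2} (A + I) D^{-1/2}`` on the expanded graph."""
    A = clique_expand(h).adjacency + np.eye(h.n_nodes)
    d = A.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return PropagationOperator(kind="gcn", matrix=dinv[:, None] * A * dinv[None, :])


def _standardized_tables(dataset: MultimodalDataset, fit_mask: np.ndarray):
    """Z-score every modality with train-fold statistics (population std)."""
    out = []
    for t in dataset.tables:
        mu = t.features[fit_mask].mean(axis=0)
        sd = t.features[fit_mask].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        out.append(ModalityFeatureTable(
            t.modality_name, t.node_ids, (t.features - mu) / sd, t.feature_names))
    return MultimodalDataset(tuple(out), dataset.labels, dataset.split_mask)


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite."""


def train(
    dataset: MultimodalDataset,
    config: TrainConfig,
    Z_per_modality,
) -> tuple[HGCNModel, TrainHistory, PropagationOperator, np.ndarray]:
    """Transductive training over the fused KNN hypergraph.

    Modality tables are z-scored with train-mask statistics, the per-modality
    KNN hypergraphs are built over *all* nodes and fused, and the classifier
    is fit by full-batch Adam on the train-mask cross-entropy.  Returns the
    model, its history, the propagation operator and the fused feature
    matrix (the latter two so callers can score test nodes).
    """
    train_mask = dataset.mask(TRAIN)
    if train_mask.sum() < 2:
        raise ValueError("need >= 2 training nodes")
    y = dataset.labels
    if len(np.unique(y[train_mask])) < 2:
        raise ValueError("training set must contain >= 2 classes")
    C = dataset.n_classes

    std = _standardized_tables(dataset, train_mask)
    X0, h = fuse_modalities(std, Z_per_modality)
    op = build_operator(h, config.operator_kind)

    n, d_in = X0.shape
    rng = np.random.default_rng(config.seed)
    dh = config.hidden_dim

    def fan_in_uniform(fan_in, shape):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    model = HGCNModel(
        R=np.zeros(n),
        W1=fan_in_uniform(d_in, (d_in, dh)),
        b1=np.zeros(dh),
        W2=fan_in_uniform(dh, (dh, C)),
        b2=np.zeros(C),
        config=config,
        node_ids=dataset.node_ids,
        n_classes=C,
    )

    P = propagate(op, X0, config.n_propagation_layers)  # G^L X0, parameter-free
    onehot = np.eye(C)[y]
    n_train = int(train_mask.sum())
    p = config.dropout

    params = ["W1", "b1", "W2", "b2"]
    if config.adaptive_gate:
        params.append("R")
    adam_m = {k: np.zeros_like(getattr(model, k)) for k in params}
    adam_v = {k: np.zeros_like(getattr(model, k)) for k in params}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    losses = np.empty(config.epochs)
    t0 = time.perf_counter()
    for epoch in range(config.epochs):
        lr = config.lr * config.lr_decay_factor ** (epoch // config.lr_decay_every)
        if config.adaptive_gate:
            s = _sigmoid(model.R)
        else:
            s = np.full(n, config.static_gate_value)
        H = P + s[:, None] * X0
        if p > 0:
            mask1 = (rng.random(H.shape) >= p) / (1.0 - p)
            Hd = H * mask1
        else:
            mask1 = None
            Hd = H
        Z1 = Hd @ model.W1 + model.b1
        A1 = np.maximum(Z1, 0.0)
        if p > 0:
            mask2 = (rng.random(A1.shape) >= p) / (1.0 - p)
            A1d = A1 * mask2
        else:
            mask2 = None
            A1d = A1
        S = A1d @ model.W2 + model.b2

        # softmax cross-entropy on the train mask
        Smax = S.max(axis=1, keepdims=True)
        logZ = Smax[:, 0] + np.log(np.exp(S - Smax).sum(axis=1))
        loss = float(np.mean(logZ[train_mask] - S[train_mask, y[train_mask]]))
        losses[epoch] = loss
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")

        prob = np.exp(S - logZ[:, None])
        dS = np.where(train_mask[:, None], (prob - onehot) / n_train, 0.0)
        grads = {
            "W2": A1d.T @ dS,
            "b2": dS.sum(axis=0),
        }
        dA1 = dS @ model.W2.T
        if mask2 is not None:
            dA1 = dA1 * mask2
        dZ1 = dA1 * (Z1 > 0)
        grads["W1"] = Hd.T @ dZ1
        grads["b1"] = dZ1.sum(axis=0)
        if config.adaptive_gate:
            dH = dZ1 @ model.W1.T
            if mask1 is not None:
                dH = dH * mask1
            grads["R"] = (dH * X0).sum(axis=1) * s * (1.0 - s)

        t = epoch + 1
        for k in params:
            g = grads[k] + config.weight_decay * getattr(model, k)
            adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
            adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
            mhat = adam_m[k] / (1 - beta1 ** t)
            vhat = adam_v[k] / (1 - beta2 ** t)
            setattr(model, k, getattr(model, k) - lr * mhat / (np.sqrt(vhat) + eps))

    model.trained = True
    scores = forward(model, op, X0, training=False)
    train_acc = float(np.mean(scores[train_mask].argmax(axis=1) == y[train_mask]))
    history = TrainHistory(losses, train_acc, time.perf_counter() - t0)
    return model, history, op, X0


def predict(
    model: HGCNModel,
    op: PropagationOperator,
    X0: np.ndarray,
    node_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels + class scores, optionally restricted to a node subset.

    Ties break toward the lowest class index (argmax convention).
    """
    if not model.trained:
        raise RuntimeError("model has not been trained")
    scores = forward(model, op, X0, training=False)
    if node_idx is not None:
        scores = scores[np.asarray(node_idx)]
    return scores.argmax(axis=1), scores


def save_model(model: HGCNModel, path) -> None:
    """Checkpoint as .npz (arrays) + .json sidecar (config, node order)."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz",
             R=model.R, W1=model.W1, b1=model.b1, W2=model.W2, b2=model.b2)
    meta = {
        "config": asdict(model.config),
        "node_ids": list(model.node_ids),
        "n_classes": model.n_classes,
        "trained": model.trained,
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path) -> HGCNModel:
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    arrays = np.load(base + ".npz")
    with open(base + ".json", encoding="utf-8") as fh:
        meta = json.load(fh)
    return HGCNModel(
        R=arrays["R"], W1=arrays["W1"], b1=arrays["b1"],
        W2=arrays["W2"], b2=arrays["b2"],
        config=TrainConfig(**meta["config"]),
        node_ids=tuple(meta["node_ids"]),
        n_classes=int(meta["n_classes"]),
        trained=bool(meta["trained"]),
    )
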