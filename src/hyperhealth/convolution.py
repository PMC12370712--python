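"""Hypergraph propagation operators and convolution layers.

Both the spectral-domain and the spatial (null-domain) hypergraph convolution
reduce to a fixed linear node aggregator ``G``:

    spectral:  G = D_q^{-1/2} B M D_e^{-1} B^T D_q^{-1/2}  (= I - L)
    spatial:   G = D_q^{-1}   B M D_e^{-1} B^T             (row-stochastic)

A convolution layer is then ``sigma(G X Theta)``; the decoupled design applies
``G`` repeatedly (propagation) without weights or nonlinearity, leaving the
feature transformation to a separate head.  ``message_passing_step`` is the
explicit three-step node->hyperedge->node formulation and must agree with the
spatial matrix form for unit weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypergraph import Hypergraph, HypergraphValidationError, degrees, laplacian

__all__ = [
    "PropagationOperator",
    "LayerWeights",
    "spectral_operator",
    "spatial_operator",
    "message_passing_step",
    "hgcn_layer",
    "propagate",
]

_ACTIVATIONS = {
    "identity": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
    "sigmoid": lambda x: 1.0 / (1.0 + np.exp(-x)),
}


@dataclass(frozen=True)
class PropagationOperator:
    """Dense node-by-node feature aggregator G.

    kind 'spectral': symmetric PSD with eigenvalues in [0, 1].
    kind 'spatial': row-stochastic (each output is a convex combination).
    kind 'gcn': symmetric-normalized adjacency with self-loops (clique-expansion
    baseline; symmetric but not PSD).
    """

    kind: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        G = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", G)
        if self.kind not in ("spectral", "spatial", "gcn"):
            raise ValueError(f"unknown operator kind {self.kind!r}")
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("operator matrix must be square")
        if self.kind == "spectral":
            if not np.allclose(G, G.T, atol=1e-10):
                raise ValueError("spectral operator must be symmetric")
        elif self.kind == "spatial":
            if not np.allclose(G.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError("spatial operator rows must sum to 1")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class LayerWeights:
    """Learnable transformation Theta plus a named nonlinearity."""

    theta: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", th)
        if not np.all(np.isfinite(th)):
            raise ValueError("theta must be finite")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


def _degree_scalings(h: Hypergraph):
    deg = degrees(h)
    if np.any(deg.node_degrees <= 0):
        raise HypergraphValidationError("zero node degree: operator undefined")
    return deg


def spectral_operator(h: Hypergraph) -> PropagationOperator:
    """Symmetric-normalized aggregator; equals ``I - laplacian(h)``."""
    G = np.eye(h.n_nodes) - laplacian(h)
    return PropagationOperator(kind="spectral", matrix=G)


def spatial_operator(h: Hypergraph) -> PropagationOperator:
    """Random-walk aggregator ``D_q^{-1} B M D_e^{-1} B^T`` (row-stochastic)."""
    deg = _degree_scalings(h)
    BMDe = h.incidence * (h.edge_weights / deg.edge_degrees)
    G = (BMDe @ h.incidence.T) / deg.node_degrees[:, None]
    return PropagationOperator(kind="spatial", matrix=G)


def message_passing_step(
    h: Hypergraph,
    features: np.ndarray,
    theta: LayerWeights | None = None,
) -> np.ndarray:
    """Explicit three-step propagation: node -> hyperedge -> node.

    Step 1 averages member features into each hyperedge (divide by d(e));
    step 2 scales hyperedge messages by m(e) and sums them at each node;
    step 3 divides by the weighted node degree and applies Theta.  Matches
    ``spatial_operator(h).matrix @ features @ theta`` (for unit weights the
    weighted node degree is the hyperedge count ``|E(q_x)|``).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != h.n_nodes:
        raise ValueError("feature rows must equal n_nodes")
    deg = _degree_scalings(h)
    B, m = h.incidence, h.edge_weights
    d = X.shape[1]
    edge_msg = np.zeros((h.n_edges, d))
    for y in range(h.n_edges):
        members = np.flatnonzero(B[:, y])
        edge_msg[y] = X[members].sum(axis=0) / deg.edge_degrees[y]
    out = np.zeros_like(X)
    for x in range(h.n_nodes):
        incident = np.flatnonzero(B[x])
        agg = (m[incident, None] * edge_msg[incident]).sum(axis=0)
        out[x] = agg / deg.node_degrees[x]
    if theta is not None:
        out = out @ theta.theta
    return out


def hgcn_layer(
    op: PropagationOperator,
    features: np.ndarray,
    weights: LayerWeights,
    dropout_rate: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One hypergraph convolution layer: ``sigma(G . dropout(X) . Theta)``.

    Dropout (inverted scaling) is applied to the layer input during training
    only; evaluation is deterministic.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] != op.n_nodes:
        raise ValueError("feature rows must equal operator size")
    if X.shape[1] != weights.theta.shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} != theta input dim {weights.theta.shape[0]}")
    if training and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = rng.random(X.shape) >= dropout_rate
        X = X * keep / (1.0 - dropout_rate)
    return _ACTIVATIONS[weights.activation](op.matrix @ X @ weights.theta)


def propagate(op: PropagationOperator, features: np.ndarray, L: int) -> np.ndarray:
    """Decoupled propagation ``G^L X`` — no weights, no nonlinearity."""
    if L < 0:
        raise ValueError("layer count L must be >= 0")
    X = np.asarray(features, dtype=float)
    if X.shape[0] != op.n_nodes:
        raise ValueError("feature rows must equal operator size")
    for _ in range(L):
        X = op.matrix @ X
    return X
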