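"""Hypergraph representation, degrees, normalized Laplacian, clique expansion, I/O.

A hypergraph over nodes ``Q`` and hyperedges ``E`` is stored as a dense binary
incidence matrix ``B`` of shape ``(|Q|, |E|)`` with ``B[x, y] = 1`` iff node
``x`` belongs to hyperedge ``y``, plus a nonnegative weight ``m(e)`` per
hyperedge (the diagonal of ``M``).  Weights default to 1 and are never
trained.  The normalized hypergraph Laplacian is

    L = I - D_q^{-1/2} B M D_e^{-1} B^T D_q^{-1/2}

where ``D_q`` holds the weighted node degrees ``d(q_x) = sum_y m(e_y) B[x, y]``
and ``D_e`` the hyperedge degrees ``d(e_y) = sum_x B[x, y]``.  ``L`` is
symmetric positive semidefinite with eigenvalues in ``[0, 1+eps]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Hypergraph",
    "DegreeSummary",
    "SimpleGraph",
    "make_hypergraph",
    "degrees",
    "laplacian",
    "clique_expand",
    "read_hypergraph",
    "write_hypergraph",
]


class HypergraphValidationError(ValueError):
    """Raised when an incidence structure violates a hypergraph invariant."""


class HypergraphParseError(ValueError):
    """Raised on a malformed hyperedge-list file; carries the line number."""


@dataclass(frozen=True)
class Hypergraph:
    """Binary incidence structure with per-hyperedge weights.

    Parameters
    ----------
    incidence : ndarray of shape (n_nodes, n_edges)
        Entries exactly 0 or 1.
    edge_weights : ndarray of shape (n_edges,)
        Nonnegative hyperedge weights (diagonal of ``M``).
    node_ids : tuple of str
        Unique subject identifiers indexing incidence rows.
    """

    incidence: np.ndarray
    edge_weights: np.ndarray
    node_ids: tuple[str, ...]
    edge_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        B = np.asarray(self.incidence, dtype=float)
        m = np.asarray(self.edge_weights, dtype=float)
        object.__setattr__(self, "incidence", B)
        object.__setattr__(self, "edge_weights", m)
        if B.ndim != 2:
            raise HypergraphValidationError("incidence must be a 2-D matrix")
        n, k = B.shape
        if n == 0 or k == 0:
            raise HypergraphValidationError("hypergraph needs >= 1 node and >= 1 hyperedge")
        if not np.all((B == 0) | (B == 1)):
            raise HypergraphValidationError("incidence entries must be exactly 0 or 1")
        if m.shape != (k,):
            raise HypergraphValidationError("edge_weights length must equal n_edges")
        if np.any(m < 0):
            raise HypergraphValidationError("edge weights must be nonnegative")
        if len(self.node_ids) != n:
            raise HypergraphValidationError("node_ids length must equal incidence rows")
        if len(set(self.node_ids)) != n:
            raise HypergraphValidationError("node_ids must be unique")
        if np.any(B.sum(axis=0) < 1):
            raise HypergraphValidationError("empty hyperedge (degree 0) not allowed")
        if np.any(B.sum(axis=1) < 1):
            raise HypergraphValidationError("every node must belong to >= 1 hyperedge")
        if not self.edge_ids:
            object.__setattr__(self, "edge_ids", tuple(f"e{i}" for i in range(k)))
        elif len(self.edge_ids) != k:
            raise HypergraphValidationError("edge_ids length must equal n_edges")

    @property
    def n_nodes(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_edges(self) -> int:
        return self.incidence.shape[1]


@dataclass(frozen=True)
class DegreeSummary:
    """Weighted node degrees d(q) and hyperedge degrees d(e)."""

    node_degrees: np.ndarray
    edge_degrees: np.ndarray


@dataclass(frozen=True)
class SimpleGraph:
    """Undirected simple graph as a symmetric binary adjacency with zero diagonal."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.all((A == 0) | (A == 1)):
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def make_hypergraph(
    edge_members: list[set[str] | frozenset[str] | list[str]],
    node_ids: list[str] | tuple[str, ...],
    edge_weights: np.ndarray | None = None,
    edge_ids: tuple[str, ...] | None = None,
) -> Hypergraph:
    """Build a hypergraph from per-hyperedge member-id sets.

    Duplicate hyperedges are retained as separate incidence columns (KNN
    construction can legitimately produce them; degrees then count
    multiplicity).  Weights default to all ones.
    """
    node_ids = tuple(str(i) for i in node_ids)
    index = {nid: x for x, nid in enumerate(node_ids)}
    if len(index) != len(node_ids):
        raise KeyError("duplicate node ids")
    B = np.zeros((len(node_ids), len(edge_members)))
    for y, members in enumerate(edge_members):
        if len(members) == 0:
            raise HypergraphValidationError(f"hyperedge {y} is empty")
        for mem in members:
            mem = str(mem)
            if mem not in index:
                raise KeyError(f"unknown node id {mem!r} in hyperedge {y}")
            B[index[mem], y] = 1.0
    if edge_weights is None:
        edge_weights = np.ones(len(edge_members))
    return Hypergraph(B, np.asarray(edge_weights, dtype=float), node_ids,
                      tuple(edge_ids) if edge_ids else ())


def degrees(h: Hypergraph) -> DegreeSummary:
    """Weighted node degrees and unweighted hyperedge degrees."""
    node_deg = h.incidence @ h.edge_weights
    edge_deg = h.incidence.sum(axis=0)
    return DegreeSummary(node_degrees=node_deg, edge_degrees=edge_deg)


def laplacian(h: Hypergraph) -> np.ndarray:
    """Normalized hypergraph Laplacian ``I - D_q^{-1/2} B M D_e^{-1} B^T D_q^{-1/2}``.

    Symmetric PSD; the result is explicitly symmetrized to kill rounding skew.
    """
    deg = degrees(h)
    if np.any(deg.node_degrees <= 0):
        raise HypergraphValidationError("isolated node: all node degrees must be > 0")
    dq_inv_sqrt = 1.0 / np.sqrt(deg.node_degrees)
    de_inv = 1.0 / deg.edge_degrees
    BMDe = h.incidence * (h.edge_weights * de_inv)  # B M D_e^{-1}, column scaling
    theta = (dq_inv_sqrt[:, None] * BMDe) @ (h.incidence.T * dq_inv_sqrt[None, :])
    L = np.eye(h.n_nodes) - theta
    return (L + L.T) / 2.0


def clique_expand(h: Hypergraph) -> SimpleGraph:
    """Replace each hyperedge by all pairwise edges among its members."""
    B = h.incidence
    co = B @ B.T  # co-membership counts
    A = (co > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    return SimpleGraph(adjacency=A)


def write_hypergraph(h: Hypergraph, path) -> None:
    """Write the hyperedge-list text format.

    Header ``#nodes: id1 id2 ...`` then one line per hyperedge:
    ``edge_id<TAB>weight<TAB>member,member,...``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#nodes: " + " ".join(h.node_ids) + "\n")
        for y in range(h.n_edges):
            members = [h.node_ids[x] for x in np.flatnonzero(h.incidence[:, y])]
            fh.write(f"{h.edge_ids[y]}\t{h.edge_weights[y]:g}\t{','.join(members)}\n")


def read_hypergraph(path) -> Hypergraph:
    """Parse the hyperedge-list text format written by :func:`write_hypergraph`."""
    node_ids: tuple[str, ...] | None = None
    edge_members: list[list[str]] = []
    weights: list[float] = []
    edge_ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#nodes:"):
                node_ids = tuple(line[len("#nodes:"):].split())
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if node_ids is None:
                raise HypergraphParseError(f"line {lineno}: hyperedge before #nodes: header")
            if len(parts) == 2:  # weightless edge: default 1.0
                eid, members = parts
                w = "1.0"
            elif len(parts) == 3:
                eid, w, members = parts
            else:
                raise HypergraphParseError(f"line {lineno}: expected 2 or 3 tab-separated fields")
            try:
                weight = float(w)
            except ValueError as exc:
                raise HypergraphParseError(f"line {lineno}: bad weight {w!r}") from exc
            mem = [m for m in members.split(",") if m]
            for m in mem:
                if m not in node_ids:
                    raise HypergraphParseError(f"line {lineno}: undeclared node id {m!r}")
            edge_ids.append(eid)
            weights.append(weight)
            edge_members.append(mem)
    if node_ids is None:
        raise HypergraphParseError("missing #nodes: header")
    return make_hypergraph(edge_members, list(node_ids), np.array(weights), tuple(edge_ids))
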