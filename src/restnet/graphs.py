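"""Binary graph construction from weighted connectivity matrices.

Three thresholding schemes turn a symmetric weighted matrix into an
undirected, unweighted graph: an absolute correlation cutoff (``R``), a
fixed edge density (``cost``), and a target mean degree (``K``).  All
three are exposed on a common :class:`BinaryGraph` container that the
rest of the package consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "BinaryGraph",
    "ThresholdGrid",
    "threshold_by_r",
    "threshold_by_cost",
    "threshold_by_degree",
    "largest_component",
]


@dataclass
class BinaryGraph:
    """Simple undirected graph stored as a dense 0/1 adjacency matrix.

    Parameters
    ----------
    adjacency
        Square symmetric array with zero diagonal; any nonzero entry is
        treated as an edge.
    labels
        Optional node labels (defaults to ``"n000"``-style ids).
    provenance
        Free-form record of how the graph was built (threshold scheme,
        threshold value, source matrix id, ...).
    """

    adjacency: np.ndarray
    labels: list[str] | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        A = (A != 0).astype(np.uint8)
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A)):
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        self.adjacency = A
        if self.labels is None:
            self.labels = [f"n{i:03d}" for i in range(A.shape[0])]
        elif len(self.labels) != A.shape[0]:
            raise ValueError("labels length must equal node count")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edge_list(self) -> list[tuple[int, int]]:
        """Edges as sorted (i, j) pairs with i < j."""
        iu = np.triu_indices(self.n_nodes, k=1)
        on = self.adjacency[iu] != 0
        return list(zip(iu[0][on].tolist(), iu[1][on].tolist()))

    def subgraph(self, nodes: Sequence[int]) -> "BinaryGraph":
        idx = np.asarray(list(nodes), dtype=np.intp)
        labels = self.labels if self.labels is not None else []
        return BinaryGraph(
            self.adjacency[np.ix_(idx, idx)],
            labels=[labels[i] for i in idx] if labels else None,
            provenance={**self.provenance, "subgraph_of": self.provenance.get("id")},
        )

    def copy(self) -> "BinaryGraph":
        labels = list(self.labels) if self.labels is not None else None
        return BinaryGraph(self.adjacency.copy(), labels=labels, provenance=dict(self.provenance))


def _as_weights(matrix: Any) -> tuple[np.ndarray, list[str] | None]:
    """Accept a ConnectivityMatrix-like object or a raw square array."""
    labels = None
    if hasattr(matrix, "values") and hasattr(matrix, "labels"):
        labels = list(matrix.labels)
        W = np.asarray(matrix.values, dtype=float)
    else:
        W = np.asarray(matrix, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    return W, labels


def threshold_by_r(matrix: Any, r: float) -> BinaryGraph:
    """Binarize a weighted matrix at an absolute threshold.

    An edge is placed iff the weight strictly exceeds ``r``; the
    diagonal is ignored.  Strictness is a documented convention — the
    calibration of the grid's upper end is insensitive to it, but one
    rule must be fixed.
    """
    if not 0 <= r < 1:
        raise ValueError(f"r must be in [0, 1), got {r}")
    W, labels = _as_weights(matrix)
    A = (W > r).astype(np.uint8)
    np.fill_diagonal(A, 0)
    A = np.maximum(A, A.T)  # guard against asymmetric float input
    return BinaryGraph(A, labels=labels, provenance={"scheme": "r", "value": r})


def _ranked_pairs(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered by (weight desc, i asc, j asc)."""
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def threshold_by_cost(matrix: Any, cost: float) -> BinaryGraph:
    """Keep the ``round(cost * N(N-1)/2)`` strongest edges.

    Ranking uses the signed weight (largest positive first); ties at the
    cutoff are broken by lexicographic node-pair order so the result is
    platform-independent.
    """
    if not 0 < cost <= 1:
        raise ValueError(f"cost must be in (0, 1], got {cost}")
    W, labels = _as_weights(matrix)
    n = W.shape[0]
    n_possible = n * (n - 1) // 2
    n_edges = int(round(cost * n_possible))
    ii, jj = _ranked_pairs(W)
    A = np.zeros((n, n), dtype=np.uint8)
    A[ii[:n_edges], jj[:n_edges]] = 1
    A |= A.T
    return BinaryGraph(A, labels=labels, provenance={"scheme": "cost", "value": cost})


def threshold_by_degree(matrix: Any, k_target: float) -> BinaryGraph:
    """Threshold to a target mean degree ``K``.

    Equivalent to cost thresholding at ``k_target / (N-1)``: mean degree
    K = 2E/N implies E = N*K/2 (rounded).
    """
    W, labels = _as_weights(matrix)
    n = W.shape[0]
    if not 2 <= k_target <= n - 1:
        raise ValueError(f"k_target must be in [2, N-1], got {k_target}")
    g = threshold_by_cost(W, k_target / (n - 1))
    g.labels = labels if labels is not None else g.labels
    g.provenance = {"scheme": "k", "value": k_target}
    return g


def largest_component(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Largest connected component by BFS.

    Returns the node index array and its size as a fraction of the
    original node count.  An edgeless graph yields a singleton
    (fraction 1/N) by convention.
    """
    A = graph.adjacency
    n = graph.n_nodes
    seen = np.zeros(n, dtype=bool)
    best: np.ndarray = np.array([0], dtype=np.intp)
    for start in range(n):
        if seen[start]:
            continue
        comp = np.zeros(n, dtype=bool)
        comp[start] = True
        frontier = comp.copy()
        while frontier.any():
            nxt = (A[frontier].any(axis=0)) & ~comp
            comp |= nxt
            frontier = nxt
        seen |= comp
        members = np.flatnonzero(comp)
        if members.size > best.size:
            best = members
    return best, best.size / n


@dataclass
class ThresholdGrid:
    """Default threshold sweeps for the three schemes.

    ``r_values``: 0 to 0.45 step 0.025 (19 values).
    ``cost_values``: 0.02 to 0.60 step 0.04 — i.e. 0.02..0.58, 15 values.
    ``k_values``: 13 integers spread over (6, 42); the count is fixed by
    design, the spacing (round-half-up on linspace(9, 39, 13)) is a
    documented convention and is configurable.
    """

    r_values: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.0, 0.45 + 1e-9, 0.025), 4))
    k_values: np.ndarray = field(
        default_factory=lambda: np.floor(np.linspace(9, 39, 13) + 0.5).astype(int)
    )
    cost_values: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.02, 0.60, 0.04), 4))

    def __post_init__(self) -> None:
        for name in ("r_values", "k_values", "cost_values"):
            v = np.asarray(getattr(self, name))
            if v.ndim != 1 or len(v) < 1:
                raise ValueError(f"{name} must be a non-empty 1-d sequence")
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, v)

    @staticmethod
    def reliable_degree_bound(n_nodes: int) -> float:
        """ln(N): mean degrees below this make small-world estimates unreliable."""
        if n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        return math.log(n_nodes)

    def validate_for(self, n_nodes: int) -> None:
        """Check the K grid sits above the ln(N) reliability bound."""
        bound = self.reliable_degree_bound(n_nodes)
        if self.k_values[0] < bound:
            raise ValueError(
                f"smallest K threshold {self.k_values[0]} is below the reliability "
                f"bound ln({n_nodes}) = {bound:.1f}"
            )
        if self.k_values[-1] > n_nodes - 1:
            raise ValueError("largest K threshold exceeds N-1")
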