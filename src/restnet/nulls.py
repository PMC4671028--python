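"""Null and comparison networks.

Degree-preserving randomization (Maslov–Sneppen double-edge swaps),
ring-lattice benchmarks matched on (N, E), and preferential-attachment
scale-free graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .graphs import BinaryGraph

__all__ = [
    "NullEnsemble",
    "rewire_degree_preserving",
    "lattice_graph",
    "scale_free_graph",
    "make_ensemble",
]


def rewire_degree_preserving(
    graph: BinaryGraph, swaps_per_edge: int = 10, seed: int | None = None
) -> BinaryGraph:
    """Randomize a graph while preserving its exact degree sequence.

    Performs ``swaps_per_edge * E`` attempted double-edge swaps,
    rejecting any swap that would create a self-loop or multi-edge.
    The default of 10 swaps per edge is a standard mixing heuristic.
    """
    if graph.n_edges < 2:
        warnings.warn("fewer than 2 edges; returning the graph unchanged", stacklevel=2)
        return graph.copy()
    rng = np.random.default_rng(seed)
    A = graph.adjacency.copy()
    edges = graph.edge_list()
    n_edges = len(edges)
    n_attempts = swaps_per_edge * n_edges
    pick = rng.integers(0, n_edges, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[t]:
            c, d = d, c
        # proposed replacement: (a,d), (c,b)
        if a == d or c == b:
            continue
        if A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = 0
        A[c, d] = A[d, c] = 0
        A[a, d] = A[d, a] = 1
        A[c, b] = A[b, c] = 1
        edges[e1] = (a, d) if a < d else (d, a)
        edges[e2] = (c, b) if c < b else (b, c)
    labels = list(graph.labels) if graph.labels is not None else None
    return BinaryGraph(
        A, labels=labels, provenance={"kind": "rewired_random", "seed": seed, "source": graph.provenance}
    )


def lattice_graph(n: int, n_edges: int) -> BinaryGraph:
    """Ring lattice with exactly ``n_edges`` edges.

    Nearest-neighbor rings are filled outward (all pairs at circular
    distance 1, then 2, ...) until the edge budget is spent; within a
    ring, pairs are added in lexicographic order.
    """
    max_edges = n * (n - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"requested {n_edges} edges but only {max_edges} possible")
    A = np.zeros((n, n), dtype=np.uint8)
    placed = 0
    for ring in range(1, n // 2 + 1):
        for i in range(n):
            j = (i + ring) % n
            if placed >= n_edges:
                break
            if A[i, j]:
                continue  # ring n/2 visits each pair twice for even n
            A[i, j] = A[j, i] = 1
            placed += 1
        if placed >= n_edges:
            break
    return BinaryGraph(A, provenance={"kind": "lattice", "n_edges": n_edges})


def scale_free_graph(n: int, target_density: float, seed: int | None = None) -> BinaryGraph:
    """Barabási–Albert preferential-attachment graph at a target density.

    The attachment count m is the value whose realized density,
    (N-m)*m / (N(N-1)/2), is nearest the target (within one edge batch).
    Construction: m seed nodes without edges; each arriving node
    attaches to m distinct targets sampled proportionally to degree
    (uniformly for the first arrival).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if target_density < 1.0 / n:
        raise ValueError(
            f"density {target_density} below the m=1 floor (~{2 / n:.3f}) at n={n}"
        )
    n_possible = n * (n - 1) / 2
    guess = target_density * (n - 1) / 2
    candidates = [m for m in {int(np.floor(guess)), int(np.ceil(guess)),
                              int(np.floor(guess)) + 1} if 1 <= m < n]
    if not candidates:
        raise ValueError(f"density {target_density} not achievable at n={n}")
    m = min(candidates, key=lambda mm: abs((n - mm) * mm / n_possible - target_density))
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n), dtype=np.uint8)
    # repeated-node list: each entry is one half-edge endpoint
    repeated: list[int] = []
    targets = list(range(m))
    for new in range(m, n):
        for t in targets:
            A[new, t] = A[t, new] = 1
            repeated.extend((new, t))
        # sample m distinct targets for the next arrival, degree-weighted
        chosen: set[int] = set()
        while len(chosen) < m:
            chosen.add(repeated[rng.integers(0, len(repeated))])
        targets = sorted(chosen)
    return BinaryGraph(
        A, provenance={"kind": "scale_free", "m": m, "target_density": target_density, "seed": seed}
    )


@dataclass
class NullEnsemble:
    """A family of comparison graphs for one source graph."""

    kind: str  # rewired_random | lattice | scale_free
    members: list[BinaryGraph]
    source_id: str | None = None
    seeds: list[int] = field(default_factory=list)


def make_ensemble(
    graph: BinaryGraph,
    kind: str,
    size: int,
    seed: int | None = None,
    swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Build an ensemble of nulls matched to ``graph``.

    ``rewired_random`` preserves the degree sequence exactly;
    ``lattice`` and ``scale_free`` are matched on (N, E) / density.
    Defaults elsewhere in the package are 100 rewired nulls per R/K
    threshold and 20 random + 20 lattice per cost threshold.
    """
    ss = np.random.SeedSequence(seed)
    member_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(size)]
    if kind == "rewired_random":
        members = [
            rewire_degree_preserving(graph, swaps_per_edge=swaps_per_edge, seed=s)
            for s in member_seeds
        ]
    elif kind == "lattice":
        members = [lattice_graph(graph.n_nodes, graph.n_edges) for _ in range(size)]
    elif kind == "scale_free":
        n = graph.n_nodes
        density = graph.n_edges / (n * (n - 1) / 2)
        members = [scale_free_graph(n, density, seed=s) for s in member_seeds]
    else:
        raise ValueError(f"unknown ensemble kind: {kind!r}")
    return NullEnsemble(
        kind=kind,
        members=members,
        source_id=str(graph.provenance.get("id")),
        seeds=member_seeds,
    )
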