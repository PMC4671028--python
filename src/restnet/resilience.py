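"""Attack and failure simulations.

Sequential targeted removal by centrality, averaged random failure, and
single-node deletion sweeps with the resulting change in global
efficiency, plus the degree-hub vs betweenness-hub comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .community import HubReport
from .graphs import BinaryGraph, largest_component
from .metrics import betweenness, global_efficiency

__all__ = [
    "AttackCurve",
    "IsolatedRemovalTable",
    "targeted_attack",
    "random_failure",
    "isolated_removal_sweep",
    "compare_hub_classes",
]


@dataclass
class AttackCurve:
    """Largest-component and efficiency trajectories under node removal.

    All arrays have one entry per step, step 0 being the intact graph.
    ``lcc_fraction`` is relative to the ORIGINAL node count (primary
    convention); ``lcc_fraction_remaining`` relative to the surviving
    node count is also recorded.  ``eglob_percent`` is Eglob as a
    percentage of the intact graph's Eglob (exactly 100 at step 0).
    """

    strategy: str
    removed: np.ndarray
    lcc_fraction: np.ndarray
    lcc_fraction_remaining: np.ndarray
    eglob: np.ndarray
    eglob_percent: np.ndarray
    n_runs: int = 1
    seeds: list[int] = field(default_factory=list)


def _attack_trajectory(graph: BinaryGraph, order: np.ndarray, n_steps: int) -> tuple[np.ndarray, ...]:
    n = graph.n_nodes
    e0 = global_efficiency(graph)
    alive = np.ones(n, dtype=bool)
    lcc = np.empty(n_steps + 1)
    lcc_rem = np.empty(n_steps + 1)
    eg = np.empty(n_steps + 1)
    members, _ = largest_component(graph)
    lcc[0] = members.size / n
    lcc_rem[0] = members.size / n
    eg[0] = e0
    for step in range(1, n_steps + 1):
        alive[order[step - 1]] = False
        remaining = np.flatnonzero(alive)
        sub = graph.subgraph(remaining)
        if remaining.size == 0:
            lcc[step] = 0.0
            lcc_rem[step] = 0.0
            eg[step] = 0.0
            continue
        members, _ = largest_component(sub)
        lcc[step] = members.size / n
        lcc_rem[step] = members.size / remaining.size
        eg[step] = global_efficiency(sub) if remaining.size >= 2 else 0.0
    pct = 100.0 * eg / e0 if e0 > 0 else np.zeros_like(eg)
    pct[0] = 100.0 if e0 > 0 else pct[0]  # exact at step 0 by contract
    return lcc, lcc_rem, eg, pct


def _centrality(graph: BinaryGraph, strategy: str) -> np.ndarray:
    if strategy == "degree":
        return graph.degrees.astype(float)
    if strategy == "betweenness":
        return betweenness(graph)
    raise ValueError(f"unknown strategy {strategy!r}")


def targeted_attack(
    graph: BinaryGraph,
    strategy: str,
    n_removals: int | None = None,
    recompute: bool = False,
) -> AttackCurve:
    """Remove nodes in descending centrality order.

    By default the ranking is computed once on the intact graph (static
    attack); ``recompute=True`` re-ranks among the survivors after every
    removal.  Ties are broken by ascending node index.
    """
    n = graph.n_nodes
    n_steps = n - 1 if n_removals is None else min(n_removals, n)
    if recompute:
        alive = np.ones(n, dtype=bool)
        order = np.empty(n_steps, dtype=np.intp)
        for step in range(n_steps):
            remaining = np.flatnonzero(alive)
            sub = graph.subgraph(remaining)
            c = _centrality(sub, strategy)
            victim = remaining[np.lexsort((remaining, -c))[0]]
            order[step] = victim
            alive[victim] = False
    else:
        c = _centrality(graph, strategy)
        order = np.lexsort((np.arange(n), -c))[:n_steps].astype(np.intp)
    lcc, lcc_rem, eg, pct = _attack_trajectory(graph, order, n_steps)
    return AttackCurve(
        strategy=strategy,
        removed=np.arange(n_steps + 1),
        lcc_fraction=lcc,
        lcc_fraction_remaining=lcc_rem,
        eglob=eg,
        eglob_percent=pct,
    )


def random_failure(
    graph: BinaryGraph,
    n_runs: int = 20,
    seed: int | None = None,
    n_removals: int | None = None,
) -> AttackCurve:
    """Mean trajectories over independent uniformly random removal orders."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n = graph.n_nodes
    n_steps = n - 1 if n_removals is None else min(n_removals, n)
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_runs)]
    acc = None
    for s in run_seeds:
        order = np.random.default_rng(s).permutation(n)[:n_steps].astype(np.intp)
        curves = _attack_trajectory(graph, order, n_steps)
        if acc is None:
            acc = [c.astype(float).copy() for c in curves]
        else:
            for a, c in zip(acc, curves):
                a += c
    assert acc is not None
    acc = [a / n_runs for a in acc]
    return AttackCurve(
        strategy="random",
        removed=np.arange(n_steps + 1),
        lcc_fraction=acc[0],
        lcc_fraction_remaining=acc[1],
        eglob=acc[2],
        eglob_percent=acc[3],
        n_runs=n_runs,
        seeds=run_seeds,
    )


@dataclass
class IsolatedRemovalTable:
    """Per-node change in Eglob after deleting that node alone.

    ``delta_eglob_percent[i]`` corresponds to ``nodes[i]``; rows are
    sorted ascending (most harmful removal first).
    """

    nodes: np.ndarray
    delta_eglob_percent: np.ndarray
    eglob_intact: float
    labels: list[str] | None = None

    def delta_for(self, node_indices) -> np.ndarray:
        """Look up deltas for arbitrary node ids (original indexing)."""
        pos = {int(n): i for i, n in enumerate(self.nodes)}
        return np.array([self.delta_eglob_percent[pos[int(i)]] for i in node_indices])


def isolated_removal_sweep(graph: BinaryGraph) -> IsolatedRemovalTable:
    """Delta Eglob% for deleting each node (and its edges) in isolation."""
    n = graph.n_nodes
    if n < 3:
        raise ValueError("need at least 3 nodes")
    e0 = global_efficiency(graph)
    if e0 == 0:
        raise ValueError("intact graph has zero global efficiency")
    deltas = np.empty(n)
    all_nodes = np.arange(n)
    for i in range(n):
        sub = graph.subgraph(all_nodes[all_nodes != i])
        deltas[i] = 100.0 * (global_efficiency(sub) - e0) / e0
    order = np.lexsort((all_nodes, deltas))
    labels = list(graph.labels) if graph.labels is not None else None
    return IsolatedRemovalTable(
        nodes=all_nodes[order],
        delta_eglob_percent=deltas[order],
        eglob_intact=e0,
        labels=[labels[i] for i in order] if labels else None,
    )


@dataclass
class HubClassComparison:
    mean_degree: float
    mean_betweenness: float
    sd_degree: float
    sd_betweenness: float
    t_statistic: float
    p_value: float
    n_degree: int
    n_betweenness: int


def _top_fraction_deltas(
    table: IsolatedRemovalTable, centrality: np.ndarray, top_fraction: float
) -> np.ndarray:
    """Delta values for the top-fraction nodes by a centrality.

    If several nodes are tied at the boundary rank, their deltas are
    averaged into a single entry (the tied group counts once).
    """
    n = centrality.size
    n_top = int(round(top_fraction * n))
    order = np.lexsort((np.arange(n), -centrality))
    boundary_value = centrality[order[n_top - 1]]
    above = order[centrality[order] > boundary_value]
    tied = np.flatnonzero(centrality == boundary_value)
    deltas = list(table.delta_for(above))
    if tied.size:
        deltas.append(float(table.delta_for(tied).mean()))
    return np.asarray(deltas)


def compare_hub_classes(
    table: IsolatedRemovalTable,
    degree_hubs: HubReport,
    betweenness_hubs: HubReport,
    top_fraction: float | None = None,
) -> HubClassComparison:
    """Welch t-test of Delta Eglob% between degree and betweenness hubs.

    With ``top_fraction=None`` the hub sets from the two reports (the
    mean + 1SD rule) are compared directly.  With a fraction, the top
    ``round(f*N)`` nodes by each centrality are used instead, with
    boundary ties collapsed to one averaged entry.
    """
    if top_fraction is None:
        d_vals = table.delta_for(degree_hubs.hubs)
        b_vals = table.delta_for(betweenness_hubs.hubs)
    else:
        d_vals = _top_fraction_deltas(table, degree_hubs.values, top_fraction)
        b_vals = _top_fraction_deltas(table, betweenness_hubs.values, top_fraction)
    if d_vals.size < 2 or b_vals.size < 2:
        raise ValueError("each hub class needs at least 2 entries")
    if np.var(d_vals) == 0 and np.var(b_vals) == 0:
        t, p = (0.0, 1.0) if np.isclose(d_vals.mean(), b_vals.mean()) else (np.inf, 0.0)
    else:
        t, p = sps.ttest_ind(d_vals, b_vals, equal_var=False)
    return HubClassComparison(
        mean_degree=float(d_vals.mean()),
        mean_betweenness=float(b_vals.mean()),
        sd_degree=float(d_vals.std(ddof=1)),
        sd_betweenness=float(b_vals.std(ddof=1)),
        t_statistic=float(t),
        p_value=float(p),
        n_degree=d_vals.size,
        n_betweenness=b_vals.size,
    )
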