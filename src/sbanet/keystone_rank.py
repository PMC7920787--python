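"""Keystone (hub) species identification on the cutoff-simplified network.

Node importance comes from either hub centrality (principal eigenvector of
the weighted adjacency, computed per connected component and normalized to a
global maximum of 1) or PageRank on the weighted graph. Species scores
aggregate their five nodes (max by default) and are ranked descending.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .sban_build import SBANetwork

DEFAULT_KEYSTONE_CUTOFF = 0.4
DEFAULT_DAMPING = 0.85
RANK_METHODS = ("hub", "pagerank")
AGGREGATES = ("max", "sum")
PAGERANK_TOL = 1e-9
PAGERANK_MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class NodeScore:
    node: tuple[str, str]
    hub_score: float = 0.0
    pagerank_score: float = 0.0


@dataclass
class SpeciesRanking:
    entries: list[tuple[str, float]]  # (species_id, score), non-increasing

    def top(self) -> str | None:
        return self.entries[0][0] if self.entries else None

    def near_leaders(self, rel_tol: float = 0.05) -> list[str]:
        """Species whose score is within ``rel_tol`` (relative) of the best."""
        if not self.entries:
            return []
        best = self.entries[0][1]
        return [sp for sp, sc in self.entries if sc >= best * (1.0 - rel_tol)]


def simplify_network(
    net: SBANetwork, cutoff: float = DEFAULT_KEYSTONE_CUTOFF
) -> SBANetwork:
    """Drop edges with weight <= cutoff (only strictly stronger ties kept)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_weighted_edges_from(
        (u, v, w)
        for u, v, w in net.graph.edges(data="weight")
        if w > cutoff
    )
    return SBANetwork(regime=net.regime, habitat=net.habitat, graph=g)


def _component_principal_vector(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Perron eigenvector (nonnegative, max entry 1) and spectral radius."""
    eigvals, eigvecs = np.linalg.eigh(adj)
    idx = int(np.argmax(eigvals))
    vec = np.abs(eigvecs[:, idx])
    peak = vec.max()
    if peak > 0:
        vec = vec / peak
    return vec, float(eigvals[idx])


def hub_scores(net: SBANetwork) -> list[NodeScore]:
    """Eigenvector-based hub centrality; isolates score 0.

    Each connected component contributes its principal eigenvector scaled
    by the component's spectral radius, and the combined scores are
    normalized so the global maximum is 1 on non-empty graphs.
    """
    nodes = list(net.graph.nodes)
    raw = {n: 0.0 for n in nodes}
    for comp in nx.connected_components(net.graph):
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        sub = net.graph.subgraph(comp)
        adj = nx.to_numpy_array(sub, nodelist=comp, weight="weight")
        vec, radius = _component_principal_vector(adj)
        for node, value in zip(comp, vec):
            raw[node] = value * radius
    peak = max(raw.values(), default=0.0)
    if peak > 0:
        raw = {n: v / peak for n, v in raw.items()}
    return [NodeScore(node=n, hub_score=raw[n]) for n in nodes]


def pagerank_scores(
    net: SBANetwork, damping: float = DEFAULT_DAMPING
) -> list[NodeScore]:
    """Weighted PageRank by power iteration; scores sum to 1.

    Undirected edges act as arc pairs with weight-proportional transition
    probabilities; isolated (dangling) nodes teleport uniformly.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping {damping} outside (0, 1)")
    nodes = list(net.graph.nodes)
    n = len(nodes)
    adj = nx.to_numpy_array(net.graph, nodelist=nodes, weight="weight")
    out_strength = adj.sum(axis=1)
    dangling = out_strength == 0.0
    trans = np.zeros_like(adj)
    np.divide(adj, out_strength[:, None], out=trans, where=~dangling[:, None])

    x = np.full(n, 1.0 / n)
    for _ in range(PAGERANK_MAX_ITER):
        dangling_mass = x[dangling].sum()
        new = damping * (trans.T @ x) + (
            damping * dangling_mass + (1.0 - damping)
        ) / n
        if np.abs(new - x).sum() < PAGERANK_TOL:
            x = new
            break
        x = new
    else:
        raise ConvergenceError(
            f"pagerank failed to converge in {PAGERANK_MAX_ITER} iterations"
        )
    return [NodeScore(node=nd, pagerank_score=float(s)) for nd, s in zip(nodes, x)]


def score_nodes(
    net: SBANetwork, method: str = "hub", damping: float = DEFAULT_DAMPING
) -> list[NodeScore]:
    if method == "hub":
        return hub_scores(net)
    if method == "pagerank":
        return pagerank_scores(net, damping=damping)
    raise ValueError(f"unknown method {method!r}; expected one of {RANK_METHODS}")


def rank_species(
    scores: list[NodeScore],
    method: str = "hub",
    aggregate: str = "max",
) -> SpeciesRanking:
    """Aggregate node scores per species and rank descending.

    Ties break by the other aggregate, then species id; species whose nodes
    all score 0 are excluded.
    """
    if method not in RANK_METHODS:
        raise ValueError(f"unknown method {method!r}")
    if aggregate not in AGGREGATES:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    attr = "hub_score" if method == "hub" else "pagerank_score"
    per_species: dict[str, list[float]] = {}
    for ns in scores:
        per_species.setdefault(ns.node[0], []).append(getattr(ns, attr))
    rows = []
    for sp, vals in per_species.items():
        primary = max(vals) if aggregate == "max" else sum(vals)
        secondary = sum(vals) if aggregate == "max" else max(vals)
        if primary > 0:
            rows.append((sp, primary, secondary))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return SpeciesRanking(entries=[(sp, primary) for sp, primary, _ in rows])


def keystone_species(
    net: SBANetwork,
    cutoff: float = DEFAULT_KEYSTONE_CUTOFF,
    method: str = "hub",
    aggregate: str = "max",
    rel_tol: float = 0.05,
) -> tuple[SpeciesRanking, list[str]]:
    """Simplify, score, rank; return the ranking and the near-leader hub list."""
    simplified = simplify_network(net, cutoff=cutoff)
    ranking = rank_species(
        score_nodes(simplified, method=method), method=method, aggregate=aggregate
    )
    return ranking, ranking.near_leaders(rel_tol)
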