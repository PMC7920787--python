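"""Build the social-behavioral association network (SBAN) for one stratum.

Pipeline: Pearson correlation of abundance-matrix columns -> sign policy
(negatives zeroed by default, absolute value optional) -> threshold (default
0.05, keeping ties; the keystone cutoff uses strict comparison) -> an
undirected weighted simple graph over the fixed node universe.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .event_store import AbundanceMatrix, SpeciesCatalog

DEFAULT_BUILD_THRESHOLD = 0.05
DEFAULT_SIGN_POLICY = "zero_negative"
SIGN_POLICIES = ("zero_negative", "absolute")


class InsufficientDataError(ValueError):
    """Fewer than two events in a stratum: correlation undefined."""


@dataclass
class CorrelationMatrix:
    """Symmetric node-label correlation matrix; diagonal excluded from edges.

    Zero-variance columns (species never seen in the stratum) produce 0
    off-diagonal by policy, so absent species stay isolates.
    """

    labels: list[tuple[str, str]]
    values: np.ndarray = field(repr=False)

    def copy(self) -> "CorrelationMatrix":
        return CorrelationMatrix(list(self.labels), self.values.copy())


@dataclass
class SBANetwork:
    """Undirected weighted simple graph over the full node universe."""

    regime: str
    habitat: str
    graph: nx.Graph = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def correlate_nodes(matrix: AbundanceMatrix) -> CorrelationMatrix:
    """Sample Pearson correlation between every pair of node columns."""
    if matrix.n_events < 2:
        raise InsufficientDataError(
            f"stratum ({matrix.regime}, {matrix.habitat}) has "
            f"{matrix.n_events} event(s); need at least 2 to correlate"
        )
    values = matrix.data.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance columns -> r = 0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(labels=list(matrix.labels), values=corr)


def apply_sign_policy(
    corr: CorrelationMatrix, policy: str = DEFAULT_SIGN_POLICY
) -> CorrelationMatrix:
    """Map negative correlations to zero (default) or take absolute values."""
    if policy not in SIGN_POLICIES:
        raise ValueError(
            f"unknown sign policy {policy!r}; expected one of {SIGN_POLICIES}"
        )
    out = corr.copy()
    if policy == "zero_negative":
        out.values[out.values < 0] = 0.0
    else:
        np.abs(out.values, out=out.values)
    return out


def threshold_adjacency(
    corr: CorrelationMatrix, threshold: float, strict: bool = False
) -> CorrelationMatrix:
    """Zero out weak entries.

    Non-strict (build threshold): entries below ``threshold`` are dropped,
    ties kept. Strict (keystone cutoff): only entries above ``threshold``
    survive. The diagonal is left untouched.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    out = corr.copy()
    off = ~np.eye(len(out.labels), dtype=bool)
    drop = (out.values <= threshold) if strict else (out.values < threshold)
    out.values[drop & off] = 0.0
    return out


def build_network(
    corr: CorrelationMatrix, regime: str, habitat: str
) -> SBANetwork:
    """One edge per nonzero off-diagonal entry; isolates retained."""
    g = nx.Graph()
    g.add_nodes_from(corr.labels)
    n = len(corr.labels)
    iu, ju = np.triu_indices(n, k=1)
    weights = corr.values[iu, ju]
    keep = weights != 0.0
    g.add_weighted_edges_from(
        (corr.labels[i], corr.labels[j], float(w))
        for i, j, w in zip(iu[keep], ju[keep], weights[keep])
    )
    return SBANetwork(regime=regime, habitat=habitat, graph=g)


def build_stratum_network(
    matrix: AbundanceMatrix,
    threshold: float = DEFAULT_BUILD_THRESHOLD,
    sign_policy: str = DEFAULT_SIGN_POLICY,
) -> SBANetwork:
    """Convenience composition: correlate -> sign policy -> threshold -> graph."""
    corr = correlate_nodes(matrix)
    corr = apply_sign_policy(corr, sign_policy)
    corr = threshold_adjacency(corr, threshold)
    return build_network(corr, matrix.regime, matrix.habitat)


def write_graphml(net: SBANetwork, catalog: SpeciesCatalog, path) -> None:
    """GraphML export with species/behavior/guild node attributes."""
    guild_of = catalog.guild_of
    g = nx.Graph()
    g.graph["regime"] = net.regime
    g.graph["habitat"] = net.habitat
    for sp, bc in net.graph.nodes:
        g.add_node(
            f"{sp}:{bc}",
            species_id=sp,
            behavior_class=bc,
            guild=guild_of.get(sp, ""),
        )
    for (usp, ubc), (vsp, vbc), data in net.graph.edges(data=True):
        g.add_edge(f"{usp}:{ubc}", f"{vsp}:{vbc}", weight=data["weight"])
    nx.write_graphml(g, path)


def read_graphml(path) -> SBANetwork:
    g = nx.read_graphml(path)
    out = nx.Graph()
    for node, data in g.nodes(data=True):
        sp, _, bc = node.partition(":")
        out.add_node(
            (data.get("species_id", sp), data.get("behavior_class", bc))
        )
    for u, v, data in g.edges(data=True):
        usp, _, ubc = u.partition(":")
        vsp, _, vbc = v.partition(":")
        out.add_edge((usp, ubc), (vsp, vbc), weight=float(data["weight"]))
    return SBANetwork(
        regime=str(g.graph.get("regime", "")),
        habitat=str(g.graph.get("habitat", "")),
        graph=out,
    )


def write_edge_list(net: SBANetwork, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for (usp, ubc), (vsp, vbc), data in sorted(net.graph.edges(data=True)):
            writer.writerow(
                [f"{usp}:{ubc}", f"{vsp}:{vbc}", repr(data["weight"])]
            )
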