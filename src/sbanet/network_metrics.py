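"""Per-stratum network attributes: active species/nodes, edges, density,
and the intra/inter edge tallies (SIPS by species, BIPS by behavior class).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from ._constants import round_half_away
from .sban_build import SBANetwork

SUMMARY_COLUMNS = (
    "regime",
    "habitat",
    "n_species",
    "active_nodes",
    "n_edges",
    "density_pct",
    "sips_intra",
    "sips_inter",
    "bips_intra",
    "bips_inter",
    "hub_species",
)

#: the 8 numeric attributes treated as replicate responses downstream
NUMERIC_ATTRIBUTES = SUMMARY_COLUMNS[2:10]


@dataclass(frozen=True)
class EdgeClass:
    species_relation: str  # intra_species | inter_species
    behavior_relation: str  # intra_behavior | inter_behavior


@dataclass
class NetworkSummary:
    regime: str
    habitat: str
    n_species: int
    active_nodes: int
    n_edges: int
    density_pct: float
    sips_intra: int
    sips_inter: int
    bips_intra: int
    bips_inter: int
    hub_species: list[str] = field(default_factory=list)

    def numeric_values(self) -> list[float]:
        return [float(getattr(self, a)) for a in NUMERIC_ATTRIBUTES]


def classify_edge(u: tuple[str, str], v: tuple[str, str]) -> EdgeClass:
    """Classify an edge by shared species and shared behavior class.

    Two distinct nodes of one species necessarily differ in behavior class,
    so intra_species implies inter_behavior.
    """
    if u == v:
        raise ValueError(f"self-edge at node {u!r}")
    return EdgeClass(
        species_relation="intra_species" if u[0] == v[0] else "inter_species",
        behavior_relation="intra_behavior" if u[1] == v[1] else "inter_behavior",
    )


def edge_density_pct(n_edges: int, universe_size: int) -> float:
    """Edge count as a percentage of all pairs in the fixed node universe,
    rounded half-away to one decimal."""
    if universe_size < 2:
        raise ValueError(f"universe_size {universe_size} < 2")
    max_edges = universe_size * (universe_size - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"n_edges {n_edges} exceeds maximum {max_edges} "
            f"for a {universe_size}-node simple graph"
        )
    return round_half_away(100.0 * n_edges / max_edges, 1)


def summarize_network(
    net: SBANetwork, hub_species: list[str] | None = None
) -> NetworkSummary:
    """Tally the attribute row for one stratum network.

    ``hub_species`` is filled by the keystone ranking stage when available.
    """
    g = net.graph
    active = [n for n in g.nodes if g.degree(n) > 0]
    sips = {"intra_species": 0, "inter_species": 0}
    bips = {"intra_behavior": 0, "inter_behavior": 0}
    for u, v in g.edges:
        ec = classify_edge(u, v)
        sips[ec.species_relation] += 1
        bips[ec.behavior_relation] += 1
    return NetworkSummary(
        regime=net.regime,
        habitat=net.habitat,
        n_species=len({sp for sp, _ in active}),
        active_nodes=len(active),
        n_edges=g.number_of_edges(),
        density_pct=edge_density_pct(g.number_of_edges(), g.number_of_nodes()),
        sips_intra=sips["intra_species"],
        sips_inter=sips["inter_species"],
        bips_intra=bips["intra_behavior"],
        bips_inter=bips["inter_behavior"],
        hub_species=list(hub_species or []),
    )


def write_summary_table(summaries: list[NetworkSummary], path) -> None:
    if not summaries:
        raise ValueError("no summaries to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_COLUMNS)
        for s in summaries:
            writer.writerow(
                [
                    s.regime,
                    s.habitat,
                    s.n_species,
                    s.active_nodes,
                    s.n_edges,
                    s.density_pct,
                    s.sips_intra,
                    s.sips_inter,
                    s.bips_intra,
                    s.bips_inter,
                    ";".join(s.hub_species),
                ]
            )


def read_summary_table(path) -> list[NetworkSummary]:
    summaries: list[NetworkSummary] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in SUMMARY_COLUMNS:
            if col not in (reader.fieldnames or []):
                raise ValueError(f"summary table is missing column {col!r}")
        for row in reader:
            summaries.append(
                NetworkSummary(
                    regime=row["regime"],
                    habitat=row["habitat"],
                    n_species=int(row["n_species"]),
                    active_nodes=int(row["active_nodes"]),
                    n_edges=int(row["n_edges"]),
                    density_pct=float(row["density_pct"]),
                    sips_intra=int(row["sips_intra"]),
                    sips_inter=int(row["sips_inter"]),
                    bips_intra=int(row["bips_intra"]),
                    bips_inter=int(row["bips_inter"]),
                    hub_species=(
                        row["hub_species"].split(";")
                        if row["hub_species"]
                        else []
                    ),
                )
            )
    return summaries
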