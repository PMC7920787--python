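from __future__ import annotations

import networkx as nx
import pytest

import sbanet
from sbanet import datasets
from sbanet.sban_build import SBANetwork


@pytest.fixture(scope="session")
def catalog():
    return datasets.load_default_catalog()


@pytest.fixture(scope="session")
def reference_summaries():
    return datasets.load_reference_summaries()


def make_network(edges, nodes=(), regime="R1", habitat="MF") -> SBANetwork:
    """Small hand-built network: edges as ((sp, bc), (sp, bc), weight)."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_weighted_edges_from(edges)
    return SBANetwork(regime=regime, habitat=habitat, graph=g)


@pytest.fixture(scope="session")
def bridged_scenario(catalog):
    """Simulated planted-block network plus its ground truth (seed fixed)."""
    from sbanet import synthetic_data

    config, block1, block2, bridge = synthetic_data.bridged_blocks_scenario(
        catalog, n_days=1000, rho=0.6, seed=0
    )
    events = sbanet.filter_daily_best(sbanet.simulate_events(config))
    matrix = sbanet.pivot_abundance(events, catalog, "R1", "MF")
    net = sbanet.build_stratum_network(matrix)
    return {
        "config": config,
        "matrix": matrix,
        "network": net,
        "block1": block1,
        "block2": block2,
        "bridge": bridge,
    }
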