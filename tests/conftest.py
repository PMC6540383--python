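import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from chiamod import synthetic_data as sd


@pytest.fixture(scope="session")
def planted_graph():
    """Standard 3x30 planted-module graph with mixed annotation classes."""
    g, labels = sd.gen_planted_graph(sd.PlantedNetworkSpec(seed=7))
    return g, labels


@pytest.fixture(scope="session")
def coexpression_fixture():
    """3 modules x 20 genes with intra-module expression correlation 0.8."""
    spec = sd.PlantedNetworkSpec(module_sizes=(20, 20, 20),
                                 label_fractions={"gene": 1.0}, seed=3)
    g, labels = sd.gen_planted_graph(spec)
    expr = sd.gen_expression(labels, ["gene"] * len(labels),
                             sd.ExpressionSimSpec(seed=3))
    return g, labels, expr


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Full on-disk fixture bundle plus its truth JSON."""
    out = tmp_path_factory.mktemp("bundle")
    paths = sd.write_fixture_bundle(out, seed=11)
    return paths


@pytest.fixture
def two_cliques_bridge():
    """Two 10-cliques joined by a single bridge edge."""
    g = nx.complete_graph(10)
    h = nx.complete_graph(10)
    g = nx.disjoint_union(g, h)
    g.add_edge(0, 10)
    return g


def random_connected_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        if n < 2 or nx.is_connected(g):
            return g
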