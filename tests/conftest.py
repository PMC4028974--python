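import networkx as nx
import numpy as np
import pytest


def _named_small_graphs() -> dict[str, nx.Graph]:
    """Every graph here has <= 20 nodes; centralities are oracle-checked on all."""
    graphs: dict[str, nx.Graph] = {}
    graphs["triangle"] = nx.complete_graph(3)
    graphs["star4"] = nx.star_graph(4)
    graphs["path3"] = nx.path_graph(3)
    graphs["path5"] = nx.path_graph(5)
    graphs["cycle6"] = nx.cycle_graph(6)
    graphs["petersen"] = nx.petersen_graph()
    disconnected = nx.disjoint_union(nx.complete_graph(3), nx.path_graph(2))
    disconnected.add_node(99)  # isolated node
    graphs["disconnected"] = disconnected
    for s in range(4):
        g = nx.gnp_random_graph(15, 0.2, seed=s)
        graphs[f"gnp15_seed{s}"] = g
    return {name: nx.relabel_nodes(g, {v: f"N{v}" for v in g.nodes()})
            for name, g in _as_items(graphs)}


def _as_items(d):
    return d.items()


SMALL_GRAPHS = _named_small_graphs()


@pytest.fixture(params=sorted(SMALL_GRAPHS), ids=sorted(SMALL_GRAPHS))
def small_graph(request) -> nx.Graph:
    return SMALL_GRAPHS[request.param]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130)


# ---- independent centrality oracles (exhaustive, networkx-path based) ----

def degree_oracle(g: nx.Graph) -> dict:
    return {v: sum(1 for e in g.edges() if v in e) for v in g.nodes()}


def closeness_oracle(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes():
        far = sum(nx.single_source_shortest_path_length(g, v).values())
        out[v] = 1.0 / far if far > 0 else 0.0
    return out


def stress_oracle(g: nx.Graph) -> dict:
    """Count shortest paths through each node by explicit path enumeration."""
    stress = dict.fromkeys(g.nodes(), 0)
    nodes = sorted(g.nodes())
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if not nx.has_path(g, s, t):
                continue
            for path in nx.all_shortest_paths(g, s, t):
                for v in path[1:-1]:
                    stress[v] += 1
    return stress
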