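"""PPI graphs and the three node centralities used for miRNA scoring.

Graphs are plain :class:`networkx.Graph` objects over upper-case gene
symbols: simple, undirected, unweighted; self-loops are dropped on load and
isolated nodes are permitted.

Centralities
------------
degree
    Number of incident edges — the package's proxy for a protein's
    functional importance.
closeness
    Unnormalised reciprocal farness restricted to the node's connected
    component: ``closeness(v) = 1 / sum_{u in comp(v), u != v} d(v, u)``,
    0 for an isolated node.  This is the classic CentiScaPe-style variant;
    distances to unreachable nodes are excluded, not treated as infinite.
stress
    Shimbel stress: the number of shortest paths between other node pairs
    that pass through the node, counting each unordered pair {s, t} once.
    Computed with breadth-first search and Brandes-style path counting in
    O(n·m).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import ConfigError, FormatError
from .interactions import normalize_gene_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "CentralityProfile",
    "NetworkSummary",
    "load_graph",
    "write_graph",
    "build_seed_network",
    "degree_centrality",
    "closeness_centrality",
    "stress_centrality",
    "centrality_profile",
    "network_summary",
]

METRICS = ("degree", "closeness", "stress")


@dataclass
class CentralityProfile:
    """Per-node degree, closeness and stress for one graph."""

    graph_id: str
    degree: dict[str, int]
    closeness: dict[str, float]
    stress: dict[str, int]

    def metric(self, name: str) -> Mapping[str, float]:
        if name not in METRICS:
            raise ConfigError(f"unknown centrality metric '{name}'")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        nodes = sorted(self.degree)
        return pd.DataFrame(
            {
                "node": nodes,
                "degree": [self.degree[n] for n in nodes],
                "closeness": [self.closeness[n] for n in nodes],
                "stress": [self.stress[n] for n in nodes],
            }
        )


@dataclass
class NetworkSummary:
    """Arithmetic means of the three centralities over all nodes."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    mean_closeness: float
    mean_stress: float


def _new_graph(nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def load_graph(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read a PPI graph from a SIF or two-column edge-list file.

    Format is inferred from the extension (``.sif`` → SIF, else edge list)
    unless ``fmt`` is given.  Symbols are upper-cased; self-loops are
    dropped (count logged); duplicate edges collapse.  SIF lines follow the
    Cytoscape fan-out rule: ``A <tab> rel <tab> B C`` yields edges (A,B) and
    (A,C); a line holding a single symbol declares an isolated node.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "edgelist"
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    n_loops = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if fmt == "sif":
            if len(fields) == 1:
                nodes.add(normalize_gene_symbol(fields[0]))
                continue
            if len(fields) == 2:
                raise FormatError(f"{path}:{lineno}: SIF line has a relation but no target")
            src = normalize_gene_symbol(fields[0])
            targets = [normalize_gene_symbol(t) for t in fields[2:]]
        else:
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: edge list line needs two symbols")
            src = normalize_gene_symbol(fields[0])
            targets = [normalize_gene_symbol(fields[1])]
        nodes.add(src)
        for tgt in targets:
            nodes.add(tgt)
            if tgt == src:
                n_loops += 1
                continue
            edges.add(tuple(sorted((src, tgt))))
    if n_loops:
        logger.info("%s: dropped %d self-loops", path, n_loops)
    return _new_graph(nodes, edges)


def write_graph(g: nx.Graph, path: str | Path, fmt: str = "sif") -> None:
    """Write a graph as SIF, edge list or GraphML.

    SIF/edge-list writes round-trip through :func:`load_graph` to an equal
    node/edge set; SIF uses the relation token ``pp``.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
        return
    if fmt not in ("sif", "edgelist"):
        raise ConfigError(f"unknown graph format '{fmt}'")
    lines = []
    for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
        lines.append(f"{a}\tpp\t{b}" if fmt == "sif" else f"{a}\t{b}")
    if fmt == "sif":
        for v in sorted(n for n in g.nodes() if g.degree(n) == 0):
            lines.append(v)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _sssp(g: nx.Graph, source):
    """BFS from ``source``: returns (visit order, distances, path counts, predecessors)."""
    dist = {source: 0}
    sigma = {source: 1}
    preds: dict = {source: []}
    order = [source]
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in g[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                preds[w] = []
                order.append(w)
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return order, dist, sigma, preds


def degree_centrality(g: nx.Graph) -> dict[str, int]:
    """Integer degree of every node."""
    return {v: int(d) for v, d in g.degree()}


def closeness_centrality(g: nx.Graph) -> dict[str, float]:
    """Reciprocal farness within each node's component (0 for isolated nodes)."""
    out = {}
    for v in g.nodes():
        _, dist, _, _ = _sssp(g, v)
        farness = sum(dist.values())  # d(v, v) = 0 contributes nothing
        out[v] = 1.0 / farness if farness > 0 else 0.0
    return out


def stress_centrality(g: nx.Graph) -> dict[str, int]:
    """Shimbel stress over unordered source/target pairs.

    Accumulation per source s: ``delta_s(v) = sum over successors w of
    sigma_sv * (1 + delta_s(w) / sigma_sw)`` — the number of shortest paths
    from s through v.  Summing over all sources counts each {s, t} pair
    twice, so the total is halved.
    """
    stress = dict.fromkeys(g.nodes(), 0.0)
    for s in g.nodes():
        order, dist, sigma, preds = _sssp(g, s)
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] * (1.0 + delta[w] / sigma[w])
            if w != s:
                stress[w] += delta[w]
    return {v: round(x / 2.0) for v, x in stress.items()}


def centrality_profile(g: nx.Graph, graph_id: str = "graph") -> CentralityProfile:
    """Compute all three centralities for one graph."""
    return CentralityProfile(
        graph_id=graph_id,
        degree=degree_centrality(g),
        closeness=closeness_centrality(g),
        stress=stress_centrality(g),
    )


def network_summary(g: nx.Graph) -> NetworkSummary:
    """Arithmetic means of degree/closeness/stress over all nodes (isolated included)."""
    n = g.number_of_nodes()
    if n == 0:
        raise ConfigError("network_summary requires a non-empty graph")
    prof = centrality_profile(g)
    return NetworkSummary(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        mean_degree=sum(prof.degree.values()) / n,
        mean_closeness=sum(prof.closeness.values()) / n,
        mean_stress=sum(prof.stress.values()) / n,
    )


def build_seed_network(
    global_graph: nx.Graph,
    seeds: Iterable[str],
    mode: str = "induced",
    max_bridge_len: int = 2,
) -> nx.Graph:
    """Extract the subnetwork around a set of seed proteins.

    ``induced``: the subgraph induced on the seeds present in the global
    graph; seeds absent from the global graph are dropped (count logged).
    ``bridged``: additionally recruit every non-seed node lying on at least
    one shortest path of length <= ``max_bridge_len`` between two retained
    seeds, then induce on the full retained set.  Bridging stands in for the
    literature-derived "shortest path" network expansion that cannot be
    reproduced from a plain edge list.
    """
    seed_set = {normalize_gene_symbol(s) for s in seeds}
    if not seed_set:
        raise ConfigError("seed set must be non-empty")
    present = seed_set & set(global_graph.nodes())
    n_absent = len(seed_set) - len(present)
    if n_absent:
        logger.info("dropped %d seeds absent from the global graph", n_absent)
    if mode == "induced":
        return nx.Graph(global_graph.subgraph(present))
    if mode != "bridged":
        raise ConfigError(f"unknown seed-network mode '{mode}'")
    if max_bridge_len < 1:
        raise ConfigError("max_bridge_len must be >= 1")
    dists = {s: _sssp(global_graph, s)[1] for s in present}
    keep = set(present)
    seed_list = sorted(present)
    for i, s in enumerate(seed_list):
        ds = dists[s]
        for t in seed_list[i + 1 :]:
            d_st = ds.get(t)
            if d_st is None or d_st > max_bridge_len:
                continue
            dt = dists[t]
            for v in global_graph.nodes():
                if v in keep or v not in ds or v not in dt:
                    continue
                if ds[v] + dt[v] == d_st:
                    keep.add(v)
    return nx.Graph(global_graph.subgraph(keep))
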