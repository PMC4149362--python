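"""Query-Query PPI (QQPPI) network construction, merging and summary.

A QQPPI network is the subgraph of an interactome induced on a query
gene set: it contains query nodes only, with every interactome edge
whose two endpoints are both queries.  Networks built from different
interactome exports are merged by edge-set union (each edge keeps the
union of its source tags), mirroring a workflow that maximizes
database coverage; intersection semantics are available via flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .datatypes import Interactome, canonical_edge

logger = logging.getLogger(__name__)


@dataclass
class QQPPINetwork:
    """Simple undirected graph on query genes with per-edge provenance."""

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def degree_of(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class GlobalStats:
    """Global network summary (node/edge counts, degree and betweenness)."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    max_degree: int
    avg_betweenness: float
    max_betweenness: float


def average_degree(n_nodes: int, n_edges: int) -> float:
    """2|E|/|V|; zero for the empty graph."""
    return 2.0 * n_edges / n_nodes if n_nodes else 0.0


def build_qqppi(
    query: set[str], interactome: Interactome, keep_isolated: bool = False
) -> QQPPINetwork:
    """Induce the interactome subgraph on a query gene set.

    By default, query genes with no intra-query interaction do not
    become nodes (only interacting queries enter the network);
    ``keep_isolated`` retains them as degree-0 nodes.
    """
    if not query:
        raise ValueError("query gene set is empty")
    net = QQPPINetwork()
    for (a, b), tags in interactome.edges.items():
        if a in query and b in query:
            net.edges[(a, b)] = set(tags)
            net.nodes.add(a)
            net.nodes.add(b)
    if keep_isolated:
        net.nodes |= set(query)
    return net


def merge_networks(
    a: QQPPINetwork, b: QQPPINetwork, mode: str = "union"
) -> QQPPINetwork:
    """Merge two QQPPI networks.

    ``union`` (default) keeps every edge of either network; an edge
    present in both appears once with concatenated provenance.
    ``intersection`` keeps only shared edges (and their endpoints).
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown merge mode: {mode}")
    out = QQPPINetwork()
    if mode == "union":
        out.nodes = set(a.nodes) | set(b.nodes)
        for src in (a, b):
            for edge, tags in src.edges.items():
                out.edges.setdefault(edge, set()).update(tags)
    else:
        shared = set(a.edges) & set(b.edges)
        for edge in shared:
            out.edges[edge] = set(a.edges[edge]) | set(b.edges[edge])
            out.nodes.update(edge)
    return out


def network_from_edges(edges, source: str | None = None) -> QQPPINetwork:
    """Convenience constructor from an iterable of (a, b) pairs."""
    net = QQPPINetwork()
    for a, b in edges:
        if a == b:
            continue
        key = canonical_edge(a, b)
        net.edges.setdefault(key, set())
        if source:
            net.edges[key].add(source)
        net.nodes.update(key)
    return net


def network_summary(net: QQPPINetwork, topo) -> GlobalStats:
    """Global stats from a network and its topology attributes."""
    if net.n_nodes == 0:
        logger.warning("network_summary: empty network")
        return GlobalStats(0, 0, 0.0, 0, 0.0, 0.0)
    degrees = [topo.degree_of[v] for v in net.nodes]
    btw = [topo.betweenness_of[v] for v in net.nodes]
    return GlobalStats(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        avg_degree=average_degree(net.n_nodes, net.n_edges),
        max_degree=max(degrees),
        avg_betweenness=sum(btw) / len(btw),
        max_betweenness=max(btw),
    )
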