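"""Degree/betweenness topology and hub/bottleneck classification.

Hubs (high-connectivity nodes) are nodes whose degree reaches the mean
plus twice the standard deviation of the degree distribution.
Bottlenecks (high-betweenness low-connectivity nodes) are non-hub
nodes in the top half of the betweenness distribution that are
directly connected to at least two hubs.

Betweenness is the unnormalized Brandes accumulation over unordered
source-target pairs with endpoints excluded, computed per connected
component and applied globally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import PreconditionError
from .network import QQPPINetwork

logger = logging.getLogger(__name__)


@dataclass
class TopologyAttributes:
    degree_of: dict[str, int]
    betweenness_of: dict[str, float]


@dataclass(frozen=True)
class HubCutoff:
    """Degree cutoff for hub status: mean + 2 * sd of the degrees."""

    mean_degree: float
    sd_degree: float

    @property
    def cutoff(self) -> float:
        return self.mean_degree + 2.0 * self.sd_degree

    @property
    def rounded_cutoff(self) -> int:
        return round(self.cutoff)


@dataclass
class NodeClassification:
    """Hub/bottleneck roles with the per-node evidence used to assign them.

    ``evidence`` maps node -> (degree, betweenness, hub-neighbor count).
    """

    hubs: set[str]
    bottlenecks: set[str]
    evidence: dict[str, tuple[int, float, int]]
    cutoff: HubCutoff


def to_networkx(net: QQPPINetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)
    return g


def compute_topology(net: QQPPINetwork) -> TopologyAttributes:
    """Degree and betweenness for every node of the network.

    networkx's unnormalized betweenness for undirected graphs counts
    each unordered pair once with endpoints excluded, which is the
    convention used throughout.
    """
    g = to_networkx(net)
    degree = {v: int(d) for v, d in g.degree()}
    btw = nx.betweenness_centrality(g, normalized=False)
    return TopologyAttributes(degree, {v: float(b) for v, b in btw.items()})


def hub_cutoff(topo: TopologyAttributes, sd_mode: str = "sample") -> HubCutoff:
    """Mean + 2 sd cutoff over the degree distribution.

    ``sd_mode`` selects the sample (n-1, default) or population (n)
    standard deviation.
    """
    if sd_mode not in ("sample", "population"):
        raise PreconditionError(f"unknown sd_mode: {sd_mode}")
    degrees = np.array(list(topo.degree_of.values()), dtype=float)
    if degrees.size < 2:
        raise PreconditionError("hub cutoff needs at least 2 nodes")
    sd = float(degrees.std(ddof=1 if sd_mode == "sample" else 0))
    cut = HubCutoff(float(degrees.mean()), sd)
    if sd == 0.0:
        logger.warning(
            "hub_cutoff: degenerate regular graph (sd=0); every node meets the cutoff"
        )
    return cut


def classify_hubs(topo: TopologyAttributes, cutoff: HubCutoff) -> set[str]:
    """Nodes with degree >= the (unrounded) cutoff."""
    return {v for v, d in topo.degree_of.items() if d >= cutoff.cutoff}


def classify_bottlenecks(
    net: QQPPINetwork, topo: TopologyAttributes, hubs: set[str], cutoff: HubCutoff
) -> set[str]:
    """Non-hub, top-half-betweenness nodes adjacent to >= 2 hubs.

    The top half is positional: nodes are ranked by betweenness
    descending and the first ceil(|V|/2) ranks qualify, with boundary
    ties included (every node whose betweenness equals the boundary
    value qualifies).
    """
    nodes = list(net.nodes)
    if not nodes:
        return set()
    ranked = sorted(nodes, key=lambda v: -topo.betweenness_of[v])
    half = math.ceil(len(ranked) / 2)
    boundary = topo.betweenness_of[ranked[half - 1]]
    top = {v for v in nodes if topo.betweenness_of[v] >= boundary}
    adj = net.adjacency()
    out = set()
    for v in top:
        if topo.degree_of[v] >= cutoff.cutoff:
            continue
        if len(adj[v] & hubs) >= 2:
            out.add(v)
    return out


def classify_nodes(
    net: QQPPINetwork, topo: TopologyAttributes | None = None, sd_mode: str = "sample"
) -> NodeClassification:
    """Full hub/bottleneck classification of a network."""
    if topo is None:
        topo = compute_topology(net)
    cut = hub_cutoff(topo, sd_mode=sd_mode)
    hubs = classify_hubs(topo, cut)
    bottlenecks = classify_bottlenecks(net, topo, hubs, cut)
    adj = net.adjacency()
    evidence = {
        v: (topo.degree_of[v], topo.betweenness_of[v], len(adj[v] & hubs))
        for v in net.nodes
    }
    return NodeClassification(hubs, bottlenecks, evidence, cut)
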