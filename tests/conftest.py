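"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: betweenness
is accumulated from explicit per-pair shortest-path counts, cliques
from exhaustive combinations, the hypergeometric tail from a direct
combinatorial sum.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from qqppi.network import QQPPINetwork, network_from_edges


# ---------------------------------------------------------------------------
# oracles


def brute_force_betweenness(net: QQPPINetwork) -> dict[str, float]:
    """Per-node betweenness from explicit BFS path counting.

    For every unordered pair (s, t), sigma_st comes from a BFS path-count
    DP; the fraction through v uses sigma_sv * sigma_vt when v lies on a
    shortest path.  Endpoints excluded, no normalization.
    """
    nodes = sorted(net.nodes)
    adj = net.adjacency()

    def bfs(src):
        dist = {src: 0}
        sigma = {src: 1}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        sigma[w] = 0
                        nxt.append(w)
                    if dist[w] == dist[u] + 1:
                        sigma[w] += sigma[u]
            frontier = nxt
        return dist, sigma

    tables = {v: bfs(v) for v in nodes}
    btw = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist_s, sigma_s = tables[s]
        if t not in dist_s:
            continue
        d_st = dist_s[t]
        total = sigma_s[t]
        for v in nodes:
            if v in (s, t) or v not in dist_s:
                continue
            dist_v, sigma_v = tables[v]
            if t in dist_v and dist_s[v] + dist_v[t] == d_st:
                btw[v] += sigma_s[v] * sigma_v[t] / total
    return btw


def brute_force_cliques(net: QQPPINetwork, k: int) -> set[tuple[str, ...]]:
    """All k-subsets of nodes that are pairwise connected."""
    edges = set(net.edges)
    out = set()
    for combo in combinations(sorted(net.nodes), k):
        if all(tuple(sorted(p)) in edges for p in combinations(combo, 2)):
            out.add(combo)
    return out


def hypergeom_tail_sum(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) summed term by term from binomial coefficients."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= N - K
    ) / total


def random_graph(n_nodes: int, p: float, rng: np.random.Generator) -> QQPPINetwork:
    names = [f"N{i:02d}" for i in range(n_nodes)]
    edges = [
        (names[i], names[j])
        for i, j in combinations(range(n_nodes), 2)
        if rng.random() < p
    ]
    net = network_from_edges(edges)
    net.nodes.update(names)  # keep isolated nodes
    return net


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def planted_bundle():
    """One seeded synthetic bundle with expression + interactome truth."""
    from qqppi import synthetic

    spec = synthetic.SyntheticSpec(
        n_genes=600, n_proteins=200, seed=11,
        interactome_model="planted", n_planted_cliques=3, n_planted_hubs=2,
    )
    data, truth = synthetic.generate_expression(spec)
    inter, itruth = synthetic.generate_interactome(spec)
    truth.planted_cliques = itruth.planted_cliques
    truth.planted_hub_genes = itruth.planted_hub_genes
    return spec, data, inter, truth


@pytest.fixture()
def toy_net() -> QQPPINetwork:
    """Two triangles joined through a bridge node."""
    return network_from_edges(
        [("A", "B"), ("B", "C"), ("A", "C"),
         ("C", "D"), ("D", "E"),
         ("E", "F"), ("F", "G"), ("E", "G")]
    )
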