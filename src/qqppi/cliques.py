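"""3/4-clique enumeration and the core functional module.

Cliques are complete subgraphs; in a PPI network a clique is a set of
proteins that all pairwise interact.  Triangles are enumerated by the
edge-iterator method (intersect the sorted neighbor sets of an edge's
endpoints), and 4-cliques by extending each triangle with a common
neighbor above the triangle's maximum node, so every clique appears
exactly once in canonical (sorted-tuple) form.  The union of all 3-
and 4-cliques forms the core functional module, the tightly knitted
subnetwork that concentrates the topologically significant nodes.

By default all complete subgraphs of the requested size are reported
(triangles inside a 4-clique count among the 3-cliques);
``maximal_only`` suppresses k-cliques contained in a (k+1)-clique.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from .errors import PreconditionError
from .network import QQPPINetwork

logger = logging.getLogger(__name__)

Clique = tuple[str, ...]


@dataclass
class CoreModule:
    """Union subnetwork of all 3- and 4-cliques with occurrence counts."""

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    occurrence_3: dict[str, int] = field(default_factory=dict)
    occurrence_4: dict[str, int] = field(default_factory=dict)


def _triangles(adj: dict[str, set[str]]) -> set[Clique]:
    out: set[Clique] = set()
    for a in sorted(adj):
        for b in adj[a]:
            if b <= a:
                continue
            for c in adj[a] & adj[b]:
                if c > b:
                    out.add((a, b, c))
    return out


def enumerate_k_cliques(
    net: QQPPINetwork, k: int, maximal_only: bool = False
) -> set[Clique]:
    """All k-cliques (k in {3, 4}) of the network in canonical form.

    With ``maximal_only``, k-cliques contained in some (k+1)-clique are
    dropped.  A warning is logged if any 5-clique exists, since the
    downstream module analysis assumes none.
    """
    if k not in (3, 4):
        raise PreconditionError("k must be 3 or 4")
    adj = net.adjacency()
    tris = _triangles(adj)
    quads: set[Clique] = set()
    for a, b, c in tris:
        for d in adj[a] & adj[b] & adj[c]:
            if d > c:
                quads.add((a, b, c, d))
    _warn_if_5_clique(adj, quads)
    if k == 4:
        if maximal_only:
            return {q for q in quads if not _in_quint(adj, q)}
        return quads
    if maximal_only:
        covered = {t for q in quads for t in combinations(q, 3)}
        return tris - covered
    return tris


def _in_quint(adj: dict[str, set[str]], quad: Clique) -> bool:
    a, b, c, d = quad
    return bool(adj[a] & adj[b] & adj[c] & adj[d])


def _warn_if_5_clique(adj: dict[str, set[str]], quads: set[Clique]) -> None:
    for a, b, c, d in quads:
        if adj[a] & adj[b] & adj[c] & adj[d]:
            logger.warning(
                "enumerate_k_cliques: a 5-clique exists (containing %s); "
                "the 3/4-clique module analysis assumes none", (a, b, c, d)
            )
            return


def core_functional_module(
    cliques3: set[Clique], cliques4: set[Clique], net: QQPPINetwork
) -> CoreModule:
    """Union of all cliques with per-node 3-/4-clique occurrence counts."""
    module = CoreModule()
    c3 = Counter(v for t in cliques3 for v in t)
    c4 = Counter(v for q in cliques4 for v in q)
    for group in (cliques3, cliques4):
        for clique in group:
            module.nodes.update(clique)
            for a, b in combinations(clique, 2):
                edge = (a, b) if a <= b else (b, a)
                if edge not in net.edges:
                    raise PreconditionError(
                        f"clique pair {edge} is not an edge of the host network"
                    )
                module.edges.add(edge)
    module.occurrence_3 = {v: c3.get(v, 0) for v in module.nodes}
    module.occurrence_4 = {v: c4.get(v, 0) for v in module.nodes}
    return module
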