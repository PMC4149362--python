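"""Match clique-forming proteins against a protein-complex catalog.

Each catalog complex is scored by how many query proteins (by default
the proteins occurring in any 3- or 4-clique) it contains; complexes
reaching a per-run minimum are reported with their full membership and
the matched subset, sorted by match size descending then id.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import ComplexCatalog
from .errors import PreconditionError


@dataclass(frozen=True)
class ComplexMatch:
    complex_id: str
    name: str
    all_members: frozenset[str]
    matched_query: frozenset[str]

    @property
    def n_matched(self) -> int:
        return len(self.matched_query)


def match_complexes(
    query: set[str], catalog: ComplexCatalog, min_query: int
) -> list[ComplexMatch]:
    """Catalog complexes containing at least ``min_query`` query proteins."""
    if min_query < 1:
        raise PreconditionError("min_query must be >= 1")
    out = []
    for cid, (name, members) in catalog.complexes.items():
        matched = members & query
        if len(matched) >= min_query:
            out.append(ComplexMatch(cid, name, members, frozenset(matched)))
    out.sort(key=lambda m: (-m.n_matched, m.complex_id))
    return out


def clique_proteins(cliques3, cliques4) -> set[str]:
    """The query set for complex matching: all clique-forming proteins."""
    return {v for c in cliques3 for v in c} | {v for c in cliques4 for v in c}
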