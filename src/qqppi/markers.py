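"""Novel network disease-marker identification and annotation.

Per network, candidate markers are the topologically significant nodes
(hubs union bottlenecks) minus the known-disease-gene list.  Across
networks the multiplicity total sums the per-network candidate counts,
while the unique marker set is their union with per-network provenance
retained.  Markers are then annotated with core-module membership
(3-/4-clique occurrence counts), matched complexes and curated
neurotransmitter associations, and two prioritized subsets are
reported: markers inside the core functional module, and markers with
at least one neurotransmitter association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cliques import CoreModule
from .errors import PreconditionError

logger = logging.getLogger(__name__)


@dataclass
class MarkerRecord:
    gene: str
    roles: set[tuple[str, str]]  # (network id, "hub"|"bottleneck")
    in_core_module: bool = False
    occurrence_3: int = 0
    occurrence_4: int = 0
    complexes: list[str] = field(default_factory=list)
    neurotransmitters: list[str] = field(default_factory=list)


@dataclass
class MarkerReport:
    markers: dict[str, MarkerRecord]
    multiplicity_total: int
    core_module_markers: set[str]
    neuro_markers: set[str]


def novel_markers(
    classifications: dict[str, "NodeClassification"], known: set[str]
) -> tuple[dict[str, MarkerRecord], int]:
    """Unique unreported markers and the per-network multiplicity total.

    ``classifications`` maps a network id to its hub/bottleneck
    classification.  Per network the candidate set is
    (hubs | bottlenecks) - known; the multiplicity total counts each
    network's candidates separately, so a gene significant in several
    networks contributes once per network.
    """
    if not classifications:
        raise PreconditionError("at least one network classification is required")
    markers: dict[str, MarkerRecord] = {}
    multiplicity = 0
    for net_id in sorted(classifications):
        cls = classifications[net_id]
        for role, nodes in (("hub", cls.hubs), ("bottleneck", cls.bottlenecks)):
            for gene in nodes - known:
                rec = markers.setdefault(gene, MarkerRecord(gene, set()))
                rec.roles.add((net_id, role))
        multiplicity += len((cls.hubs | cls.bottlenecks) - known)
    return markers, multiplicity


def annotate_markers(
    markers: dict[str, MarkerRecord],
    core: CoreModule | None = None,
    matches=None,
    neuro_table: dict[str, list[str]] | None = None,
) -> MarkerReport:
    """Attach clique, complex and neurotransmitter evidence to markers."""
    for gene, rec in markers.items():
        if core is not None and gene in core.nodes:
            rec.in_core_module = True
            rec.occurrence_3 = core.occurrence_3.get(gene, 0)
            rec.occurrence_4 = core.occurrence_4.get(gene, 0)
    if matches:
        for match in matches:
            for gene in match.matched_query:
                if gene in markers:
                    markers[gene].complexes.append(match.complex_id)
    if neuro_table:
        for gene, labels in neuro_table.items():
            if gene in markers:
                markers[gene].neurotransmitters = list(labels)
            else:
                logger.info("annotate_markers: %s in association table but not a marker", gene)
    multiplicity = sum(len(r.roles) for r in markers.values())
    return MarkerReport(
        markers=markers,
        multiplicity_total=multiplicity,
        core_module_markers={g for g, r in markers.items() if r.in_core_module},
        neuro_markers={g for g, r in markers.items() if r.neurotransmitters},
    )
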