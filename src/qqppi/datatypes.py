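"""Core in-memory containers for the pipeline.

The substrate of every statistic is an :class:`ExpressionDataset` — a
log2-scale genes x samples matrix with a two-group (control/disease)
phenotype.  Interaction data live in an :class:`Interactome` (a
deduplicated undirected edge set with per-edge source tags), protein
complexes in a :class:`ComplexCatalog` and term->gene-set annotation
(biological-process style) in a :class:`TermAnnotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, PreconditionError

CONTROL = "control"
DISEASE = "disease"


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an undirected gene-symbol pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ExpressionDataset:
    """Log2 expression matrix with two-group phenotype labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes as the index (unique symbols), samples as columns.
    group_of : Mapping[str, str]
        Sample id -> ``"control"`` or ``"disease"``; must cover every
        sample column and provide at least one sample per group.
    """

    values: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str).str.strip()
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols after collapse: {dups}")
        missing = [s for s in self.values.columns if s not in self.group_of]
        if missing:
            raise FormatError(f"samples missing from phenotype: {missing}")
        bad = {s: g for s, g in self.group_of.items() if g not in (CONTROL, DISEASE)}
        if bad:
            raise FormatError(f"unknown phenotype groups: {bad}")
        groups = {self.group_of[s] for s in self.values.columns}
        if groups != {CONTROL, DISEASE}:
            raise PreconditionError(
                "dataset must contain at least one control and one disease sample"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def group_matrix(self, group: str) -> pd.DataFrame:
        """Submatrix (genes x samples) restricted to one phenotype group."""
        return self.values[self.samples_in_group(group)]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionDataset(self.values.loc[keep].copy(), dict(self.group_of))


@dataclass
class Interactome:
    """Undirected simple edge set over gene symbols with source tags.

    ``edges`` maps each canonical unordered pair to the set of source
    labels (e.g. which database export contributed it).  Self-pairs are
    rejected; an unordered pair is stored exactly once.
    """

    edges: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, source: str | None = None) -> bool:
        """Add an undirected edge; returns False for a dropped self-loop."""
        a, b = a.strip(), b.strip()
        if a == b:
            return False
        key = canonical_edge(a, b)
        tags = self.edges.setdefault(key, set())
        if source is not None:
            tags.add(source)
        return True

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ComplexCatalog:
    """Protein-complex catalog: id -> (name, member gene set)."""

    complexes: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def add(self, cid: str, name: str, members: Iterable[str]) -> None:
        if cid in self.complexes:
            raise FormatError(f"duplicate complex id: {cid}")
        members = frozenset(m.strip() for m in members if m.strip())
        if not members:
            raise FormatError(f"complex {cid} has no members")
        self.complexes[cid] = (name, members)

    def __len__(self) -> int:
        return len(self.complexes)


@dataclass
class TermAnnotation:
    """Term -> (name, namespace, gene set) annotation (GMT-style)."""

    terms: dict[str, tuple[str, str, frozenset[str]]] = field(default_factory=dict)

    def add(self, term_id: str, name: str, namespace: str, genes: Iterable[str]) -> None:
        if term_id in self.terms:
            raise FormatError(f"duplicate term id: {term_id}")
        genes = frozenset(g.strip() for g in genes if g.strip())
        if not genes:
            raise FormatError(f"term {term_id} has an empty gene set")
        self.terms[term_id] = (name, namespace, genes)

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][2]

    def __len__(self) -> int:
        return len(self.terms)


def matrix_from_arrays(
    values: np.ndarray, gene_ids: list[str], sample_ids: list[str]
) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(values, dtype=float), index=gene_ids, columns=sample_ids)
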