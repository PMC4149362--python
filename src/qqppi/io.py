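"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV; graphs are SIF in and GraphML out
(the GraphML replaces interactive network-viewer export).  Readers are
tolerant of line-ending dialect (LF/CRLF) and trailing whitespace;
writers emit LF with floats at 6 decimal places so that outputs are
bit-stable across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .datatypes import ComplexCatalog, ExpressionDataset, Interactome, TermAnnotation
from .errors import FormatError

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6f"

#: supported probe-collapse policies for duplicate gene symbols
COLLAPSE_POLICIES = ("mean", "max-mean-row", "first")


def read_expression(
    matrix_path: str | Path,
    phenotype_path: str | Path,
    collapse: str = "mean",
) -> ExpressionDataset:
    """Read an expression matrix TSV plus a two-group phenotype TSV.

    The matrix has a header row of sample ids and gene symbols in the
    first column.  Rows sharing a gene symbol (probe multiplicity) are
    collapsed per ``collapse``: elementwise ``mean`` (default), the row
    with the highest mean (``max-mean-row``), or the ``first`` row.
    """
    if collapse not in COLLAPSE_POLICIES:
        raise FormatError(f"unknown collapse policy: {collapse}")
    try:
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0, skip_blank_lines=True)
    except ValueError as exc:
        raise FormatError(f"cannot parse expression matrix {matrix_path}: {exc}") from exc
    mat.index = mat.index.astype(str).str.strip()
    mat.columns = mat.columns.astype(str).str.strip()
    non_numeric = mat.columns[[not pd.api.types.is_numeric_dtype(mat[c]) for c in mat.columns]]
    if len(non_numeric):
        for col in non_numeric:
            bad = mat[pd.to_numeric(mat[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"non-numeric expression value at gene {row!r}, sample {col!r}"
            )
    if mat.index.has_duplicates:
        if collapse == "mean":
            mat = mat.groupby(level=0, sort=False).mean()
        elif collapse == "max-mean-row":
            means = mat.mean(axis=1).to_numpy()
            best: dict[str, int] = {}
            for i, g in enumerate(mat.index):
                if g not in best or means[i] > means[best[g]]:
                    best[g] = i
            mat = mat.iloc[[best[g] for g in dict.fromkeys(mat.index)]]
        else:  # first
            mat = mat[~mat.index.duplicated(keep="first")]
    group_of = read_phenotype(phenotype_path)
    missing = [s for s in mat.columns if s not in group_of]
    if missing:
        raise FormatError(f"samples missing from phenotype: {missing}")
    return ExpressionDataset(mat, {s: group_of[s] for s in mat.columns})


def read_phenotype(path: str | Path) -> dict[str, str]:
    """Read ``sample<TAB>group`` lines (header optional) into a dict."""
    group_of: dict[str, str] = {}
    for lineno, raw in enumerate(_lines(path), start=1):
        parts = raw.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'sample<TAB>group'")
        sample, group = (p.strip() for p in parts)
        if lineno == 1 and group.lower() in ("group", "phenotype", "label"):
            continue  # header row
        group_of[sample] = group.lower()
    return group_of


def write_expression(data: ExpressionDataset, matrix_path: str | Path,
                     phenotype_path: str | Path | None = None) -> None:
    data.values.to_csv(matrix_path, sep="\t", float_format=FLOAT_FORMAT,
                       index_label="gene", lineterminator="\n")
    if phenotype_path is not None:
        with open(phenotype_path, "w", newline="\n") as fh:
            fh.write("sample\tgroup\n")
            for s in data.sample_ids:
                fh.write(f"{s}\t{data.group_of[s]}\n")


def read_sif(path: str | Path, source_tag: str | None = None) -> Interactome:
    """Read a SIF-style edge list: ``A <relation> B`` or ``A<TAB>B``.

    Duplicate undirected pairs collapse to one edge; self-loops are
    dropped (and counted in a log record).
    """
    inter = Interactome()
    tag = source_tag if source_tag is not None else Path(path).stem
    dropped = 0
    for lineno, raw in enumerate(_lines(path), start=1):
        parts = raw.split()
        if len(parts) == 2:
            a, b = parts
        elif len(parts) == 3:
            a, _, b = parts
        else:
            raise FormatError(f"{path}:{lineno}: malformed SIF line: {raw!r}")
        if not inter.add_edge(a, b, source=tag):
            dropped += 1
    if dropped:
        logger.info("read_sif(%s): dropped %d self-loop line(s)", path, dropped)
    return inter


def write_sif(inter: Interactome, path: str | Path, relation: str = "pp") -> None:
    with open(path, "w", newline="\n") as fh:
        for a, b in sorted(inter.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")


def read_complex_catalog(path: str | Path) -> ComplexCatalog:
    """Read ``id<TAB>name<TAB>member1;member2;...`` rows."""
    catalog = ComplexCatalog()
    for lineno, raw in enumerate(_lines(path), start=1):
        parts = raw.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 'id<TAB>name<TAB>members'")
        cid, name, members = (p.strip() for p in parts)
        if lineno == 1 and cid.lower() in ("id", "complex_id"):
            continue
        try:
            catalog.add(cid, name, members.split(";"))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return catalog


def write_complex_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("id\tname\tmembers\n")
        for cid, (name, members) in catalog.complexes.items():
            fh.write(f"{cid}\t{name}\t{';'.join(sorted(members))}\n")


def read_gmt(path: str | Path, namespace: str = "BP") -> TermAnnotation:
    """Read a standard GMT file: ``term<TAB>description<TAB>gene...``.

    The description column may carry a ``namespace|name`` pair; a bare
    description gets the default ``namespace``.
    """
    ann = TermAnnotation()
    for lineno, raw in enumerate(_lines(path), start=1):
        parts = raw.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT rows need >= 3 columns")
        term_id, desc = parts[0].strip(), parts[1].strip()
        ns, _, name = desc.partition("|")
        if not name:
            ns, name = namespace, desc
        try:
            ann.add(term_id, name, ns, parts[2:])
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return ann


def write_gmt(ann: TermAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for term_id, (name, ns, genes) in ann.terms.items():
            fh.write("\t".join([term_id, f"{ns}|{name}", *sorted(genes)]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read one gene symbol per line (blank lines ignored)."""
    return set(_lines(path))


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def write_graphml(network, path: str | Path, classification=None,
                  coexpression=None) -> None:
    """Export a QQPPI network to GraphML with analysis attributes.

    Node attributes: ``role`` (hub/bottleneck/other), ``degree`` and
    ``betweenness`` when a :class:`~qqppi.topology.NodeClassification`
    is given.  Edge attributes ``r_control``/``r_disease`` when
    co-expression records are given.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(network.nodes))
    for (a, b), tags in sorted(network.edges.items()):
        g.add_edge(a, b, sources=";".join(sorted(tags)))
    if classification is not None:
        for node in g.nodes:
            deg, btw, _ = classification.evidence.get(node, (0, 0.0, 0))
            if node in classification.hubs:
                role = "hub"
            elif node in classification.bottlenecks:
                role = "bottleneck"
            else:
                role = "other"
            g.nodes[node].update(role=role, degree=int(deg), betweenness=float(btw))
    if coexpression is not None:
        for rec in coexpression:
            if g.has_edge(rec.node1, rec.node2):
                g.edges[rec.node1, rec.node2].update(
                    r_control=float(rec.r_control), r_disease=float(rec.r_disease)
                )
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def read_neuro_table(path: str | Path) -> dict[str, list[str]]:
    """Read a curated gene -> neurotransmitter-association table.

    Format: ``gene<TAB>label1;label2`` (header optional); labels name
    transmitter systems (dopaminergic, cholinergic, ...).
    """
    table: dict[str, list[str]] = {}
    for lineno, raw in enumerate(_lines(path), start=1):
        parts = raw.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'gene<TAB>labels'")
        gene, labels = parts[0].strip(), parts[1].strip()
        if lineno == 1 and gene.lower() == "gene":
            continue
        table[gene] = [x.strip() for x in labels.split(";") if x.strip()]
    return table


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _lines(path: str | Path):
    """Yield stripped, non-blank lines, tolerant of CRLF."""
    with open(path, "r", newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n").rstrip()
            if line:
                yield line
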