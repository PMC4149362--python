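"""End-to-end orchestration of the marker-discovery pipeline.

Stage order: DE selection (two parallel branches, t-test and SAM) ->
over-representation filter -> QQPPI construction from one or more
interactomes, merged -> topology and hub/bottleneck classification ->
3/4-clique enumeration and core module -> complex matching ->
per-edge co-expression -> novel-marker identification combining the
branches.  Every stage output is written to the run directory along
with a manifest recording inputs, parameters and the seed, so a rerun
with the same config is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io as qio
from .cliques import core_functional_module, enumerate_k_cliques
from .coexpression import edge_coexpression
from .complexes import clique_proteins, match_complexes
from .diffexpr import sam_analysis, select_de_sam, select_de_ttest, t_test_dataset
from .enrichment import over_representation, select_genes_in_significant_terms
from .errors import ParameterError, QQPPIError
from .markers import annotate_markers, novel_markers
from .network import build_qqppi, merge_networks, network_summary
from .topology import classify_nodes, compute_topology

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one full run."""

    expression: str
    phenotype: str
    interactomes: list[str]
    annotation: str
    known_genes: str
    complex_catalog: str | None = None
    neuro_table: str | None = None
    out_dir: str = "qqppi_run"
    alpha_ttest: float = 0.001
    ttest_variant: str = "welch"
    fdr_target: float = 0.0019
    n_permutations: int = 200
    enrichment_alpha: float = 0.05
    namespace: str = "BP"
    sd_mode: str = "sample"
    merge_mode: str = "union"
    maximal_only: bool = False
    min_query: dict[str, int] = field(default_factory=lambda: {"ttest": 5, "sam": 4})
    collapse: str = "mean"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        stray = set(raw) - known
        if stray:
            raise ParameterError(f"unknown config keys: {sorted(stray)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        paths = [self.expression, self.phenotype, self.annotation, self.known_genes,
                 *self.interactomes]
        if self.complex_catalog:
            paths.append(self.complex_catalog)
        if self.neuro_table:
            paths.append(self.neuro_table)
        for p in paths:
            if not Path(p).exists():
                raise ParameterError(f"input path does not exist: {p}")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns a summary dict (also written as JSON).

    Two branches (t-test- and SAM-derived query sets) produce two
    networks whose classifications are combined only at the marker
    stage.  Any stage failure writes a FAILED marker naming the stage
    and re-raises.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        data = qio.read_expression(config.expression, config.phenotype,
                                   collapse=config.collapse)
        interactomes = [qio.read_sif(p) for p in config.interactomes]
        annotation = qio.read_gmt(config.annotation, namespace=config.namespace)
        known = qio.read_gene_list(config.known_genes)
        catalog = (qio.read_complex_catalog(config.complex_catalog)
                   if config.complex_catalog else None)
        neuro = qio.read_neuro_table(config.neuro_table) if config.neuro_table else None
        background = set(data.gene_ids)

        stage = "differential_expression"
        records = t_test_dataset(data, variant=config.ttest_variant)
        de_ttest = select_de_ttest(records, config.alpha_ttest)
        sam = sam_analysis(data, n_permutations=config.n_permutations,
                           seed=config.seed, fdr_target=config.fdr_target)
        de_sam, sam_dirs = select_de_sam(sam, config.fdr_target)
        _write_de_tables(out, records, sam, sam_dirs)

        summary: dict = {"seed": config.seed, "stages": {}}
        summary["stages"]["differential_expression"] = {
            "de_ttest": len(de_ttest), "de_sam": len(de_sam),
            "sam_up": sum(1 for v in sam_dirs.values() if v == "UR"),
            "sam_down": sum(1 for v in sam_dirs.values() if v == "DR"),
        }

        classifications = {}
        cores, matches_all, coexpr_all = {}, {}, {}
        for branch, de_set in (("ttest", de_ttest), ("sam", de_sam)):
            stage = f"enrichment[{branch}]"
            enr = over_representation(de_set, background, annotation)
            query = select_genes_in_significant_terms(
                enr, annotation, de_set, alpha=config.enrichment_alpha,
                namespace=config.namespace)
            qio.write_gene_list(query, out / f"query_{branch}.txt")
            if not query:
                logger.warning("branch %s: empty query set after enrichment", branch)
                summary["stages"][f"network_{branch}"] = {"nodes": 0, "edges": 0}
                continue

            stage = f"network[{branch}]"
            nets = [build_qqppi(query, inter) for inter in interactomes]
            net = nets[0]
            for other in nets[1:]:
                net = merge_networks(net, other, mode=config.merge_mode)

            stage = f"topology[{branch}]"
            topo = compute_topology(net)
            stats = network_summary(net, topo)
            if net.n_nodes >= 2:
                cls = classify_nodes(net, topo, sd_mode=config.sd_mode)
                classifications[branch] = cls
            else:
                cls = None

            stage = f"cliques[{branch}]"
            c3 = enumerate_k_cliques(net, 3, maximal_only=config.maximal_only)
            c4 = enumerate_k_cliques(net, 4, maximal_only=config.maximal_only)
            core = core_functional_module(c3, c4, net)
            cores[branch] = core

            stage = f"complexes[{branch}]"
            if catalog is not None:
                matches_all[branch] = match_complexes(
                    clique_proteins(c3, c4), catalog,
                    config.min_query.get(branch, 4))

            stage = f"coexpression[{branch}]"
            coexpr = edge_coexpression(net.edges, data)
            coexpr_all[branch] = coexpr
            _write_coexpr_table(out / f"coexpression_{branch}.tsv", coexpr)
            qio.write_graphml(net, out / f"network_{branch}.graphml",
                              classification=cls, coexpression=coexpr)

            summary["stages"][f"network_{branch}"] = {
                "query": len(query), "nodes": stats.n_nodes, "edges": stats.n_edges,
                "avg_degree": round(stats.avg_degree, 1),
                "hubs": len(cls.hubs) if cls else 0,
                "bottlenecks": len(cls.bottlenecks) if cls else 0,
                "cliques3": len(c3), "cliques4": len(c4),
                "core_nodes": len(core.nodes),
            }

        stage = "markers"
        if classifications:
            marker_map, multiplicity = novel_markers(classifications, known)
            core_union = _union_cores(list(cores.values()))
            matches_flat = [m for ms in matches_all.values() for m in ms]
            report = annotate_markers(marker_map, core_union, matches_flat, neuro)
            _write_marker_table(out / "markers.tsv", report)
            summary["stages"]["markers"] = {
                "multiplicity_total": multiplicity,
                "unique": len(report.markers),
                "core_module_markers": len(report.core_module_markers),
                "neuro_markers": len(report.neuro_markers),
            }
        else:
            summary["stages"]["markers"] = {"multiplicity_total": 0, "unique": 0}

        manifest = {"config": asdict(config), "summary": summary}
        qio.write_json(manifest, out / "manifest.json")
        return summary
    except QQPPIError:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.error("pipeline failed at stage %s", stage)
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise


def _union_cores(cores):
    from .cliques import CoreModule

    if not cores:
        return None
    out = CoreModule()
    for core in cores:
        out.nodes |= core.nodes
        out.edges |= core.edges
        for v, c in core.occurrence_3.items():
            out.occurrence_3[v] = out.occurrence_3.get(v, 0) + c
        for v, c in core.occurrence_4.items():
            out.occurrence_4[v] = out.occurrence_4.get(v, 0) + c
    return out


def _write_de_tables(out: Path, records, sam, sam_dirs) -> None:
    with open(out / "de_ttest.tsv", "w", newline="\n") as fh:
        fh.write("gene\tt\tp\tdf\n")
        for r in sorted(records, key=lambda r: r.gene):
            if r.undefined:
                continue
            fh.write(f"{r.gene}\t{r.t:.6f}\t{r.p:.6g}\t{r.df:.2f}\n")
    with open(out / "de_sam.tsv", "w", newline="\n") as fh:
        fh.write("gene\td\ts\tdirection\n")
        for gene, d, s in sorted(zip(sam.genes, sam.d, sam.s)):
            fh.write(f"{gene}\t{d:.6f}\t{s:.6f}\t{sam_dirs.get(gene, '')}\n")


def _write_coexpr_table(path: Path, records) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("node1\tnode2\tr_control\tr_disease\tchange\tpct_max_change\n")
        for r in records:
            fh.write(
                f"{r.node1}\t{r.node2}\t{r.r_control:.6f}\t{r.r_disease:.6f}"
                f"\t{r.change:.6f}\t{r.pct_max_change:.6f}\n"
            )


def _write_marker_table(path: Path, report) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene\troles\tin_core_module\tocc3\tocc4\tcomplexes\tneurotransmitters\n")
        for gene in sorted(report.markers):
            r = report.markers[gene]
            roles = ";".join(f"{n}:{role}" for n, role in sorted(r.roles))
            fh.write(
                f"{gene}\t{roles}\t{int(r.in_core_module)}\t{r.occurrence_3}"
                f"\t{r.occurrence_4}\t{';'.join(r.complexes)}"
                f"\t{';'.join(r.neurotransmitters)}\n"
            )
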