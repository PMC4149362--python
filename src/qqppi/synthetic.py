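"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the study conditions of a small two-group brain
microarray comparison: a log2-scale expression matrix with 15 control
and 24 disease samples and a planted fraction of up/down-regulated
genes; an undirected interactome (scale-free growth, configuration
background, or a planted model that overlays cliques and hubs on an
Erdos-Renyi background); a protein-complex catalog; and a term ->
gene-set annotation with terms enriched for the planted DE genes.
Every generator is a pure function of (spec, seed): the same spec and
seed reproduce byte-identical outputs, and a ground-truth sidecar
records what was planted so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ComplexCatalog, ExpressionDataset, Interactome, TermAnnotation, matrix_from_arrays
from .errors import ParameterError

INTERACTOME_MODELS = ("scale_free", "configuration", "planted")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study bundle.

    Defaults describe the emulated study: 2000 genes measured on 15
    control and 24 disease samples (log2 scale), 10% of genes
    differentially expressed with a mean log2 shift of 2 and
    within-group noise sd 0.5, of which 20% are up-regulated; a
    500-protein interactome with ~2 edges per node.
    """

    n_genes: int = 2000
    n_control: int = 15
    n_disease: int = 24
    de_fraction: float = 0.1
    up_fraction: float = 0.2
    de_protein_fraction: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 0.5
    interactome_model: str = "scale_free"
    n_proteins: int = 500
    edges_per_node: int = 2
    n_planted_cliques: int = 0
    planted_clique_sizes: list[int] = field(default_factory=lambda: [3, 4])
    n_planted_hubs: int = 0
    n_complexes: int = 20
    complex_size_range: tuple[int, int] = (4, 10)
    n_terms: int = 50
    n_enriched_terms: int = 5
    probes_per_gene: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_control", "n_disease", "n_proteins",
                     "edges_per_node", "n_planted_cliques", "n_planted_hubs",
                     "n_complexes", "n_terms", "n_enriched_terms", "probes_per_gene"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("de_fraction", "up_fraction", "de_protein_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.n_control < 3 or self.n_disease < 3:
            raise ParameterError("n_control and n_disease must be >= 3")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.interactome_model not in INTERACTOME_MODELS:
            raise ParameterError(
                f"interactome_model must be one of {INTERACTOME_MODELS}"
            )
        if any(s not in (3, 4) for s in self.planted_clique_sizes):
            raise ParameterError("planted_clique_sizes entries must be 3 or 4")
        if self.planted_clique_sizes and self.n_planted_cliques * max(
            self.planted_clique_sizes
        ) > self.n_proteins:
            raise ParameterError(
                "n_planted_cliques * max(planted_clique_sizes) exceeds n_proteins"
            )
        lo, hi = self.complex_size_range
        if not (2 <= lo <= hi):
            raise ParameterError("complex_size_range must satisfy 2 <= min <= max")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What the generators planted, for recovery tests."""

    de_genes_up: set[str] = field(default_factory=set)
    de_genes_down: set[str] = field(default_factory=set)
    planted_cliques: set[tuple[str, ...]] = field(default_factory=set)
    planted_hub_genes: set[str] = field(default_factory=set)

    @property
    def de_genes(self) -> set[str]:
        return self.de_genes_up | self.de_genes_down


def gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Planted-DE two-group log2 expression matrix.

    Baseline per-gene means are drawn once and shared by both groups;
    DE genes are shifted by +/- effect_size in the disease group;
    every cell receives independent Normal(0, noise_sd) noise.  With
    ``probes_per_gene`` > 1 each gene contributes several probe rows
    (same mean, independent noise) to exercise probe collapsing.

    A ``de_protein_fraction`` share of the DE genes is drawn from the
    interactome's symbol range (the first ``n_proteins`` genes), since
    disease-relevant DE genes concentrate in the well-studied part of
    the interactome; the rest are uniform over the remaining genes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = gene_symbols(spec.n_genes)
    n_de = int(round(spec.de_fraction * spec.n_genes))
    n_prot = min(spec.n_proteins, spec.n_genes)
    n_in = min(int(round(spec.de_protein_fraction * n_de)), n_prot)
    in_prot = rng.choice(n_prot, size=n_in, replace=False)
    n_out = min(n_de - n_in, spec.n_genes - n_prot)
    out_prot = (n_prot + rng.choice(spec.n_genes - n_prot, size=n_out,
                                    replace=False)
                if n_out > 0 else np.array([], dtype=int))
    de_idx = np.concatenate([in_prot, out_prot]).astype(int)
    rng.shuffle(de_idx)
    n_up = int(round(spec.up_fraction * n_de))
    up_idx = set(de_idx[:n_up].tolist())
    down_idx = set(de_idx[n_up:].tolist())

    base = rng.normal(8.0, 2.0, size=spec.n_genes)
    shift = np.zeros(spec.n_genes)
    for i in up_idx:
        shift[i] = spec.effect_size
    for i in down_idx:
        shift[i] = -spec.effect_size

    n_samples = spec.n_control + spec.n_disease
    rows = []
    row_ids = []
    for rep in range(spec.probes_per_gene):
        mean = np.tile(base[:, None], (1, n_samples))
        mean[:, spec.n_control:] += shift[:, None]
        rows.append(mean + rng.normal(0.0, spec.noise_sd, size=mean.shape))
        row_ids.extend(
            genes if spec.probes_per_gene == 1 else [f"{g}" for g in genes]
        )
    values = np.vstack(rows)
    samples = [f"C{i:02d}" for i in range(spec.n_control)] + [
        f"D{i:02d}" for i in range(spec.n_disease)
    ]
    frame = pd.DataFrame(values, index=row_ids, columns=samples)
    if spec.probes_per_gene > 1:
        # duplicate symbols are intentional here; collapse before wrapping
        frame = frame.groupby(level=0, sort=False).mean()
    group_of = {s: ("control" if s.startswith("C") else "disease") for s in samples}
    truth = GroundTruth(
        de_genes_up={genes[i] for i in up_idx},
        de_genes_down={genes[i] for i in down_idx},
    )
    return ExpressionDataset(frame, group_of), truth


def generate_probe_matrix(spec: SyntheticSpec):
    """Uncollapsed probe-level matrix (gene symbols repeated) as a DataFrame.

    Used to exercise the probe-collapse policy of the expression
    reader; probes of one gene share the mean but not the noise.
    """
    spec.validate()
    if spec.probes_per_gene < 2:
        raise ParameterError("probes_per_gene must be >= 2 for a probe matrix")
    rng = np.random.default_rng(spec.seed)
    genes = gene_symbols(spec.n_genes)
    base = rng.normal(8.0, 2.0, size=spec.n_genes)
    n_samples = spec.n_control + spec.n_disease
    samples = [f"C{i:02d}" for i in range(spec.n_control)] + [
        f"D{i:02d}" for i in range(spec.n_disease)
    ]
    rows, idx = [], []
    for i, g in enumerate(genes):
        for _ in range(spec.probes_per_gene):
            rows.append(base[i] + rng.normal(0.0, spec.noise_sd, size=n_samples))
            idx.append(g)
    return pd.DataFrame(np.vstack(rows), index=idx, columns=samples)


def generate_correlated_pair(
    n_control: int,
    n_disease: int,
    r_control: float,
    r_disease: float,
    seed: int = 0,
    names: tuple[str, str] = ("GA", "GB"),
) -> ExpressionDataset:
    """Two-gene dataset with a planted co-expression break.

    The pair is drawn from a bivariate normal with correlation
    ``r_control`` over control samples and ``r_disease`` over disease
    samples (a co-expression change of r_control - r_disease).
    """
    rng = np.random.default_rng(seed)
    def draw(n, r):
        cov = np.array([[1.0, r], [r, 1.0]])
        return rng.multivariate_normal([8.0, 8.0], cov, size=n).T
    ctrl = draw(n_control, r_control)
    dis = draw(n_disease, r_disease)
    samples = [f"C{i:02d}" for i in range(n_control)] + [f"D{i:02d}" for i in range(n_disease)]
    values = np.hstack([ctrl, dis])
    frame = matrix_from_arrays(values, list(names), samples)
    group_of = {s: ("control" if s.startswith("C") else "disease") for s in samples}
    return ExpressionDataset(frame, group_of)


def generate_interactome(
    spec: SyntheticSpec, expression_truth: GroundTruth | None = None
) -> tuple[Interactome, GroundTruth]:
    """Synthetic undirected interactome over the first n_proteins genes.

    ``scale_free`` grows by preferential attachment (heavy-tailed
    degrees); ``configuration`` shuffles a power-law degree sequence;
    ``planted`` overlays fully connected cliques and high-degree hubs
    on an Erdos-Renyi background so that topology recovery can be
    scored against ground truth.  When the expression ground truth is
    supplied, planted cliques and hubs are placed preferentially on DE
    genes (disease-relevant proteins form the tightly connected core),
    so the planted structure survives the DE/enrichment filter in
    end-to-end runs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    proteins = gene_symbols(spec.n_genes)[: spec.n_proteins]
    if spec.n_proteins < 2:
        raise ParameterError("n_proteins must be >= 2")
    truth = GroundTruth()
    inter = Interactome()
    tag = "synthetic"

    if spec.interactome_model == "scale_free":
        edges = _preferential_attachment(spec.n_proteins, spec.edges_per_node, rng)
    elif spec.interactome_model == "configuration":
        edges = _configuration_model(spec.n_proteins, spec.edges_per_node, rng)
    else:
        edges = _erdos_renyi(spec.n_proteins, spec.edges_per_node, rng)

    adj: dict[int, set[int]] = {i: set() for i in range(spec.n_proteins)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    if spec.interactome_model == "planted":
        pool = rng.permutation(spec.n_proteins).tolist()
        if expression_truth is not None:
            de = expression_truth.de_genes
            # pop() draws from the end: keep DE-gene proteins there
            pool = ([i for i in pool if proteins[i] not in de]
                    + [i for i in pool if proteins[i] in de])
        for c in range(spec.n_planted_cliques):
            size = spec.planted_clique_sizes[c % len(spec.planted_clique_sizes)]
            members = [pool.pop() for _ in range(size)]
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    adj[a].add(b)
                    adj[b].add(a)
            truth.planted_cliques.add(tuple(sorted(proteins[i] for i in members)))
        hub_ids = [pool.pop() for _ in range(spec.n_planted_hubs)]
        _plant_hubs(adj, hub_ids, rng)
        truth.planted_hub_genes = {proteins[i] for i in hub_ids}

    for a in adj:
        for b in adj[a]:
            if a < b:
                inter.add_edge(proteins[a], proteins[b], source=tag)
    return inter, truth


def _preferential_attachment(n: int, m: int, rng: np.random.Generator):
    """Barabasi-Albert growth: heavy-tailed degree distribution."""
    m = max(1, min(m, n - 1))
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    return {(min(a, b), max(a, b)) for a, b in g.edges}


def _configuration_model(n: int, m: int, rng: np.random.Generator):
    """Power-law degree sequence, stub-matched; self/multi edges dropped."""
    degrees = np.clip(rng.zipf(2.5, size=n), 1, n - 1)
    target_total = 2 * m * n
    if degrees.sum() > target_total:
        degrees = np.maximum(1, (degrees * target_total / degrees.sum()).astype(int))
    if degrees.sum() % 2:
        degrees[0] += 1
    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    return {(min(a, b), max(a, b)) for a, b in nx.Graph(g).edges if a != b}


def _erdos_renyi(n: int, m: int, rng: np.random.Generator):
    p = min(1.0, m / max(1, n - 1))
    g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return {(min(a, b), max(a, b)) for a, b in g.edges}


def _plant_hubs(adj: dict[int, set[int]], hub_ids: list[int], rng: np.random.Generator) -> None:
    """Raise hub degrees until each reaches round(mean + 2 sd) of the
    final degree distribution (iterated because planting moves the
    distribution)."""
    n = len(adj)
    for _ in range(20):
        degrees = np.array([len(adj[i]) for i in range(n)], dtype=float)
        cut = int(round(degrees.mean() + 2.0 * degrees.std(ddof=1)))
        deficient = [h for h in hub_ids if len(adj[h]) < cut]
        if not deficient:
            return
        for h in deficient:
            need = cut - len(adj[h]) + 2  # small margin against drift
            candidates = [v for v in range(n) if v != h and v not in adj[h]]
            rng.shuffle(candidates)
            for v in candidates[:need]:
                adj[h].add(v)
                adj[v].add(h)


def write_bundle(spec: SyntheticSpec, out_dir) -> GroundTruth:
    """Generate and write a complete input bundle for one pipeline run.

    Produces expression/phenotype TSVs, a SIF interactome (planted
    structures biased onto DE genes), a complex catalog, a GMT
    annotation, an empty known-gene list and a ground-truth JSON
    sidecar; returns the combined ground truth.
    """
    from pathlib import Path

    from . import io as qio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data, truth = generate_expression(spec)
    inter, itruth = generate_interactome(spec, expression_truth=truth)
    truth.planted_cliques = itruth.planted_cliques
    truth.planted_hub_genes = itruth.planted_hub_genes
    catalog = generate_complex_catalog(inter, spec, truth)
    ann = generate_term_annotation(set(data.gene_ids), spec, truth)
    qio.write_expression(data, out / "expression.tsv", out / "phenotype.tsv")
    qio.write_sif(inter, out / "interactome.sif")
    qio.write_complex_catalog(catalog, out / "complexes.tsv")
    qio.write_gmt(ann, out / "annotation.gmt")
    (out / "known.txt").write_text("")
    qio.write_json(
        {
            "de_genes_up": truth.de_genes_up,
            "de_genes_down": truth.de_genes_down,
            "planted_cliques": sorted(truth.planted_cliques),
            "planted_hub_genes": truth.planted_hub_genes,
            "spec": spec.to_dict(),
        },
        out / "ground_truth.json",
    )
    return truth


def generate_complex_catalog(
    interactome: Interactome, spec: SyntheticSpec, truth: GroundTruth | None = None
) -> ComplexCatalog:
    """Random complexes over interactome nodes.

    Sizes are uniform in ``complex_size_range``; when planted cliques
    exist, the first complex is built around one of them so at least
    one catalog entry contains a planted clique.
    """
    spec.validate()
    nodes = sorted(interactome.nodes)
    if not nodes:
        raise ParameterError("interactome is empty")
    lo, hi = spec.complex_size_range
    if lo > len(nodes):
        raise ParameterError("complex_size_range min exceeds interactome size")
    rng = np.random.default_rng(spec.seed + 2)
    catalog = ComplexCatalog()
    planted = sorted(truth.planted_cliques) if truth and truth.planted_cliques else []
    for c in range(spec.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        if c == 0 and planted:
            seedset = list(planted[0])
            extra = [v for v in nodes if v not in seedset]
            rng.shuffle(extra)
            members = seedset + extra[: max(0, size - len(seedset))]
        else:
            members = rng.choice(nodes, size=min(size, len(nodes)), replace=False).tolist()
        catalog.add(f"CPX{c:04d}", f"synthetic complex {c}", members)
    return catalog


def generate_term_annotation(
    genes: set[str], spec: SyntheticSpec, truth: GroundTruth
) -> TermAnnotation:
    """Term annotation with a configurable number of DE-enriched terms.

    Enriched terms draw ~80% of their members from the planted DE
    genes; the remaining terms are uniform over all genes, so the
    over-representation filter has genuine signal to detect.
    """
    spec.validate()
    if not genes:
        raise ParameterError("gene set is empty")
    rng = np.random.default_rng(spec.seed + 3)
    universe = sorted(genes)
    de = sorted(truth.de_genes & genes)
    ann = TermAnnotation()
    term_size = max(5, min(50, len(universe) // 10))
    for t in range(spec.n_terms):
        enriched = t < spec.n_enriched_terms and de
        if enriched:
            n_de = min(len(de), int(round(0.8 * term_size)))
            members = rng.choice(de, size=n_de, replace=False).tolist()
            rest = [g for g in universe if g not in set(members)]
            rng.shuffle(rest)
            members += rest[: term_size - n_de]
        else:
            members = rng.choice(universe, size=min(term_size, len(universe)),
                                 replace=False).tolist()
        kind = "enriched" if enriched else "background"
        ann.add(f"T{t:04d}", f"synthetic {kind} process {t}", "BP", members)
    return ann
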