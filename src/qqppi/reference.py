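"""Loaders for the curated reference tables shipped with the package.

These are small published tables from a Parkinson's-disease
substantia-nigra QQPPI analysis, consumed as inputs: the hub and
bottleneck gene lists of two networks (one built from a t-test DE set,
one from a SAM DE set), the curated list of genes already reported as
disease-associated, per-network global statistics and hub-cutoff
moments, intra-complex co-expression values, complex-catalog rows and
a gene -> neurotransmitter association table.  They drive the
arithmetic cross-checks in the test suite and the acceptance script.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as qio
from .datatypes import ComplexCatalog


def _path(name: str):
    return resources.files("qqppi") / "reference_data" / name


def hub_list(network: str) -> set[str]:
    """Hub genes of reference network ``"a"`` (t-test) or ``"b"`` (SAM)."""
    return qio.read_gene_list(_path(f"network_{network}_hubs.txt"))


def bottleneck_list(network: str) -> set[str]:
    return qio.read_gene_list(_path(f"network_{network}_bottlenecks.txt"))


def known_disease_genes() -> set[str]:
    """Genes already reported as disease-associated (curated)."""
    return qio.read_gene_list(_path("known_disease_genes.txt"))


def complex_catalog(network: str) -> ComplexCatalog:
    return qio.read_complex_catalog(_path(f"complex_catalog_{network}.tsv"))


def coexpression_pairs(network: str) -> pd.DataFrame:
    """Published per-pair control/disease correlations with the printed change."""
    return pd.read_csv(_path(f"coexpression_pairs_{network}.tsv"), sep="\t")


def global_stats() -> pd.DataFrame:
    return pd.read_csv(_path("global_stats.tsv"), sep="\t")


def hub_cutoffs() -> pd.DataFrame:
    return pd.read_csv(_path("hub_cutoffs.tsv"), sep="\t")


def neurotransmitter_associations() -> dict[str, list[str]]:
    return qio.read_neuro_table(_path("neurotransmitter_associations.tsv"))
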