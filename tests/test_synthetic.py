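"""Generator determinism, null calibration and planted-structure recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from qqppi import synthetic
from qqppi.diffexpr import select_de_ttest, t_test_dataset
from qqppi.errors import ParameterError
from qqppi.synthetic import (
    SyntheticSpec,
    generate_complex_catalog,
    generate_expression,
    generate_interactome,
    generate_term_annotation,
)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "field,value",
        [("n_genes", -1), ("de_fraction", 1.5), ("n_control", 2),
         ("noise_sd", -0.1), ("interactome_model", "smallworld")],
    )
    def test_invalid_field_named_in_error(self, field, value):
        spec = SyntheticSpec(**{field: value})
        with pytest.raises(ParameterError, match=field.split("_")[0]):
            spec.validate()

    def test_planted_cliques_must_fit(self):
        spec = SyntheticSpec(n_proteins=10, n_planted_cliques=4,
                             planted_clique_sizes=[4], interactome_model="planted")
        with pytest.raises(ParameterError):
            spec.validate()


class TestExpression:
    def test_null_model_has_no_de_genes(self):
        _, truth = generate_expression(SyntheticSpec(n_genes=50, de_fraction=0.0,
                                                     seed=0))
        assert truth.de_genes_up == truth.de_genes_down == set()

    def test_determinism(self):
        spec = SyntheticSpec(n_genes=100, seed=42)
        d1, t1 = generate_expression(spec)
        d2, t2 = generate_expression(SyntheticSpec(n_genes=100, seed=42))
        pd.testing.assert_frame_equal(d1.values, d2.values)
        assert t1.de_genes_up == t2.de_genes_up

    def test_shape_and_group_sizes(self):
        spec = SyntheticSpec(n_genes=80, n_control=5, n_disease=7, seed=1)
        data, _ = generate_expression(spec)
        assert data.values.shape == (80, 12)
        assert len(data.samples_in_group("control")) == 5
        assert len(data.samples_in_group("disease")) == 7

    def test_de_shift_direction(self):
        spec = SyntheticSpec(n_genes=500, effect_size=3.0, noise_sd=0.2, seed=6)
        data, truth = generate_expression(spec)
        ctrl = data.group_matrix("control").mean(axis=1)
        dis = data.group_matrix("disease").mean(axis=1)
        diff = dis - ctrl
        assert all(diff[g] > 2.0 for g in truth.de_genes_up)
        assert all(diff[g] < -2.0 for g in truth.de_genes_down)

    def test_ttest_recovers_planted_genes(self):
        """At alpha=0.001 the t stage recovers >= 90% of planted genes with
        a false-positive fraction <= 0.005 among nulls (10 seeds)."""
        tp = fp = n_de = n_null = 0
        for seed in range(10):
            spec = SyntheticSpec(n_genes=2000, de_fraction=0.1, effect_size=2.0,
                                 noise_sd=0.5, seed=seed)
            data, truth = generate_expression(spec)
            selected = select_de_ttest(t_test_dataset(data), 0.001)
            tp += len(selected & truth.de_genes)
            fp += len(selected - truth.de_genes)
            n_de += len(truth.de_genes)
            n_null += spec.n_genes - len(truth.de_genes)
        assert tp / n_de >= 0.9
        assert fp / n_null <= 0.005

    def test_null_type_i_calibration(self):
        """Fraction of null genes with p < alpha stays within
        3*sqrt(alpha(1-alpha)/n) of alpha averaged over 20 seeds."""
        alpha, n_genes = 0.001, 2000
        fractions = []
        for seed in range(20):
            spec = SyntheticSpec(n_genes=n_genes, de_fraction=0.0, seed=seed)
            data, _ = generate_expression(spec)
            fractions.append(
                len(select_de_ttest(t_test_dataset(data), alpha)) / n_genes)
        band = 3 * math.sqrt(alpha * (1 - alpha) / n_genes)
        assert abs(np.mean(fractions) - alpha) <= band


class TestInteractome:
    def test_planted_k4_induces_six_edges(self):
        spec = SyntheticSpec(n_proteins=50, interactome_model="planted",
                             n_planted_cliques=1, planted_clique_sizes=[4], seed=3)
        inter, truth = generate_interactome(spec)
        (clique,) = truth.planted_cliques
        members = set(clique)
        induced = {e for e in inter.edge_set if set(e) <= members}
        assert len(induced) == 6

    def test_scale_free_heavy_tail(self):
        """Preferential attachment yields max degree >= 10x median."""
        for seed in range(10):
            spec = SyntheticSpec(n_proteins=500, edges_per_node=2, seed=seed)
            inter, _ = generate_interactome(spec)
            from collections import Counter

            deg = Counter()
            for a, b in inter.edge_set:
                deg[a] += 1
                deg[b] += 1
            counts = sorted(deg.values())
            median = counts[len(counts) // 2]
            assert max(counts) >= 10 * median

    def test_determinism(self):
        spec = SyntheticSpec(n_proteins=100, seed=9)
        i1, _ = generate_interactome(spec)
        i2, _ = generate_interactome(SyntheticSpec(n_proteins=100, seed=9))
        assert i1.edge_set == i2.edge_set

    def test_planted_hub_degrees_reach_cutoff(self):
        spec = SyntheticSpec(n_proteins=200, interactome_model="planted",
                             n_planted_hubs=3, seed=5)
        inter, truth = generate_interactome(spec)
        from collections import Counter

        deg = Counter()
        for a, b in inter.edge_set:
            deg[a] += 1
            deg[b] += 1
        degrees = np.array([deg.get(p, 0) for p in sorted(inter.nodes)])
        cutoff = round(degrees.mean() + 2 * degrees.std(ddof=1))
        for hub in truth.planted_hub_genes:
            assert deg[hub] >= cutoff


class TestCatalogAndAnnotation:
    def bundle(self, seed=7):
        spec = SyntheticSpec(n_proteins=60, interactome_model="planted",
                             n_planted_cliques=1, planted_clique_sizes=[4],
                             n_complexes=5, seed=seed)
        inter, truth = generate_interactome(spec)
        return spec, inter, truth

    def test_zero_complexes(self):
        spec, inter, truth = self.bundle()
        spec.n_complexes = 0
        assert len(generate_complex_catalog(inter, spec, truth)) == 0

    def test_planted_clique_contained_in_some_complex(self):
        spec, inter, truth = self.bundle()
        catalog = generate_complex_catalog(inter, spec, truth)
        (clique,) = truth.planted_cliques
        assert any(set(clique) <= members
                   for _, members in catalog.complexes.values())

    def test_catalog_determinism(self):
        spec, inter, truth = self.bundle()
        c1 = generate_complex_catalog(inter, spec, truth)
        c2 = generate_complex_catalog(inter, spec, truth)
        assert c1.complexes == c2.complexes

    def test_single_term_covering_all_genes_passes_everything(self):
        from qqppi.enrichment import (over_representation,
                                      select_genes_in_significant_terms)

        from qqppi.datatypes import TermAnnotation

        spec = SyntheticSpec(n_genes=40, seed=2, n_terms=1, n_enriched_terms=0)
        data, truth = generate_expression(spec)
        genes = set(data.gene_ids)
        ann = TermAnnotation()
        ann.add("T0", "everything", "BP", genes)
        query = set(list(genes)[:10])
        records = over_representation(query, genes, ann)
        out = select_genes_in_significant_terms(records, ann, query, alpha=1.0)
        assert out == query

    def test_annotation_determinism(self):
        spec = SyntheticSpec(n_genes=100, seed=4)
        data, truth = generate_expression(spec)
        genes = set(data.gene_ids)
        a1 = generate_term_annotation(genes, spec, truth)
        a2 = generate_term_annotation(genes, spec, truth)
        assert a1.terms == a2.terms
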