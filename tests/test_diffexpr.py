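"""Two-sample t statistics and SAM against brute-force oracles and
planted ground truth."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from qqppi import synthetic
from qqppi.datatypes import ExpressionDataset
from qqppi.diffexpr import (
    GroupSummary,
    group_summaries,
    sam_analysis,
    select_de_sam,
    select_de_ttest,
    t_test,
    t_test_dataset,
)
from qqppi.errors import PreconditionError


def dataset_from_arrays(ctrl: np.ndarray, dis: np.ndarray) -> ExpressionDataset:
    ctrl, dis = np.atleast_2d(ctrl), np.atleast_2d(dis)
    genes = [f"G{i}" for i in range(ctrl.shape[0])]
    cs = [f"c{i}" for i in range(ctrl.shape[1])]
    ds = [f"d{i}" for i in range(dis.shape[1])]
    frame = pd.DataFrame(np.hstack([ctrl, dis]), index=genes, columns=cs + ds)
    groups = {**{s: "control" for s in cs}, **{s: "disease" for s in ds}}
    return ExpressionDataset(frame, groups)


class TestGroupSummaries:
    def test_hand_arithmetic(self):
        data = dataset_from_arrays(np.array([[1.0, 2.0, 3.0]]),
                                   np.array([[5.0, 5.0, 5.0]]))
        ctrl, dis = group_summaries(data)["G0"]
        assert ctrl.mean == 2.0 and ctrl.sd == 1.0 and ctrl.n == 3
        assert dis.mean == 5.0 and dis.sd == 0.0

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        ctrl, dis = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        out = group_summaries(dataset_from_arrays(ctrl, dis))
        for i, gene in enumerate(sorted(out, key=lambda g: int(g[1:]))):
            for summ, row in zip(out[gene], (ctrl[i], dis[i])):
                mean = sum(row) / len(row)
                sd = math.sqrt(sum((v - mean) ** 2 for v in row) / (len(row) - 1))
                assert summ.mean == pytest.approx(mean, abs=1e-12)
                assert summ.sd == pytest.approx(sd, abs=1e-12)

    def test_rejects_single_sample_group(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G0"],
                              columns=["c0", "c1", "d0"])
        data = ExpressionDataset(values, {"c0": "control", "c1": "control",
                                          "d0": "disease"})
        with pytest.raises(PreconditionError):
            group_summaries(data)


class TestTTest:
    def test_equal_means_gives_zero_t_unit_p(self):
        rec = t_test(GroupSummary(5.0, 1.0, 4), GroupSummary(5.0, 2.0, 6))
        assert rec.t == 0.0 and rec.p == pytest.approx(1.0)

    def test_welch_matches_formula_and_numeric_tail(self):
        x, y = (1.0, 2.0, 3.0), (4.0, 5.0, 6.0)
        sx = math.sqrt(sum((v - 2.0) ** 2 for v in x) / 2)
        sy = math.sqrt(sum((v - 5.0) ** 2 for v in y) / 2)
        rec = t_test(GroupSummary(2.0, sx, 3), GroupSummary(5.0, sy, 3))
        t_direct = (2.0 - 5.0) / math.sqrt(sx**2 / 3 + sy**2 / 3)
        assert rec.t == pytest.approx(t_direct, abs=1e-12)
        # numeric integration of the t density as an independent tail oracle
        df = rec.df

        def pdf(u):
            return (math.gamma((df + 1) / 2) /
                    (math.sqrt(df * math.pi) * math.gamma(df / 2)) *
                    (1 + u * u / df) ** (-(df + 1) / 2))

        tail, _ = integrate.quad(pdf, abs(rec.t), np.inf)
        assert rec.p == pytest.approx(2 * tail, rel=1e-8)

    def test_swapping_groups_negates_t_preserves_p(self):
        a, b = GroupSummary(1.0, 0.5, 5), GroupSummary(2.0, 0.8, 7)
        r1, r2 = t_test(a, b), t_test(b, a)
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)

    def test_welch_equals_pooled_for_equal_variance_equal_n(self):
        a, b = GroupSummary(1.0, 0.7, 6), GroupSummary(3.0, 0.7, 6)
        assert t_test(a, b, "welch").t == pytest.approx(t_test(a, b, "pooled").t,
                                                        abs=1e-12)

    def test_zero_variance_equal_means_is_flagged(self):
        rec = t_test(GroupSummary(2.0, 0.0, 3), GroupSummary(2.0, 0.0, 3))
        assert rec.undefined
        assert select_de_ttest([rec], 0.5) == set()


class TestSelectTtest:
    def test_alpha_extremes(self):
        data = dataset_from_arrays(np.random.default_rng(0).normal(size=(10, 4)),
                                   np.random.default_rng(1).normal(size=(10, 4)))
        records = t_test_dataset(data)
        assert select_de_ttest(records, 1.0) == {r.gene for r in records}
        assert select_de_ttest(records, 0.0) == set()

    def test_null_calibration_within_binomial_bounds(self):
        """Type-I error at alpha=0.001 on null data stays near alpha."""
        alpha, n_genes, n_seeds = 0.001, 2000, 20
        total = 0
        for seed in range(n_seeds):
            spec = synthetic.SyntheticSpec(n_genes=n_genes, de_fraction=0.0,
                                           seed=seed)
            data, _ = synthetic.generate_expression(spec)
            total += len(select_de_ttest(t_test_dataset(data), alpha))
        n = n_genes * n_seeds
        mean, sd = n * alpha, math.sqrt(n * alpha * (1 - alpha))
        assert abs(total - mean) <= 3.5 * sd


class TestSam:
    def test_planted_recovery_and_directions(self):
        spec = synthetic.SyntheticSpec(seed=5)
        data, truth = synthetic.generate_expression(spec)
        result = sam_analysis(data, seed=5, fdr_target=0.0019)
        called, dirs = select_de_sam(result, 0.0019)
        assert len(called & truth.de_genes) / len(truth.de_genes) >= 0.9
        false_calls = len(called - truth.de_genes)
        assert false_calls / max(1, len(called)) <= 0.01
        assert all(dirs[g] == "UR" for g in called & truth.de_genes_up)
        assert all(dirs[g] == "DR" for g in called & truth.de_genes_down)

    def test_null_data_calls_nearly_nothing(self):
        spec = synthetic.SyntheticSpec(n_genes=1000, de_fraction=0.0, seed=2)
        data, _ = synthetic.generate_expression(spec)
        result = sam_analysis(data, seed=2, fdr_target=0.0019)
        called, _ = select_de_sam(result, 0.0019)
        assert len(called) <= 10  # <= 1% of genes

    def test_duplicating_samples_preserves_d_sign(self):
        rng = np.random.default_rng(8)
        ctrl, dis = rng.normal(size=(30, 4)), rng.normal(size=(30, 5))
        r1 = sam_analysis(dataset_from_arrays(ctrl, dis), n_permutations=50, seed=0)
        r2 = sam_analysis(
            dataset_from_arrays(np.hstack([ctrl, ctrl]), np.hstack([dis, dis])),
            n_permutations=50, seed=0)
        assert np.array_equal(np.sign(r1.d), np.sign(r2.d))

    def test_fdr_curve_non_increasing_and_nested_calls(self):
        spec = synthetic.SyntheticSpec(n_genes=500, seed=3)
        data, _ = synthetic.generate_expression(spec)
        result = sam_analysis(data, seed=3)
        assert np.all(np.diff(result.fdr_grid) <= 1e-12)
        smaller, _ = select_de_sam(result, 0.001)
        larger, _ = select_de_sam(result, 0.05)
        assert smaller <= larger

    def test_fdr_target_one_calls_everything_beyond_minimal_delta(self):
        spec = synthetic.SyntheticSpec(n_genes=300, seed=4)
        data, _ = synthetic.generate_expression(spec)
        result = sam_analysis(data, seed=4)
        called, _ = select_de_sam(result, 1.0)
        assert len(called) > 0

    def test_zero_variance_genes_excluded(self):
        ctrl = np.vstack([[1.0, 1.0, 1.0], [0.3, 0.9, 0.5]])
        dis = np.vstack([[1.0, 1.0, 1.0], [1.2, 0.4, 0.8]])
        result = sam_analysis(dataset_from_arrays(ctrl, dis), n_permutations=10,
                              seed=0)
        assert result.excluded == {"G0"}
        assert result.genes == ["G1"]

    def test_fold_change_filter_drops_small_shifts(self):
        rng = np.random.default_rng(9)
        base = rng.normal(8, 1, size=50)
        ctrl = base[:, None] + rng.normal(0, 0.1, size=(50, 6))
        dis = base[:, None] + rng.normal(0, 0.1, size=(50, 6))
        dis[:10] += 3.0   # large shift, passes any fold filter
        dis[10:20] += 0.4  # significant but below a 2-fold (1 log2) change
        no_fc = sam_analysis(dataset_from_arrays(ctrl, dis), n_permutations=100,
                             seed=1, fdr_target=0.05)
        with_fc = sam_analysis(dataset_from_arrays(ctrl, dis), n_permutations=100,
                               seed=1, fdr_target=0.05, fold_change=2.0)
        small_shift = {f"G{i}" for i in range(10, 20)}
        assert no_fc.called & small_shift
        assert not (with_fc.called & small_shift)
        assert {f"G{i}" for i in range(10)} <= with_fc.called
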