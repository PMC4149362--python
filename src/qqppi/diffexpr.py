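"""Differential-expression selection: two-sample t and SAM.

Two routes select differentially expressed (DE) genes between the
control and disease groups of an :class:`~qqppi.datatypes.ExpressionDataset`:

* a per-gene two-sample t test (Welch by default, pooled-variance
  optional) with selection at a raw two-sided p-value threshold, and
* Significance Analysis of Microarrays (SAM): a moderated relative
  difference d_i = (mean_disease - mean_control) / (s_i + s0) whose
  null distribution is estimated by permuting group labels, with the
  false discovery rate at a threshold delta estimated as the median
  falsely-called count over permutations divided by the observed
  called count.  SAM additionally reports the direction (up- or
  down-regulated in disease) of each called gene and supports an
  optional fold-change filter.

Genes whose variance is zero in both groups carry no usable signal for
either statistic; they are flagged and excluded from calling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .datatypes import CONTROL, DISEASE, ExpressionDataset
from .errors import PreconditionError

logger = logging.getLogger(__name__)

UP = "UR"
DOWN = "DR"


@dataclass(frozen=True)
class GroupSummary:
    """Per-group per-gene summary: mean, sample s.d. (n-1), count."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class TTestRecord:
    """Result of one per-gene two-sample t test."""

    gene: str
    t: float
    p: float
    df: float
    undefined: bool = False  # both sds zero and means equal: excluded from calling


@dataclass
class SamResult:
    """Full SAM output for one dataset.

    ``d`` and ``s`` are aligned with ``genes``; ``expected_d`` are the
    permutation-averaged order statistics aligned with ``order`` (the
    argsort of ``d``).  ``delta_grid``/``fdr_grid`` tabulate the FDR
    estimate over candidate thresholds; ``called``/``direction_of``
    hold the call at the selected ``delta``.
    """

    genes: list[str]
    d: np.ndarray
    s: np.ndarray
    s0: float
    order: np.ndarray
    expected_d: np.ndarray
    perm_d_sorted: np.ndarray  # permutations x genes, each row sorted
    delta: float
    fdr: float
    called: set[str]
    direction_of: dict[str, str]
    fold_change_threshold: float | None
    excluded: set[str] = field(default_factory=set)
    delta_grid: np.ndarray | None = None
    fdr_grid: np.ndarray | None = None  # monotone (reported) curve
    fdr_grid_raw: np.ndarray | None = None  # per-delta estimates (selection)
    mean_control: np.ndarray | None = None
    mean_disease: np.ndarray | None = None


def group_summaries(
    data: ExpressionDataset,
) -> dict[str, tuple[GroupSummary, GroupSummary]]:
    """Per-gene (control, disease) summaries: mean, sd (n-1), n."""
    out: dict[str, tuple[GroupSummary, GroupSummary]] = {}
    ctrl = data.group_matrix(CONTROL).to_numpy()
    dis = data.group_matrix(DISEASE).to_numpy()
    n, m = ctrl.shape[1], dis.shape[1]
    if n < 2 or m < 2:
        raise PreconditionError("each group needs at least 2 samples")
    cm, dm = ctrl.mean(axis=1), dis.mean(axis=1)
    cs, ds = ctrl.std(axis=1, ddof=1), dis.std(axis=1, ddof=1)
    for i, gene in enumerate(data.gene_ids):
        out[gene] = (
            GroupSummary(float(cm[i]), float(cs[i]), n),
            GroupSummary(float(dm[i]), float(ds[i]), m),
        )
    return out


def t_test(
    summary_c: GroupSummary,
    summary_d: GroupSummary,
    variant: str = "welch",
    gene: str = "",
) -> TTestRecord:
    """Two-sample t between a control and a disease group summary.

    ``welch`` uses per-group variances with Welch-Satterthwaite degrees
    of freedom; ``pooled`` is the classical equal-variance form.  When
    both sds are zero the statistic is undefined: equal means yield a
    flagged record (excluded from calling downstream), unequal means an
    infinite statistic with p = 0.
    """
    if variant not in ("welch", "pooled"):
        raise PreconditionError(f"unknown t-test variant: {variant}")
    n, m = summary_c.n, summary_d.n
    if n < 2 or m < 2:
        raise PreconditionError("t test needs >= 2 samples per group")
    diff = summary_c.mean - summary_d.mean
    if summary_c.sd == 0.0 and summary_d.sd == 0.0:
        if diff == 0.0:
            return TTestRecord(gene, math.nan, math.nan, math.nan, undefined=True)
        return TTestRecord(gene, math.copysign(math.inf, diff), 0.0, float(n + m - 2))
    vc, vd = summary_c.sd**2, summary_d.sd**2
    if variant == "welch":
        se2 = vc / n + vd / m
        df = se2**2 / ((vc / n) ** 2 / (n - 1) + (vd / m) ** 2 / (m - 1))
    else:
        sp2 = ((n - 1) * vc + (m - 1) * vd) / (n + m - 2)
        se2 = sp2 * (1.0 / n + 1.0 / m)
        df = float(n + m - 2)
    t = diff / math.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestRecord(gene, float(t), float(p), float(df))


def t_test_dataset(data: ExpressionDataset, variant: str = "welch") -> list[TTestRecord]:
    """Run :func:`t_test` for every gene of a dataset."""
    summaries = group_summaries(data)
    return [t_test(c, d, variant=variant, gene=g) for g, (c, d) in summaries.items()]


def select_de_ttest(records: list[TTestRecord], alpha: float) -> set[str]:
    """Genes with two-sided p strictly below ``alpha`` (raw, unadjusted)."""
    if not 0.0 <= alpha <= 1.0:
        raise PreconditionError("alpha must lie in [0, 1]")
    return {r.gene for r in records if not r.undefined and r.p < alpha}


# ---------------------------------------------------------------------------
# SAM


def _relative_difference(
    ctrl: np.ndarray, dis: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """d_i and pooled scatter s_i for a genes x samples split."""
    n, m = ctrl.shape[1], dis.shape[1]
    a = (1.0 / n + 1.0 / m) / (n + m - 2)
    ss = ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((dis - dis.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt(a * ss)
    denom = s + s0
    diff = dis.mean(axis=1) - ctrl.mean(axis=1)
    d = np.divide(diff, denom, out=np.zeros_like(diff), where=denom > 0)
    return d, s


def _tune_s0(ctrl: np.ndarray, dis: np.ndarray, s: np.ndarray) -> float:
    """Exchangeability constant minimizing the coefficient of variation
    of the median absolute deviation of d across windows of s.

    Candidate s0 values are the 0,5,...,100 percentiles of s; d is
    recomputed for each candidate, its MAD is taken within each of 100
    s-quantile windows, and the candidate with the smallest CV of those
    window MADs wins.  Degenerate windows (all-equal s) fall back to
    the median of s.
    """
    qs = np.percentile(s, np.arange(0, 101, 5))
    edges = np.percentile(s, np.arange(0, 101, 1))
    bin_of = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 99)
    best_s0, best_cv = float(np.median(s)), math.inf
    for s0 in qs:
        d, _ = _relative_difference(ctrl, dis, float(s0))
        mads = []
        for b in range(100):
            db = d[bin_of == b]
            if db.size:
                mads.append(np.median(np.abs(db - np.median(db))))
        mads = np.asarray(mads)
        mu = mads.mean()
        if mu <= 0:
            continue
        cv = mads.std(ddof=0) / mu
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _balanced_permutations(n: int, m: int, n_permutations: int, rng: np.random.Generator):
    """Permuted control-column index sets of size n out of n+m labels.

    All distinct label permutations are enumerated when their count is
    within budget; otherwise ``n_permutations`` are sampled with the
    seeded generator.  The identity split is always included first.
    """
    total = math.comb(n + m, n)
    identity = tuple(range(n))
    if total <= n_permutations:
        combos = [c for c in combinations(range(n + m), n)]
        combos.remove(identity)
        return [identity] + combos
    picks = {identity}
    out = [identity]
    while len(out) < n_permutations:
        c = tuple(sorted(rng.choice(n + m, size=n, replace=False).tolist()))
        if c not in picks:
            picks.add(c)
            out.append(c)
    return out


def sam_analysis(
    data: ExpressionDataset,
    n_permutations: int = 200,
    s0_policy: str = "tusher",
    fold_change: float | None = None,
    seed: int = 0,
    fdr_target: float | None = None,
    n_delta: int = 200,
) -> SamResult:
    """Run SAM on a two-group dataset.

    Parameters
    ----------
    n_permutations : int
        Budget for label permutations; all distinct splits are
        enumerated when fewer than the budget exist.
    s0_policy : {"tusher", "median"}
        How the exchangeability constant s0 is chosen: the CV-of-MAD
        percentile search, or simply the median of the gene scatters.
    fold_change : float, optional
        When set, a called gene must additionally change by at least
        this ratio between group means (expression is log2 scale, so
        the mean difference must exceed log2(fold_change)).
    fdr_target : float, optional
        When given, ``delta`` is the smallest grid threshold whose FDR
        estimate is <= the target; otherwise delta 0 (all genes ranked,
        nothing thresholded yet — use :func:`select_de_sam`).
    """
    if n_permutations < 1:
        raise PreconditionError("n_permutations must be >= 1")
    if s0_policy not in ("tusher", "median"):
        raise PreconditionError(f"unknown s0_policy: {s0_policy}")
    ctrl = data.group_matrix(CONTROL).to_numpy()
    dis = data.group_matrix(DISEASE).to_numpy()
    n, m = ctrl.shape[1], dis.shape[1]
    if n < 2 or m < 2:
        raise PreconditionError("SAM needs >= 2 samples per group")
    genes = data.gene_ids

    _, s = _relative_difference(ctrl, dis, 0.0)
    flat = s == 0.0
    excluded = {genes[i] for i in np.nonzero(flat)[0]}
    if excluded:
        logger.info("sam_analysis: excluded %d zero-variance gene(s)", len(excluded))
    keep = ~flat
    ctrl_k, dis_k = ctrl[keep], dis[keep]
    genes_k = [g for g, k in zip(genes, keep) if k]
    s_k = s[keep]

    s0 = _tune_s0(ctrl_k, dis_k, s_k) if s0_policy == "tusher" else float(np.median(s_k))
    d, _ = _relative_difference(ctrl_k, dis_k, s0)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]

    rng = np.random.default_rng(seed)
    splits = _balanced_permutations(n, m, n_permutations, rng)
    pooled = np.hstack([ctrl_k, dis_k])
    all_cols = set(range(n + m))
    perm_rows = []
    for cols in splits[1:]:  # identity excluded from the null ensemble
        c_idx = list(cols)
        d_idx = sorted(all_cols - set(cols))
        dp, _ = _relative_difference(pooled[:, c_idx], pooled[:, d_idx], s0)
        perm_rows.append(np.sort(dp))
    if not perm_rows:  # n_permutations=1: identity only; null = observed
        perm_rows.append(d_sorted.copy())
    perm_d_sorted = np.vstack(perm_rows)
    expected_d = perm_d_sorted.mean(axis=0)

    mc, md = ctrl_k.mean(axis=1), dis_k.mean(axis=1)
    # candidate thresholds are the achieved |gap| values themselves (every
    # distinct calling configuration occurs at one of them); rank-sampled
    # down to the budget so no gap in the value range is skipped
    gaps = np.unique(np.abs(d_sorted - expected_d))
    if gaps.size > n_delta:
        idx = np.unique(np.linspace(0, gaps.size - 1, n_delta).round().astype(int))
        gaps = gaps[idx]
    grid = np.unique(np.concatenate([[0.0], gaps, [gaps[-1] + 1.0]]))
    fdr_grid_raw = np.array([
        _fdr_at_delta(d_sorted, expected_d, perm_d_sorted, float(dl))[0] for dl in grid
    ])
    # reported curve is monotonized (the estimate at delta is the best
    # achievable at or beyond delta) so it is non-increasing in the
    # threshold; threshold selection uses the raw per-delta estimates
    fdr_grid = np.minimum.accumulate(fdr_grid_raw[::-1])[::-1]

    if fdr_target is None:
        delta = 0.0
    else:
        ok = np.nonzero(fdr_grid_raw <= fdr_target)[0]
        if ok.size == 0:
            logger.warning("sam_analysis: no delta reaches FDR target %g", fdr_target)
            delta = float(grid[-1]) + 1.0  # calls nothing
        else:
            delta = float(grid[ok[0]])
    fdr, called_mask = _fdr_at_delta(d_sorted, expected_d, perm_d_sorted, delta)

    called: set[str] = set()
    direction_of: dict[str, str] = {}
    log_fc = math.log2(fold_change) if fold_change else None
    # map sorted-order call mask back to gene positions
    call_by_pos = np.zeros(len(genes_k), dtype=bool)
    call_by_pos[order] = called_mask
    for i, gene in enumerate(genes_k):
        if not call_by_pos[i]:
            continue
        if log_fc is not None and abs(md[i] - mc[i]) < log_fc:
            continue
        called.add(gene)
        direction_of[gene] = UP if d[i] > 0 else DOWN
    return SamResult(
        genes=genes_k, d=d, s=s_k, s0=s0, order=order, expected_d=expected_d,
        perm_d_sorted=perm_d_sorted, delta=delta, fdr=fdr, called=called,
        direction_of=direction_of, fold_change_threshold=fold_change,
        excluded=excluded, delta_grid=grid, fdr_grid=fdr_grid,
        fdr_grid_raw=fdr_grid_raw, mean_control=mc, mean_disease=md,
    )


def _fdr_at_delta(
    d_sorted: np.ndarray,
    expected_d: np.ndarray,
    perm_d_sorted: np.ndarray,
    delta: float,
) -> tuple[float, np.ndarray]:
    """FDR estimate and sorted-order call mask at one threshold.

    The observed sorted d are compared with the permutation-expected
    order statistics; the cut points are the smallest observed d (on
    the positive side) and largest (negative side) whose gap from the
    expectation reaches delta.  Falsely-called counts are permutation d
    values beyond the cut points; the estimate is their median over
    permutations divided by the observed called count.
    """
    gap = d_sorted - expected_d
    i0 = int(np.searchsorted(d_sorted, 0.0))
    up = np.nonzero(gap[i0:] >= delta)[0]
    cut_up = d_sorted[i0 + up[0]] if up.size else math.inf
    low = np.nonzero(gap[:i0] <= -delta)[0]
    cut_low = d_sorted[low[-1]] if low.size else -math.inf
    called_mask = (d_sorted >= cut_up) | (d_sorted <= cut_low)
    n_called = int(called_mask.sum())
    if n_called == 0:
        logger.info("_fdr_at_delta: zero called genes at delta=%g; FDR reported 0", delta)
        return 0.0, called_mask
    false_counts = ((perm_d_sorted >= cut_up) | (perm_d_sorted <= cut_low)).sum(axis=1)
    return float(np.median(false_counts)) / n_called, called_mask


def select_de_sam(
    result: SamResult, fdr_target: float
) -> tuple[set[str], dict[str, str]]:
    """Called genes at the smallest delta whose FDR estimate meets the target.

    Returns the called gene set and its UP/DOWN direction map; an
    unreachable target yields the empty set with a warning.
    """
    if result.delta_grid is None or result.fdr_grid_raw is None:
        raise PreconditionError("SamResult lacks a delta grid")
    ok = np.nonzero(result.fdr_grid_raw <= fdr_target)[0]
    if ok.size == 0:
        logger.warning("select_de_sam: no delta achieves FDR <= %g", fdr_target)
        return set(), {}
    delta = float(result.delta_grid[ok[0]])
    _, called_mask = _fdr_at_delta(
        np.sort(result.d), result.expected_d, result.perm_d_sorted, delta
    )
    call_by_pos = np.zeros(len(result.genes), dtype=bool)
    call_by_pos[result.order] = called_mask
    log_fc = (
        math.log2(result.fold_change_threshold)
        if result.fold_change_threshold
        else None
    )
    called: set[str] = set()
    directions: dict[str, str] = {}
    for i, gene in enumerate(result.genes):
        if not call_by_pos[i]:
            continue
        if log_fc is not None and result.mean_control is not None:
            if abs(result.mean_disease[i] - result.mean_control[i]) < log_fc:
                continue
        called.add(gene)
        directions[gene] = UP if result.d[i] > 0 else DOWN
    return called, directions
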