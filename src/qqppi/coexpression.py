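"""Differential co-expression of interacting gene pairs.

For every network edge the Pearson correlation of the two genes'
expression is computed separately over control samples (C) and disease
samples (D).  The co-expression change is C - D; since r lies in
[-1, 1] the maximum possible change is 2, and the percent of maximum
change is 100 * (C - D) / 2.  Pairs involving a constant (zero
variance) vector have undefined correlation and are excluded with a
logged warning rather than silently reported as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import CONTROL, DISEASE, ExpressionDataset
from .errors import PreconditionError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoexpressionRecord:
    node1: str
    node2: str
    r_control: float
    r_disease: float

    @property
    def change(self) -> float:
        return self.r_control - self.r_disease

    @property
    def pct_max_change(self) -> float:
        return 100.0 * self.change / 2.0


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise PreconditionError("pearson_r needs two equal-length vectors, n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx = float(np.sqrt((xd * xd).sum()))
    sy = float(np.sqrt((yd * yd).sum()))
    if sx == 0.0 or sy == 0.0:
        raise PreconditionError("pearson_r undefined for a constant vector")
    return float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))


def coexpression_change(r_control: float, r_disease: float) -> tuple[float, float]:
    """(C - D, percent of the maximum possible change of 2)."""
    change = r_control - r_disease
    return change, 100.0 * change / 2.0


def edge_coexpression(edges, data: ExpressionDataset) -> list[CoexpressionRecord]:
    """One record per edge with r over control and disease samples.

    Edges with a missing gene or an undefined correlation are skipped
    with a logged identity.
    """
    ctrl = data.group_matrix(CONTROL)
    dis = data.group_matrix(DISEASE)
    if ctrl.shape[1] < 3 or dis.shape[1] < 3:
        raise PreconditionError("co-expression needs >= 3 samples per group")
    present = set(data.gene_ids)
    out = []
    for a, b in sorted(edges):
        if a not in present or b not in present:
            logger.info("edge_coexpression: skipping %s-%s (gene missing)", a, b)
            continue
        try:
            rc = pearson_r(ctrl.loc[a].to_numpy(), ctrl.loc[b].to_numpy())
            rd = pearson_r(dis.loc[a].to_numpy(), dis.loc[b].to_numpy())
        except PreconditionError:
            logger.warning("edge_coexpression: undefined r for %s-%s; excluded", a, b)
            continue
        out.append(CoexpressionRecord(a, b, rc, rd))
    return out


def complex_coexpression(
    matches, net_edges, data: ExpressionDataset
) -> list[tuple[str, str, CoexpressionRecord]]:
    """Co-expression of intra-complex pairs that are also network edges.

    Returns rows of (complex id, complex name, record), grouped by
    complex in match order.
    """
    edge_set = set(net_edges)
    rows = []
    for match in matches:
        pairs = []
        members = sorted(match.all_members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                edge = (a, b) if a <= b else (b, a)
                if edge in edge_set:
                    pairs.append(edge)
        for rec in edge_coexpression(pairs, data):
            rows.append((match.complex_id, match.name, rec))
    return rows
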