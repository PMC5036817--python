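"""Target-gene normalization with a chosen reference set, and group tests.

Given relative quantities RQ(g, s), the per-sample normalization factor is
the geometric mean of the reference genes' RQs,

    NF_s = ( prod_{r in RG} RQ(r, s) )^(1/|RG|),

and the normalized relative quantity of a target t is
NRQ(t, s) = RQ(t, s) / NF_s.  Between-group differences in NRQ are tested
with the two-sided Mann-Whitney U test and summarised as the ratio of
group medians.  Everything a reference set fails to cancel — e.g. a group
effect carried by the reference genes themselves — propagates into the
targets' NRQ with opposite sign, which is exactly why reference-gene
choice can make or break significance calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .expression import to_rq
from .panel import ExpressionMatrix

__all__ = ["NrqReport", "normalize", "mann_whitney", "compare_groups"]

EXACT_MAX_N = 16  # exact U distribution up to this combined sample size


@dataclass
class NrqReport:
    """Normalized expression of target genes plus group-comparison results."""

    rg_set: list[str]
    targets: list[str]
    nf: pd.Series  # per-sample normalization factor
    rq: pd.DataFrame  # target x sample relative quantities
    nrq: pd.DataFrame  # target x sample normalized relative quantities
    groups: dict[str, str]
    comparisons: pd.DataFrame | None = None
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    group_order: list[str] = field(default_factory=list)


def normalize(
    matrix: ExpressionMatrix,
    rg_set: list[str],
    targets: list[str] | None = None,
) -> NrqReport:
    """Compute NF and NRQ for ``targets`` using reference set ``rg_set``."""
    if not rg_set:
        raise ValueError("reference gene set is empty")
    absent = [g for g in rg_set if g not in matrix.data.index]
    if absent:
        raise ValueError(
            f"reference gene(s) not in the retained matrix (excluded by QC?): {absent}"
        )
    if matrix.scale == "cq":
        raise ValueError("normalize expects relative quantities; convert Cq first")
    rq = to_rq(matrix)
    if targets is None:
        targets = [g for g in rq.genes if g not in set(rg_set)]
    missing_t = [g for g in targets if g not in rq.data.index]
    if missing_t:
        raise ValueError(f"target gene(s) not in the matrix: {missing_t}")

    nf = pd.Series(
        np.exp(np.log(rq.data.loc[list(rg_set)].to_numpy()).mean(axis=0)),
        index=rq.samples,
        name="nf",
    )
    rq_t = rq.data.loc[list(targets)]
    nrq = rq_t / nf
    return NrqReport(
        rg_set=list(rg_set),
        targets=list(targets),
        nf=nf,
        rq=rq_t,
        nrq=nrq,
        groups=dict(matrix.groups),
    )


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U, p) with U = min(U_x, U_y).

    The exact null distribution is used when the combined sample size is at
    most 16 and there are no ties; otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return u, min(1.0, float(res.pvalue))


def _stars(p: float, alpha_levels: tuple[float, float]) -> str:
    lo, hi = min(alpha_levels), max(alpha_levels)
    if p < lo:
        return "**"
    if p < hi:
        return "*"
    return "ns"


def compare_groups(
    report: NrqReport,
    *,
    group_order: tuple[str, str] | None = None,
    alpha_levels: tuple[float, float] = (0.05, 0.01),
    summary: str = "median",
    bonferroni: bool = False,
) -> NrqReport:
    """Fill in per-target Mann-Whitney tests between the two groups.

    ``group_order`` is (reference, test); fold change is the test-group
    summary divided by the reference-group summary.  Defaults to the order
    of first appearance over samples (e.g. control, infected).
    """
    labels = []
    for s in report.nrq.columns:
        g = report.groups[s]
        if g not in labels:
            labels.append(g)
    if group_order is None:
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 groups, found {labels}")
        group_order = (labels[0], labels[1])
    ref, test = group_order
    ref_samples = [s for s in report.nrq.columns if report.groups[s] == ref]
    test_samples = [s for s in report.nrq.columns if report.groups[s] == test]
    if not ref_samples or not test_samples:
        raise ValueError(f"empty group after cohort filtering: {group_order}")
    summarise = np.median if summary == "median" else np.mean

    rows = []
    for t in report.targets:
        a = report.nrq.loc[t, ref_samples].to_numpy()
        b = report.nrq.loc[t, test_samples].to_numpy()
        u, p = mann_whitney(a, b)
        if bonferroni:
            p = min(1.0, p * len(report.targets))
        m_ref = float(summarise(a))
        m_test = float(summarise(b))
        rows.append(
            {
                "gene": t,
                f"{summary}_{ref}": m_ref,
                f"{summary}_{test}": m_test,
                "fold_change": m_test / m_ref,
                "U": u,
                "p_value": p,
                "significance": _stars(p, alpha_levels),
            }
        )
    report.comparisons = pd.DataFrame(rows).set_index("gene")
    report.alpha_levels = alpha_levels
    report.group_order = [ref, test]
    return report
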