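"""geNorm reference-gene stability analysis.

For genes j, k with log-scale expression vectors x_j, x_k over samples,
the pairwise variation V_jk is the standard deviation over samples of the
log-ratio x_j - x_k.  A gene's stability M_j is the mean of V_jk over all
partner genes k; lower M means the gene co-varies more tightly with the
rest of the panel, i.e. behaves more like a constant reference.  The
classical acceptability cut-off is M < 0.5.

Ranking proceeds by stepwise elimination: the gene with the highest M is
dropped and M is recomputed for the survivors, down to a final pair which
the procedure itself cannot separate (here ordered by final-round M, then
input order, for downstream rank aggregation).

The V-curve decides how many reference genes are enough: with NF_n the
per-sample mean log expression of the top-n genes, V(n/n+1) is the
standard deviation over samples of NF_n - NF_{n+1}; the smallest n with
V < 0.15 is recommended.

All statistics here depend only on differences between gene rows, so they
are invariant to per-sample loading offsets and to the anchor used when
forming relative quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ExpressionMatrix
from .tables import StabilityTable

__all__ = ["GeNormResult", "pairwise_variation", "m_values", "rank_genorm"]

M_THRESHOLD_DEFAULT = 0.5
V_THRESHOLD_DEFAULT = 0.15


def pairwise_variation(x: np.ndarray, y: np.ndarray) -> float:
    """Standard deviation (n-1 denominator) of the paired differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("pairwise variation needs at least 2 samples")
    return float(np.std(x - y, ddof=1))


def _as_frame(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, ExpressionMatrix) else matrix


def m_values(
    matrix: ExpressionMatrix | pd.DataFrame, genes: list[str] | None = None
) -> pd.Series:
    """M value of every gene in ``genes`` against the others in the subset.

    Computed pair-by-pair from the definition (sd of each log-ratio, then
    the mean over partners).
    """
    df = _as_frame(matrix)
    if genes is not None:
        df = df.loc[list(genes)]
    k = len(df)
    if k < 2:
        raise ValueError("M values need at least 2 genes")
    X = df.to_numpy(dtype=float)
    M = np.zeros(k)
    for j in range(k):
        total = 0.0
        for l in range(k):
            if l != j:
                total += np.std(X[j] - X[l], ddof=1)
        M[j] = total / (k - 1)
    return pd.Series(M, index=df.index, name="M")


@dataclass
class GeNormResult:
    """Full output of the stepwise geNorm procedure."""

    ranking: list[str]  # most stable first
    m_trace: list[dict[str, float]]  # per elimination round: gene -> M
    final_m: dict[str, float]  # M at the round each gene left (or last round)
    v_curve: dict[int, float]  # n -> V(n/n+1)
    m_threshold: float = M_THRESHOLD_DEFAULT
    v_threshold: float = V_THRESHOLD_DEFAULT
    recommended_n: int | None = None
    stable_genes: list[str] = field(default_factory=list)

    def stability_table(self, *, tie_average_final_pair: bool = False) -> StabilityTable:
        """Ranks 1..k by elimination order; optionally give the unrankable
        final pair the tied rank 1.5 each."""
        scores = pd.Series(self.final_m).reindex(self.ranking)
        table = StabilityTable.from_order("genorm", self.ranking, scores=scores)
        if tie_average_final_pair and len(self.ranking) >= 2:
            table.ranks.iloc[:2] = 1.5
        return table


def rank_genorm(
    matrix: ExpressionMatrix | pd.DataFrame,
    *,
    m_threshold: float = M_THRESHOLD_DEFAULT,
    v_threshold: float = V_THRESHOLD_DEFAULT,
) -> GeNormResult:
    """Stepwise elimination ranking plus the V(n/n+1) curve.

    Ties in M during elimination are broken by removing the gene that comes
    later in input order, for determinism.
    """
    df = _as_frame(matrix)
    k = len(df)
    if k < 3:
        raise ValueError("geNorm ranking needs >= 3 genes; use m_values for a pair")
    if df.shape[1] < 2:
        raise ValueError("geNorm needs >= 2 samples")
    if df.isna().any().any():
        raise ValueError("matrix has missing cells; run QC first")

    remaining = list(df.index)
    eliminated: list[str] = []
    m_trace: list[dict[str, float]] = []
    final_m: dict[str, float] = {}
    while len(remaining) > 2:
        m = m_values(df, remaining)
        m_trace.append({g: float(m[g]) for g in remaining})
        worst_val = m.max()
        # tie-break: later in input order == last position in `remaining`
        worst = [g for g in remaining if m[g] == worst_val][-1]
        final_m[worst] = float(m[worst])
        remaining.remove(worst)
        eliminated.append(worst)

    m_last = m_values(df, remaining)
    m_trace.append({g: float(m_last[g]) for g in remaining})
    for g in remaining:
        final_m[g] = float(m_last[g])
    # final pair ordered by last-round M ascending, then input order
    pair = sorted(remaining, key=lambda g: (m_last[g], list(df.index).index(g)))
    ranking = pair + eliminated[::-1]

    v_curve: dict[int, float] = {}
    X = df.loc[ranking].to_numpy(dtype=float)
    for n in range(2, k):
        nf_n = X[:n].mean(axis=0)
        nf_n1 = X[: n + 1].mean(axis=0)
        v_curve[n] = float(np.std(nf_n - nf_n1, ddof=1))
    recommended = next((n for n, v in v_curve.items() if v < v_threshold), None)

    return GeNormResult(
        ranking=ranking,
        m_trace=m_trace,
        final_m=final_m,
        v_curve=v_curve,
        m_threshold=m_threshold,
        v_threshold=v_threshold,
        recommended_n=recommended,
        stable_genes=[g for g in ranking if final_m[g] < m_threshold],
    )
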