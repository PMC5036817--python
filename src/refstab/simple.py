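"""Descriptive stability measures: BestKeeper and the comparative ΔCt method.

BestKeeper works on raw Cq: a candidate is stable when its Cq varies
little across samples (low sd, low CV%) and tracks the per-sample
BestKeeper index — the geometric mean of all candidates' Cq.  Because it
operates on raw cycles it is deliberately *not* invariant to per-sample
loading offsets.  Ranking is by sd ascending (CV% as tie-break); the
classical sd <= 1 cycle acceptability flag is reported but does not drop
genes, and the index correlation r is reported, not ranked on.

The comparative ΔCt method scores gene g by the mean, over every partner
gene p, of the standard deviation across samples of Cq_g - Cq_p.  On a
shared efficiency base this is algebraically the same quantity as the
full-panel geNorm M value, computed here from the covariance matrix as an
independent route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ExpressionMatrix
from .tables import StabilityTable

__all__ = ["BestKeeperResult", "DeltaCtResult", "bestkeeper", "delta_ct"]


@dataclass
class BestKeeperResult:
    table: pd.DataFrame  # per gene: sd_cq, cv_pct, pearson_r, sd_acceptable
    index: pd.Series  # per sample: geometric mean Cq
    ranking: list[str]  # by sd_cq ascending, cv_pct tie-break

    def stability_table(self) -> StabilityTable:
        return StabilityTable.from_scores("bestkeeper", self.table["sd_cq"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.loc[self.ranking].reset_index(names="gene")
        out.insert(1, "rank", np.arange(1, len(out) + 1))
        return out


@dataclass
class DeltaCtResult:
    scores: pd.Series  # gene -> mean pairwise sd (cycles)
    ranking: list[str]

    def stability_table(self) -> StabilityTable:
        return StabilityTable.from_scores("deltact", self.scores)

    def to_frame(self) -> pd.DataFrame:
        tab = self.stability_table().to_frame()
        return tab.rename(columns={"score": "mean_pair_sd"})


def bestkeeper(matrix: ExpressionMatrix) -> BestKeeperResult:
    """BestKeeper descriptive statistics on a complete Cq matrix."""
    if matrix.scale != "cq":
        raise ValueError("BestKeeper operates on raw Cq values")
    if not matrix.is_complete:
        raise ValueError("matrix has missing cells; run QC first")
    df = matrix.data
    if df.shape[1] < 2:
        raise ValueError("BestKeeper needs >= 2 samples")

    index = pd.Series(
        np.exp(np.log(df.to_numpy(dtype=float)).mean(axis=0)),
        index=df.columns,
        name="bestkeeper_index",
    )
    sd = df.std(axis=1, ddof=1)
    cv = 100.0 * sd / df.mean(axis=1)
    centred = df.sub(df.mean(axis=1), axis=0)
    idx_centred = index - index.mean()
    denom = sd * np.sqrt((idx_centred**2).sum()) * np.sqrt(df.shape[1] - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centred @ idx_centred) / denom
    r[sd == 0] = np.nan  # correlation undefined for a constant gene

    table = pd.DataFrame(
        {
            "sd_cq": sd,
            "cv_pct": cv,
            "pearson_r": r,
            "sd_acceptable": sd <= 1.0,
        }
    )
    order = table.sort_values(["sd_cq", "cv_pct"], kind="stable").index.tolist()
    return BestKeeperResult(table=table, index=index, ranking=order)


def delta_ct(matrix: ExpressionMatrix) -> DeltaCtResult:
    """Comparative ΔCt stability scores on a complete matrix.

    Uses the identity sd(x - y)^2 = var(x) + var(y) - 2 cov(x, y) over the
    gene covariance matrix, so every unordered pair contributes once to
    each member's mean.
    """
    if not matrix.is_complete:
        raise ValueError("matrix has missing cells; run QC first")
    df = matrix.data
    k = len(df)
    if k < 2:
        raise ValueError("ΔCt needs >= 2 genes")
    if df.shape[1] < 2:
        raise ValueError("ΔCt needs >= 2 samples")

    cov = np.cov(df.to_numpy(dtype=float), ddof=1)
    diag = np.diag(cov)
    pair_var = np.clip(diag[:, None] + diag[None, :] - 2.0 * cov, 0.0, None)
    pair_sd = np.sqrt(pair_var)
    np.fill_diagonal(pair_sd, 0.0)
    scores = pd.Series(pair_sd.sum(axis=1) / (k - 1), index=df.index, name="mean_pair_sd")
    order = scores.sort_values(kind="stable").index.tolist()
    return DeltaCtResult(scores=scores, ranking=order)
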