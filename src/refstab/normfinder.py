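"""Model-based (NormFinder-style) stability estimation.

The expression of gene i in sample j of group g is modelled, on the log2
scale after removing per-sample loading, as

    z_ijg = alpha_ig + e_ijg,      e_ijg ~ (0, sigma2_ig)

where the group-specific means alpha_ig decompose into a gene effect plus
an intergroup deviation d_ig.  A reference gene should have both small
|d_ig| (no systematic group regulation) and small sigma2_ig (low
biological scatter).  The stability value combines the two:

    rho_i = (1/G) * sum_g ( |d~_ig| + sqrt(sigma2_ig / n_g) )

where d~_ig is the raw deviation shrunk towards zero by the empirical-
Bayes factor gamma2 / (gamma2 + sigma2_ig / n_g), with gamma2 the
between-group variance of the d's across genes.  Shrinkage keeps genes
with noisy, poorly-estimated deviations from being rewarded for chance
cancellation.  With a single group the intergroup term vanishes and rho
reduces to the bias-corrected within-group standard deviation.

Because the candidate panel itself is the only yardstick, the raw
within-group variances are corrected for the variance contributed by the
panel mean: sigma2_ig = (v_ig - vbar_g/(k-1)) * k/(k-2), floored at a
small epsilon; hence at least 3 genes are required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ExpressionMatrix
from .tables import StabilityTable

__all__ = ["NormFinderResult", "normfinder"]

VARIANCE_FLOOR = 1e-12


@dataclass
class NormFinderResult:
    """Stability values and their intergroup/intragroup components."""

    stability: pd.Series  # gene -> rho (lower = more stable)
    intergroup: pd.DataFrame  # gene x group, shrunk deviations d~ (log2 units)
    intergroup_raw: pd.DataFrame  # gene x group, unshrunk d
    intragroup_sd: pd.DataFrame  # gene x group, corrected sigma-hat (log2 units)
    gamma2: float  # between-group variance estimate
    ranking: list[str]  # genes sorted by rho ascending

    def stability_table(self) -> StabilityTable:
        return StabilityTable.from_scores("normfinder", self.stability)


def normfinder(
    matrix: ExpressionMatrix,
    *,
    use_groups: bool = True,
    weighted: bool = True,
) -> NormFinderResult:
    """Compute per-gene stability values on a complete log2 matrix.

    ``use_groups=False`` pools every sample into one group (pure
    intragroup analysis).  ``weighted`` controls whether the overall gene
    mean weights groups by size (default) or equally.
    """
    if not matrix.is_complete:
        raise ValueError("matrix has missing cells; run QC first")
    df = matrix.data
    k = len(df)
    if k < 3:
        raise ValueError("NormFinder needs >= 3 genes (variance correction undefined)")

    if use_groups:
        labels = matrix.group_labels()
    else:
        labels = ["__all__"]
    members = (
        {g: matrix.samples_in(g) for g in labels}
        if use_groups
        else {"__all__": matrix.samples}
    )
    n_g = {g: len(members[g]) for g in labels}
    for g, n in n_g.items():
        if n < 2:
            raise ValueError(f"group {g!r} has {n} sample(s); need >= 2")
    G = len(labels)
    N = sum(n_g.values())

    # 1. remove per-sample loading: subtract each sample's across-gene mean
    z = df - df.mean(axis=0)

    # 2. intergroup deviations
    zbar = pd.DataFrame({g: z[members[g]].mean(axis=1) for g in labels})
    if weighted:
        overall = sum(n_g[g] * zbar[g] for g in labels) / N
    else:
        overall = zbar.mean(axis=1)
    d = zbar.sub(overall, axis=0)

    # 3. bias-corrected within-group variances
    v = pd.DataFrame({g: z[members[g]].var(axis=1, ddof=1) for g in labels})
    vbar = v.mean(axis=0)  # per-group mean over genes
    sigma2 = ((v - vbar / (k - 1)) * (k / (k - 2))).clip(lower=VARIANCE_FLOOR)
    se2 = sigma2 / pd.Series(n_g)  # squared standard error of each group mean

    if G >= 2:
        # 4. between-group variance of the deviations across genes
        gamma2 = max(
            0.0,
            float((d**2).to_numpy().sum() / (k * (G - 1)) - se2.to_numpy().mean()),
        )
        # 5. shrink the deviations
        d_shrunk = d * (gamma2 / (gamma2 + se2))
        # 6. combine
        rho = (d_shrunk.abs() + np.sqrt(se2)).mean(axis=1)
    else:
        gamma2 = 0.0
        d_shrunk = d * 0.0
        rho = np.sqrt(sigma2.iloc[:, 0])

    rho = rho.astype(float)
    order = rho.sort_values(kind="stable").index.tolist()
    return NormFinderResult(
        stability=rho,
        intergroup=d_shrunk,
        intergroup_raw=d,
        intragroup_sd=np.sqrt(sigma2),
        gamma2=gamma2,
        ranking=order,
    )
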