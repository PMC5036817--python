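"""Replicate aggregation and missing-amplification gene filtering.

The stability algorithms downstream all require a complete gene x sample
matrix, so a candidate gene for which even one sample produced no signal
cannot be ranked across the whole data set and is dropped.  By default a
gene x sample cell counts as non-amplified only when *all* of its
replicates failed (``mode="cell"``); the stricter ``mode="replicate"``
drops a gene as soon as any single replicate reaction failed.  Replicate-
level failure counts are reported either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CqPanel, ExpressionMatrix

__all__ = ["QcReport", "aggregate_replicates", "exclude_incomplete_genes", "run_qc"]


@dataclass
class QcReport:
    """Bookkeeping of the missing-amplification exclusion step."""

    n_genes_input: int
    n_genes_excluded: int
    n_genes_retained: int
    n_reactions_total: int
    n_reactions_missing: int
    fraction_missing: float
    mode: str = "cell"
    #: gene -> {"n_missing_cells": ..., "n_missing_replicates": ...}
    excluded_genes: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        assert self.n_genes_input == self.n_genes_excluded + self.n_genes_retained
        assert 0 <= self.fraction_missing <= 1


def aggregate_replicates(panel: CqPanel) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Collapse replicates to a gene x sample Cq matrix.

    Each cell is the arithmetic mean of its non-missing replicate Cq values
    (no outlier rejection).  Returns the matrix together with a boolean
    gene x sample flag frame marking cells whose replicates *all* failed;
    those cells hold NaN in the matrix.
    """
    import warnings

    with warnings.catch_warnings():  # all-NaN cells warn otherwise
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(panel.values, axis=2)
    flags = np.isnan(panel.values).all(axis=2)
    data = pd.DataFrame(means, index=panel.genes, columns=panel.samples)
    flag_df = pd.DataFrame(flags, index=panel.genes, columns=panel.samples)
    return ExpressionMatrix(data, dict(panel.groups), scale="cq"), flag_df


def exclude_incomplete_genes(
    matrix: ExpressionMatrix,
    flags: pd.DataFrame,
    panel: CqPanel | None = None,
    *,
    mode: str = "cell",
) -> tuple[ExpressionMatrix, QcReport]:
    """Drop genes with non-amplified cells and tabulate QC counts.

    ``mode="cell"`` excludes a gene when any gene x sample cell has no
    surviving replicate; ``mode="replicate"`` excludes on any single
    missing replicate (requires ``panel``).  Reaction totals and missing
    counts are reported at replicate level when ``panel`` is given,
    otherwise at cell level.
    """
    if mode not in ("cell", "replicate"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "replicate" and panel is None:
        raise ValueError("mode='replicate' requires the source CqPanel")

    missing_cells = flags.sum(axis=1)
    if panel is not None:
        rep_missing = pd.Series(
            np.isnan(panel.values).sum(axis=(1, 2)), index=panel.genes
        ).reindex(matrix.genes)
        n_total = panel.n_reactions
        n_missing = panel.n_missing
    else:
        rep_missing = missing_cells
        n_total = int(flags.size)
        n_missing = int(flags.to_numpy().sum())

    if mode == "cell":
        bad = missing_cells > 0
    else:
        bad = rep_missing > 0
    excluded = [g for g in matrix.genes if bad[g]]
    retained = [g for g in matrix.genes if not bad[g]]
    if not retained:
        raise ValueError("no genes retained: every gene has non-amplified reactions")

    report = QcReport(
        n_genes_input=len(matrix.genes),
        n_genes_excluded=len(excluded),
        n_genes_retained=len(retained),
        n_reactions_total=n_total,
        n_reactions_missing=n_missing,
        fraction_missing=n_missing / n_total if n_total else 0.0,
        mode=mode,
        excluded_genes={
            g: {
                "n_missing_cells": int(missing_cells[g]),
                "n_missing_replicates": int(rep_missing[g]),
            }
            for g in excluded
        },
    )
    report.validate()
    out = matrix.subset_genes(retained)
    assert out.is_complete
    return out, report


def run_qc(panel: CqPanel, *, mode: str = "cell") -> tuple[ExpressionMatrix, QcReport]:
    """Aggregate replicates and apply the exclusion rule in one step."""
    matrix, flags = aggregate_replicates(panel)
    return exclude_incomplete_genes(matrix, flags, panel, mode=mode)
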