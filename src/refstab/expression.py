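"""Cq to (log) relative-quantity conversion.

A Cq value is the PCR cycle at which fluorescence crosses threshold; each
cycle multiplies the amplicon by the amplification efficiency ``base``
(2.0 for perfect doubling — appropriate here because the instrument's
relative-threshold Cq values are already efficiency-corrected).  Relative
quantity against a per-gene anchor Cq is therefore

    RQ(g, s)     = base ** (anchor_g - Cq(g, s))
    log2RQ(g, s) = log2(base) * (anchor_g - Cq(g, s))

With the default per-gene *mean* anchor, each gene's log2RQ averages to
zero across samples (geometric-mean-centred RQ); the *min* anchor instead
scores every sample relative to the highest-expressing one.  All
pairwise-ratio statistics downstream are invariant to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import ExpressionMatrix

__all__ = ["EfficiencyModel", "to_log2_rq", "to_rq"]


@dataclass(frozen=True)
class EfficiencyModel:
    """Per-cycle amplification factor, shared by all assays."""

    base: float = 2.0

    def __post_init__(self) -> None:
        if not self.base > 1:
            raise ValueError("amplification base must be > 1")


def to_log2_rq(
    matrix: ExpressionMatrix,
    eff: EfficiencyModel = EfficiencyModel(),
    anchor: str = "mean",
) -> ExpressionMatrix:
    """Convert a complete Cq matrix to log2 relative quantities."""
    if matrix.scale != "cq":
        raise ValueError(f"expected a cq-scale matrix, got {matrix.scale!r}")
    if not matrix.is_complete:
        raise ValueError("Cq matrix has missing cells; run QC first")
    if anchor == "mean":
        anchor_cq = matrix.data.mean(axis=1)
    elif anchor == "min":
        anchor_cq = matrix.data.min(axis=1)
    else:
        raise ValueError(f"unknown anchor {anchor!r}; expected 'mean' or 'min'")
    log2rq = matrix.data.rsub(anchor_cq, axis=0) * np.log2(eff.base)
    return ExpressionMatrix(log2rq, dict(matrix.groups), scale="log2rq")


def to_rq(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Linear relative quantities from a log2RQ matrix."""
    if matrix.scale == "rq":
        return matrix
    if matrix.scale != "log2rq":
        raise ValueError(f"expected a log2rq matrix, got {matrix.scale!r}")
    return ExpressionMatrix(2.0 ** matrix.data, dict(matrix.groups), scale="rq")
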