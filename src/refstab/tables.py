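"""Per-algorithm stability tables: the common currency of rank aggregation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["StabilityTable"]


@dataclass
class StabilityTable:
    """Per-gene stability score and rank for one algorithm on one cohort.

    Lower score means more stable; ``ranks`` are 1-based with ties as
    average ranks (so they may be non-integer).
    """

    method: str
    scores: pd.Series
    ranks: pd.Series

    def __post_init__(self) -> None:
        if set(self.scores.index) != set(self.ranks.index):
            raise ValueError("scores and ranks cover different gene sets")

    @classmethod
    def from_scores(cls, method: str, scores: pd.Series) -> "StabilityTable":
        """Rank by score ascending with midrank ties."""
        ranks = pd.Series(rankdata(scores.to_numpy(), method="average"), index=scores.index)
        return cls(method=method, scores=scores.astype(float), ranks=ranks)

    @classmethod
    def from_order(
        cls, method: str, order: list[str], scores: pd.Series | None = None
    ) -> "StabilityTable":
        """Integer ranks 1..k from an explicit best-first gene order."""
        ranks = pd.Series(np.arange(1, len(order) + 1, dtype=float), index=order)
        if scores is None:
            scores = ranks.copy()
        return cls(method=method, scores=scores.reindex(order).astype(float), ranks=ranks)

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    def ordering(self) -> list[str]:
        """Genes most-stable first (rank, then input order on exact ties)."""
        return list(self.ranks.sort_values(kind="stable").index)

    def top(self, n: int) -> list[str]:
        if not 1 <= n <= len(self.ranks):
            raise ValueError(f"top-n must be in [1, {len(self.ranks)}], got {n}")
        return self.ordering()[:n]

    def to_frame(self) -> pd.DataFrame:
        order = self.ordering()
        return pd.DataFrame(
            {
                "gene": order,
                "score": self.scores.reindex(order).to_numpy(),
                "rank": self.ranks.reindex(order).to_numpy(),
            }
        )
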