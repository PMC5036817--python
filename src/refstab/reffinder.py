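"""Rank aggregation across stability algorithms (RefFinder-style).

Each algorithm contributes a per-gene rank; the comprehensive score is the
geometric mean of a gene's ranks across the four methods (geNorm,
NormFinder, BestKeeper, ΔCt), final order by that geometric mean
ascending.  A second operation intersects the top-n gene lists of several
rankings — the "identical among the top-ten regardless of algorithm"
consensus used to nominate robust reference genes across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import StabilityTable

__all__ = ["ComprehensiveRanking", "aggregate", "consensus_top"]


@dataclass
class ComprehensiveRanking:
    """Per-gene ranks from each method plus their geometric mean."""

    table: pd.DataFrame  # index gene; rank_<method> columns, geomean_rank, position
    methods: list[str]

    @property
    def ordering(self) -> list[str]:
        return self.table.sort_values("position").index.tolist()

    def top(self, n: int) -> list[str]:
        if not 1 <= n <= len(self.table):
            raise ValueError(f"top-n must be in [1, {len(self.table)}], got {n}")
        return self.ordering[:n]

    def stability_table(self) -> StabilityTable:
        return StabilityTable(
            method="comprehensive",
            scores=self.table["geomean_rank"],
            ranks=self.table["position"].astype(float),
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.table.sort_values("position").reset_index(names="gene")
        cols = ["gene", "position"] + [f"rank_{m}" for m in self.methods] + ["geomean_rank"]
        return out[cols]


def aggregate(tables: Sequence[StabilityTable]) -> ComprehensiveRanking:
    """Geometric-mean rank aggregation over stability tables.

    All tables must cover the same gene set.  Final positions order by
    geometric-mean rank ascending; exact ties are broken by the best
    single-method rank, then by gene order in the first table.
    """
    if len(tables) < 2:
        raise ValueError("aggregation needs >= 2 stability tables")
    genes = list(tables[0].scores.index)
    for t in tables[1:]:
        if set(t.scores.index) != set(genes):
            diff = sorted(set(t.scores.index) ^ set(genes))
            raise ValueError(f"gene sets differ between tables: {diff}")

    methods = [t.method for t in tables]
    if len(set(methods)) != len(methods):
        methods = [f"{t.method}_{i}" for i, t in enumerate(tables)]
    ranks = pd.DataFrame(
        {f"rank_{m}": t.ranks.reindex(genes) for m, t in zip(methods, tables)}
    )
    geomean = np.exp(np.log(ranks).mean(axis=1))
    best_single = ranks.min(axis=1)
    order = sorted(
        genes,
        key=lambda g: (geomean[g], best_single[g], genes.index(g)),
    )
    position = pd.Series(
        {g: i + 1 for i, g in enumerate(order)}, name="position"
    ).reindex(genes)
    table = ranks.assign(geomean_rank=geomean, position=position)
    return ComprehensiveRanking(table=table, methods=methods)


def consensus_top(
    rankings: Sequence[StabilityTable | ComprehensiveRanking], n: int
) -> set[str]:
    """Genes appearing in the top-n of every ranking."""
    if len(rankings) < 2:
        raise ValueError("consensus needs >= 2 rankings")
    tops = [set(r.top(n)) for r in rankings]
    return set.intersection(*tops)
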