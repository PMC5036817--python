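"""In-memory containers for replicate-level Cq panels and aggregated matrices.

A :class:`CqPanel` holds the raw quantification-cycle (Cq) values of a
gene-expression qPCR experiment: one value per (gene, sample, replicate)
reaction, with failed reactions (no amplification) stored as NaN.  A
:class:`ExpressionMatrix` is the replicate-aggregated gene x sample table
that the stability algorithms consume, on one of three scales: raw Cq,
log2 relative quantity, or linear relative quantity.

Gene and sample identifiers are kept in sorted (canonical) order so that a
panel is a pure function of its set of reactions, independent of file row
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["CqPanel", "ExpressionMatrix", "PanelError"]


class PanelError(ValueError):
    """Raised when a panel or matrix violates its structural invariants."""


@dataclass
class CqPanel:
    """Replicate-level Cq values for a gene panel.

    Parameters
    ----------
    genes, samples
        Unique identifiers, stored sorted.
    groups
        Map sample -> group label (e.g. ``"control"`` / ``"infected"``);
        every sample has exactly one label.
    values
        Array of shape ``(n_genes, n_samples, n_replicates)``; NaN marks a
        reaction that did not amplify.  Non-missing entries must be finite
        and strictly positive (a Cq is a cycle number, typically 10-40).
    """

    genes: list[str]
    samples: list[str]
    groups: dict[str, str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise PanelError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise PanelError("duplicate sample identifiers")
        if self.values.ndim != 3:
            raise PanelError("values must be (gene, sample, replicate) 3-D")
        ng, ns, _ = self.values.shape
        if ng != len(self.genes) or ns != len(self.samples):
            raise PanelError("values shape does not match gene/sample lists")
        missing_groups = set(self.samples) - set(self.groups)
        if missing_groups:
            raise PanelError(f"samples without group label: {sorted(missing_groups)}")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (not np.all(np.isfinite(finite)) or np.any(finite <= 0)):
            raise PanelError("non-missing Cq values must be finite and > 0")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    @property
    def n_reactions(self) -> int:
        return self.values.size

    @property
    def n_missing(self) -> int:
        """Replicate-level count of reactions with no amplification."""
        return int(np.isnan(self.values).sum())

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(gene) from None

    def subset_samples(self, samples: list[str]) -> "CqPanel":
        """Panel restricted to ``samples`` (canonical order preserved)."""
        keep = [s for s in self.samples if s in set(samples)]
        unknown = set(samples) - set(self.samples)
        if unknown:
            raise PanelError(f"unknown samples: {sorted(unknown)}")
        idx = [self.samples.index(s) for s in keep]
        return CqPanel(
            genes=list(self.genes),
            samples=keep,
            groups={s: self.groups[s] for s in keep},
            values=self.values[:, idx, :].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CqPanel):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.samples == other.samples
            and self.groups == other.groups
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


SCALES = ("cq", "log2rq", "rq")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression table with per-sample group labels.

    ``data`` is a DataFrame indexed by gene with sample columns; ``scale``
    records what the numbers mean (``"cq"`` cycles, ``"log2rq"`` log2
    relative quantity, ``"rq"`` linear relative quantity).  A matrix may
    carry NaN cells only on the ``cq`` scale, before QC filtering.
    """

    data: pd.DataFrame
    groups: dict[str, str]
    scale: str = "cq"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise PanelError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        missing = set(self.data.columns) - set(self.groups)
        if missing:
            raise PanelError(f"samples without group label: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def is_complete(self) -> bool:
        return not self.data.isna().any().any()

    def group_of(self, sample: str) -> str:
        return self.groups[sample]

    def group_labels(self) -> list[str]:
        """Distinct group labels in order of first appearance over samples."""
        seen: list[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        unknown = set(genes) - set(self.data.index)
        if unknown:
            raise PanelError(f"unknown genes: {sorted(unknown)}")
        return ExpressionMatrix(self.data.loc[list(genes)].copy(), dict(self.groups), self.scale)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        unknown = set(samples) - set(self.data.columns)
        if unknown:
            raise PanelError(f"unknown samples: {sorted(unknown)}")
        keep = [s for s in self.samples if s in set(samples)]
        return ExpressionMatrix(
            self.data[keep].copy(), {s: self.groups[s] for s in keep}, self.scale
        )


def groups_from_mapping(samples: list[str], groups: Mapping[str, str]) -> dict[str, str]:
    """Validate and normalise a sample -> group mapping for ``samples``."""
    out = {}
    for s in samples:
        if s not in groups:
            raise PanelError(f"sample {s!r} has no group label")
        out[s] = str(groups[s])
    return out
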