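"""Synthetic Cq panels with known ground truth.

The generator produces replicate-level Cq values under the additive
log2-scale model

    Cq(g, s, r) = B_g + L_s + Delta_g * [group(s) = test] + eps_gs + tau_gsr

with per-gene baseline B_g (cycles), per-sample loading offset
L_s ~ N(0, loading_sd) (shared by all genes in a sample, mimicking
differences in cDNA input), per-gene biological noise
eps_gs ~ N(0, sigma_g), a group shift Delta_g for regulated genes
(negative Delta = higher expression in the test group, since each PCR
cycle is a doubling), and technical replicate noise tau_gsr.  Replicate
dropout (no amplification) is planted deterministically for a chosen
seed, by default concentrated in the lowest-expressed (highest-Cq) genes
to mimic detection-limit censoring.

:func:`study_scenario` builds the fixed panel that mirrors the infection
study's bookkeeping: 112 assays x 47 mice (23 control + 24 infected) x 3
replicates = 15792 reactions, of which exactly 1516 fail, spread over
exactly 41 genes so that 71 complete genes survive QC.  It embeds a
designed-stable block (including Il2rg and Itgb2), six classical
reference-gene candidates of mixed quality, and the infection-induced
targets Cxcl10, Ifng and Tnf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import CqPanel

__all__ = [
    "GeneDesign",
    "DropoutSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate",
    "study_scenario",
    "study_config",
]

DEFAULT_STUDY_SEED = 163219


@dataclass(frozen=True)
class GeneDesign:
    """Ground-truth parameters of one simulated assay."""

    name: str
    baseline: float  # mean Cq in the reference group
    sigma: float  # biological noise sd (cycles)
    delta: float = 0.0  # Cq shift in the test group (cycles)
    category: str = "other"  # stable | unstable | regulated | other

    @property
    def designed_instability(self) -> float:
        """|Delta|/2 + sigma: the planted scale of group bias + scatter."""
        return abs(self.delta) / 2.0 + self.sigma


@dataclass(frozen=True)
class DropoutSpec:
    """Where and how many replicate reactions fail to amplify."""

    n_genes: int  # number of affected genes
    total_missing: int  # replicate-level reactions knocked out in total
    genes: tuple[str, ...] | None = None  # explicit affected genes (overrides n_genes)
    placement: str = "low_expression"  # or "random"
    ensure_full_cell: bool = True  # >= 1 gene x sample cell fully missing per gene


@dataclass(frozen=True)
class SimulationConfig:
    """Panel dimensions, noise levels and effect sizes for one simulation.

    Per-gene parameters are either drawn from the configured ranges
    (``n_stable`` genes with low noise and no group shift, ``n_regulated``
    with a planted shift, ``n_unstable`` with high noise) or supplied
    explicitly via ``gene_designs``.
    """

    n_stable: int = 5
    n_unstable: int = 10
    n_regulated: int = 3
    n_other: int = 0
    n_per_group: tuple[int, ...] = (23, 24)
    group_labels: tuple[str, ...] = ("control", "infected")
    n_replicates: int = 3
    baseline_range: tuple[float, float] = (18.0, 32.0)
    stable_sigma_range: tuple[float, float] = (0.1, 0.25)
    unstable_sigma_range: tuple[float, float] = (0.5, 2.0)
    other_sigma_range: tuple[float, float] = (0.25, 0.5)
    regulated_sigma_range: tuple[float, float] = (0.3, 0.6)
    regulated_delta_range: tuple[float, float] = (-3.0, -1.5)
    loading_sd: float = 0.5
    technical_sd: float = 0.1
    dropout: DropoutSpec | None = None
    seed: int = 0
    gene_designs: tuple[GeneDesign, ...] | None = None

    @property
    def n_genes(self) -> int:
        if self.gene_designs is not None:
            return len(self.gene_designs)
        return self.n_stable + self.n_unstable + self.n_regulated + self.n_other


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the noise-free panel and the
    planted dropout pattern."""

    designs: dict[str, GeneDesign]
    loading: dict[str, float]  # sample -> L_s
    groups: dict[str, str]
    dropout_cells: dict[str, list[tuple[str, int]]]  # gene -> (sample, 1-based rep)
    seed: int = 0

    def expected_cq(self, gene: str, sample: str, test_label: str) -> float:
        d = self.designs[gene]
        shift = d.delta if self.groups[sample] == test_label else 0.0
        return d.baseline + self.loading[sample] + shift

    def genes_in(self, category: str) -> list[str]:
        return [g for g, d in self.designs.items() if d.category == category]


def _draw_designs(config: SimulationConfig, rng: np.random.Generator) -> list[GeneDesign]:
    designs: list[GeneDesign] = []
    blocks = (
        ("stable", config.n_stable, config.stable_sigma_range, None),
        ("unstable", config.n_unstable, config.unstable_sigma_range, None),
        ("regulated", config.n_regulated, config.regulated_sigma_range,
         config.regulated_delta_range),
        ("other", config.n_other, config.other_sigma_range, None),
    )
    counter = 0
    for category, count, sigma_range, delta_range in blocks:
        for _ in range(count):
            counter += 1
            designs.append(
                GeneDesign(
                    name=f"Gene{counter:03d}",
                    baseline=float(rng.uniform(*config.baseline_range)),
                    sigma=float(rng.uniform(*sigma_range)),
                    delta=float(rng.uniform(*delta_range)) if delta_range else 0.0,
                    category=category,
                )
            )
    return designs


def _resolve_dropout(
    spec: DropoutSpec,
    designs: list[GeneDesign],
    n_cells: int,
    n_replicates: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Affected gene -> number of missing replicate reactions."""
    if spec.genes is not None:
        affected = list(spec.genes)
        known = {d.name for d in designs}
        unknown = [g for g in affected if g not in known]
        if unknown:
            raise ValueError(f"dropout genes not in panel: {unknown}")
    elif spec.placement == "low_expression":
        by_cq = sorted(designs, key=lambda d: -d.baseline)
        affected = [d.name for d in by_cq[: spec.n_genes]]
    else:
        affected = list(rng.choice([d.name for d in designs], spec.n_genes, replace=False))
    m = len(affected)
    if m == 0 or spec.total_missing < m:
        raise ValueError("dropout spec must place >= 1 reaction in each affected gene")
    base, rem = divmod(spec.total_missing, m)
    counts = {g: base + (1 if i < rem else 0) for i, g in enumerate(affected)}
    per_gene_max = n_cells * n_replicates
    for g, c in counts.items():
        if c > per_gene_max:
            raise ValueError(f"dropout count {c} for {g} exceeds {per_gene_max} reactions")
        if spec.ensure_full_cell and c < n_replicates:
            raise ValueError(
                f"dropout count {c} for {g} cannot contain a fully-missing cell"
            )
    return counts


def generate(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CqPanel, GroundTruth]:
    """Simulate a replicate-level Cq panel; identical config + seed gives
    an identical panel."""
    used_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    if len(config.n_per_group) != len(config.group_labels):
        raise ValueError("n_per_group and group_labels lengths differ")
    if config.loading_sd < 0 or config.technical_sd < 0:
        raise ValueError("standard deviations must be >= 0")

    if config.gene_designs is not None:
        designs = list(config.gene_designs)
    else:
        designs = _draw_designs(config, rng)
    designs = sorted(designs, key=lambda d: d.name)  # canonical panel order
    if len({d.name for d in designs}) != len(designs):
        raise ValueError("duplicate gene names in design")

    samples: list[str] = []
    groups: dict[str, str] = {}
    for label, n in zip(config.group_labels, config.n_per_group):
        for i in range(n):
            s = f"{label}_{i + 1:02d}"
            samples.append(s)
            groups[s] = label
    samples = sorted(samples)
    test_label = config.group_labels[-1]

    G, S, R = len(designs), len(samples), config.n_replicates
    loading = rng.normal(0.0, config.loading_sd, S) if config.loading_sd else np.zeros(S)
    baseline = np.array([d.baseline for d in designs])
    sigma = np.array([d.sigma for d in designs])
    delta = np.array([d.delta for d in designs])
    is_test = np.array([groups[s] == test_label for s in samples], dtype=float)

    bio = rng.normal(0.0, 1.0, (G, S)) * sigma[:, None]
    tech = rng.normal(0.0, config.technical_sd, (G, S, R)) if config.technical_sd else 0.0
    cq = (
        baseline[:, None]
        + loading[None, :]
        + delta[:, None] * is_test[None, :]
        + bio
    )[:, :, None] + tech
    cq = np.maximum(cq, 1.0)  # Cq must stay positive even in extreme draws

    dropout_cells: dict[str, list[tuple[str, int]]] = {}
    if config.dropout is not None:
        counts = _resolve_dropout(config.dropout, designs, S, R, rng)
        name_to_idx = {d.name: i for i, d in enumerate(designs)}
        for gene, count in counts.items():
            gi = name_to_idx[gene]
            if config.dropout.placement == "random":
                cell_order = rng.permutation(S)
            else:  # highest-Cq cells fail first (detection limit)
                cell_order = np.argsort(-cq[gi].mean(axis=1), kind="stable")
            full, part = divmod(count, R)
            cells: list[tuple[str, int]] = []
            for ci in cell_order[:full]:
                cq[gi, ci, :] = np.nan
                cells.extend((samples[ci], r + 1) for r in range(R))
            if part:
                ci = cell_order[full]
                cq[gi, ci, :part] = np.nan
                cells.extend((samples[ci], r + 1) for r in range(part))
            dropout_cells[gene] = cells

    panel = CqPanel(
        genes=[d.name for d in designs], samples=samples, groups=groups, values=cq
    )
    truth = GroundTruth(
        designs={d.name: d for d in designs},
        loading={s: float(l) for s, l in zip(samples, loading)},
        groups=groups,
        dropout_cells=dropout_cells,
        seed=used_seed,
    )
    return panel, truth


# ----------------------------------------------------------------------
# fixed study-scale scenario


def _study_designs(rng: np.random.Generator) -> list[GeneDesign]:
    designs: list[GeneDesign] = []

    stable = [  # designed-stable block: low noise, no group shift
        ("Il2rg", 0.12), ("Itgb2", 0.13), ("Myd88", 0.15), ("Stat6", 0.16),
        ("Il10ra", 0.18), ("Il10rb", 0.19), ("Il6st", 0.20), ("Tgfbr1", 0.21),
        ("Stat4", 0.22), ("Hprt", 0.24),
    ]
    for name, s in stable:
        designs.append(GeneDesign(name, float(rng.uniform(21, 26)), s, 0.0, "stable"))

    classical = [  # classical RG candidates of mixed, mostly poor, stability
        ("Ubc", 0.80, 0.4), ("B2m", 0.90, -0.5), ("Polr2a", 0.70, 0.3),
        ("Tbp", 0.75, -0.3), ("Pgk1", 0.45, 0.0),
    ]
    for name, s, d in classical:
        designs.append(GeneDesign(name, float(rng.uniform(20, 27)), s, d, "unstable"))

    targets = [  # infection-induced cytokines: strong negative Cq shift
        ("Cxcl10", 0.50, -2.8), ("Ifng", 0.60, -2.2), ("Tnf", 0.50, -1.8),
    ]
    for name, s, d in targets:
        designs.append(GeneDesign(name, float(rng.uniform(22, 27)), s, d, "regulated"))

    # 94 immune-panel fillers; the last 41 sit at the highest baselines and
    # will carry the planted dropout
    for i in range(1, 54):
        designs.append(
            GeneDesign(
                f"Gene{i:03d}",
                float(rng.uniform(18, 28)),
                float(rng.uniform(0.25, 1.5)),
                float(rng.uniform(-1.0, 1.0)) if i % 2 else 0.0,
                "other",
            )
        )
    for i in range(54, 95):
        designs.append(
            GeneDesign(
                f"Gene{i:03d}",
                float(rng.uniform(29, 33)),
                float(rng.uniform(0.4, 1.5)),
                float(rng.uniform(-1.0, 1.0)) if i % 2 else 0.0,
                "other",
            )
        )
    return designs


def study_config(seed: int = DEFAULT_STUDY_SEED) -> SimulationConfig:
    """Configuration of the fixed study-scale panel (112 x 47 x 3)."""
    rng = np.random.default_rng(seed)
    designs = _study_designs(rng)
    dropout_genes = tuple(f"Gene{i:03d}" for i in range(54, 95))
    return SimulationConfig(
        n_per_group=(23, 24),
        group_labels=("control", "infected"),
        n_replicates=3,
        loading_sd=0.5,
        technical_sd=0.1,
        dropout=DropoutSpec(
            n_genes=41, total_missing=1516, genes=dropout_genes,
            placement="low_expression",
        ),
        seed=seed,
        gene_designs=tuple(designs),
    )


def study_scenario(
    seed: int = DEFAULT_STUDY_SEED, *, return_truth: bool = False
) -> CqPanel | tuple[CqPanel, GroundTruth]:
    """The deterministic study-scale fixture (see module docstring)."""
    config = study_config(seed)
    panel, truth = generate(config)
    if return_truth:
        return panel, truth
    return panel
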