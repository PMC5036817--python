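"""Optional diagnostic plots (requires matplotlib; never imported by the
core pipeline unless plotting is requested)."""

from __future__ import annotations

from pathlib import Path

from .evaluate import NrqReport
from .genorm import GeNormResult

__all__ = ["plot_m_values", "plot_v_curve", "plot_nrq"]


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_m_values(result: GeNormResult, path: str | Path, *, top: int | None = None) -> None:
    """Bar chart of per-gene geNorm M values (most stable first) with the
    acceptability threshold line."""
    plt = _pyplot()
    genes = result.ranking[: top or len(result.ranking)]
    values = [result.final_m[g] for g in genes]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(genes)), 3.5))
    ax.bar(range(len(genes)), values, color="0.6")
    ax.axhline(result.m_threshold, color="k", lw=1, ls="--",
               label=f"M = {result.m_threshold}")
    ax.set_xticks(range(len(genes)), genes, rotation=90, fontsize=7)
    ax.set_ylabel("geNorm M value")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_v_curve(result: GeNormResult, path: str | Path) -> None:
    """Pairwise-variation V(n/n+1) against n, with the 0.15 threshold."""
    plt = _pyplot()
    ns = sorted(result.v_curve)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(ns, [result.v_curve[n] for n in ns], "o-", color="0.3")
    ax.axhline(result.v_threshold, color="k", lw=1, ls="--",
               label=f"V = {result.v_threshold}")
    ax.set_xlabel("n (reference genes in the normalization factor)")
    ax.set_ylabel("V(n/n+1)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_nrq(report: NrqReport, path: str | Path) -> None:
    """Per-target NRQ distributions split by group, with significance."""
    plt = _pyplot()
    labels: list[str] = []
    for s in report.nrq.columns:
        g = report.groups[s]
        if g not in labels:
            labels.append(g)
    fig, axes = plt.subplots(
        1, len(report.targets), figsize=(2.2 * len(report.targets), 3.2),
        squeeze=False,
    )
    for ax, target in zip(axes[0], report.targets):
        data = [
            report.nrq.loc[
                target, [s for s in report.nrq.columns if report.groups[s] == g]
            ].to_numpy()
            for g in labels
        ]
        ax.boxplot(data, tick_labels=labels)
        title = target
        if report.comparisons is not None and target in report.comparisons.index:
            title += f" ({report.comparisons.loc[target, 'significance']})"
        ax.set_title(title, fontsize=9)
        ax.set_ylabel("NRQ")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
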