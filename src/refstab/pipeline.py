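"""Full-analysis orchestration: QC -> per-cohort stability -> aggregation
-> consensus -> reference-set evaluation, with reproducible artifacts."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cq_io import read_cq_long, write_report
from .evaluate import compare_groups, normalize
from .expression import EfficiencyModel, to_log2_rq
from .genorm import M_THRESHOLD_DEFAULT, V_THRESHOLD_DEFAULT, rank_genorm
from .normfinder import normfinder
from .panel import CqPanel, PanelError
from .qc import run_qc
from .reffinder import aggregate, consensus_top
from .simple import bestkeeper, delta_ct

__all__ = ["RunConfig", "run_full"]

log = logging.getLogger("refstab")


@dataclass
class RunConfig:
    """Everything a full run needs; hashable for the manifest."""

    input_path: str | None = None  # long CSV; None = synthetic study panel
    output_dir: str = "refstab_run"
    cohorts: dict[str, list[str] | None] = field(
        default_factory=lambda: {"control": ["control"], "infected": ["infected"],
                                 "combined": None}  # None = all groups
    )
    qc_mode: str = "cell"
    efficiency_base: float = 2.0
    anchor: str = "mean"
    m_threshold: float = M_THRESHOLD_DEFAULT
    v_threshold: float = V_THRESHOLD_DEFAULT
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    rg_sets: list[list[str]] = field(default_factory=list)
    eval_targets: list[str] = field(default_factory=list)
    consensus_top_n: int = 10
    genorm_tie_average: bool = False
    normfinder_use_groups: bool = True
    make_plots: bool = False  # PNG diagnostics; needs matplotlib
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            k: v for k, v in self.__dict__.items()
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cohort_panel(panel: CqPanel, labels: list[str] | None) -> CqPanel:
    if labels is None:
        return panel
    known = set(panel.groups.values())
    missing = [l for l in labels if l not in known]
    if missing:
        raise PanelError(f"cohort labels absent from metadata: {missing}")
    samples = [s for s in panel.samples if panel.groups[s] in set(labels)]
    return panel.subset_samples(samples)


def run_full(config: RunConfig, panel: CqPanel | None = None) -> Path:
    """Run the whole analysis; returns the run directory.

    For each cohort: QC report, the four stability tables, the geNorm
    trace, the comprehensive ranking, and the top-n consensus across
    {geNorm, NormFinder, comprehensive}.  Then one evaluation report per
    configured reference set on the full two-group data.  A manifest
    records version, config hash and seed; outputs are pure functions of
    (input, config, seed).
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if panel is None:
        if config.input_path is None:
            from .synthetic import study_scenario

            panel = study_scenario(seed=config.seed)
        else:
            panel = read_cq_long(config.input_path)
    # validate cohorts before any computation
    for labels in config.cohorts.values():
        if labels is not None:
            _cohort_panel(panel, labels)
    log.info(
        "input: %d genes x %d samples x %d replicates",
        panel.n_genes, panel.n_samples, panel.n_replicates,
    )

    eff = EfficiencyModel(config.efficiency_base)
    steps: list[dict] = []
    for cohort, labels in config.cohorts.items():
        sub = _cohort_panel(panel, labels)
        cdir = out / cohort
        cdir.mkdir(exist_ok=True)
        stage = f"cohort {cohort!r}"
        try:
            cq, qc_report = run_qc(sub, mode=config.qc_mode)
            write_report(qc_report, cdir / "qc_report.json")
            log2rq = to_log2_rq(cq, eff, anchor=config.anchor)

            gn = rank_genorm(
                log2rq, m_threshold=config.m_threshold, v_threshold=config.v_threshold
            )
            nf = normfinder(log2rq, use_groups=config.normfinder_use_groups
                            and len(set(sub.groups.values())) > 1)
            bk = bestkeeper(cq)
            dc = delta_ct(cq)

            tables = [
                gn.stability_table(tie_average_final_pair=config.genorm_tie_average),
                nf.stability_table(),
                bk.stability_table(),
                dc.stability_table(),
            ]
            comp = aggregate(tables)
            for t in tables:
                write_report(t, cdir / f"stability_{t.method}.tsv")
            write_report(gn, cdir / "genorm_detail.json")
            if config.make_plots:
                from .plots import plot_m_values, plot_v_curve

                plot_m_values(gn, cdir / "genorm_m.png", top=30)
                plot_v_curve(gn, cdir / "genorm_v.png")
            write_report(nf, cdir / "normfinder_detail.json")
            write_report(comp, cdir / "comprehensive.tsv")
            n_top = min(config.consensus_top_n, len(comp.table))
            consensus = consensus_top([tables[0], tables[1], comp.stability_table()],
                                      n_top)
            write_report(
                {"top_n": n_top, "methods": ["genorm", "normfinder", "comprehensive"],
                 "genes": sorted(consensus)},
                cdir / "consensus.json",
            )
            steps.append(
                {"stage": cohort, "n_genes_retained": qc_report.n_genes_retained,
                 "n_samples": sub.n_samples, "recommended_n": gn.recommended_n,
                 "consensus": sorted(consensus)}
            )
            log.info("%s: %d genes retained, consensus %s", stage,
                     qc_report.n_genes_retained, sorted(consensus))
        except Exception as exc:
            raise RuntimeError(f"failed at {stage}: {exc}") from exc

    if config.rg_sets:
        cq, _ = run_qc(panel, mode=config.qc_mode)
        log2rq = to_log2_rq(cq, eff, anchor=config.anchor)
        for rg_set in config.rg_sets:
            stage = f"evaluation with RG set {rg_set}"
            try:
                report = normalize(log2rq, rg_set, config.eval_targets or None)
                report = compare_groups(report, alpha_levels=config.alpha_levels)
                name = "_".join(rg_set)
                write_report(report, out / f"evaluation_{name}.json")
                write_report(
                    report.comparisons.reset_index(), out / f"comparison_{name}.tsv"
                )
                if config.make_plots:
                    from .plots import plot_nrq

                    plot_nrq(report, out / f"nrq_{name}.png")
                steps.append({"stage": stage,
                              "p_values": report.comparisons["p_value"].to_dict()})
            except Exception as exc:
                raise RuntimeError(f"failed at {stage}: {exc}") from exc

    manifest = {
        "software": "refstab",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 3),
        "steps": steps,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return out
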