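"""The synthetic panel generator and the fixed study-scale fixture."""

import numpy as np
import pytest

from refstab import (
    DropoutSpec,
    GeneDesign,
    SimulationConfig,
    generate,
    run_qc,
    study_scenario,
)


class TestGenerate:
    def test_same_seed_identical_panels(self):
        cfg = SimulationConfig(seed=42, dropout=DropoutSpec(n_genes=2, total_missing=9))
        a, _ = generate(cfg)
        b, _ = generate(cfg)
        assert a == b

    def test_different_seed_differs(self):
        cfg = SimulationConfig(seed=42)
        a, _ = generate(cfg)
        b, _ = generate(cfg, seed=43)
        assert not np.array_equal(a.values, b.values)

    def test_noise_free_limit_matches_ground_truth(self):
        cfg = SimulationConfig(
            n_stable=2, n_unstable=1, n_regulated=1, n_per_group=(3, 3),
            loading_sd=0.0, technical_sd=0.0,
            stable_sigma_range=(0.0, 0.0), unstable_sigma_range=(0.0, 0.0),
            regulated_sigma_range=(0.0, 0.0), seed=5,
        )
        panel, truth = generate(cfg)
        for gi, g in enumerate(panel.genes):
            for si, s in enumerate(panel.samples):
                expected = truth.expected_cq(g, s, "infected")
                np.testing.assert_allclose(panel.values[gi, si, :], expected)

    def test_noise_free_limit_degenerate_stability(self):
        cfg = SimulationConfig(
            n_stable=3, n_unstable=2, n_regulated=0, n_per_group=(4, 4),
            loading_sd=0.0, technical_sd=0.0,
            stable_sigma_range=(0.0, 0.0), unstable_sigma_range=(0.0, 0.0),
            seed=5,
        )
        panel, _ = generate(cfg)
        # every gene constant across samples
        assert np.ptp(panel.values, axis=(1, 2)).max() == 0.0

    def test_dropout_counts_exact_and_full_cell_guaranteed(self):
        cfg = SimulationConfig(
            n_stable=4, n_unstable=4, n_regulated=0, n_per_group=(5, 5),
            n_replicates=3, dropout=DropoutSpec(n_genes=3, total_missing=20),
            seed=11,
        )
        panel, truth = generate(cfg)
        assert panel.n_missing == 20
        assert len(truth.dropout_cells) == 3
        for gene, cells in truth.dropout_cells.items():
            gi = panel.gene_index(gene)
            assert int(np.isnan(panel.values[gi]).sum()) == len(cells)
            assert np.isnan(panel.values[gi]).all(axis=1).any()  # >=1 full cell

    def test_low_expression_placement_targets_high_cq_genes(self):
        cfg = SimulationConfig(
            n_stable=3, n_unstable=3, n_regulated=0, n_per_group=(4, 4),
            dropout=DropoutSpec(n_genes=2, total_missing=8,
                                placement="low_expression"),
            seed=2,
        )
        panel, truth = generate(cfg)
        baselines = {g: truth.designs[g].baseline for g in panel.genes}
        affected = set(truth.dropout_cells)
        top2 = sorted(baselines, key=baselines.get, reverse=True)[:2]
        assert affected == set(top2)

    def test_infeasible_dropout_rejected(self):
        cfg = SimulationConfig(
            n_stable=3, n_unstable=0, n_regulated=0, n_per_group=(2, 2),
            n_replicates=3,
            dropout=DropoutSpec(n_genes=1, total_missing=2),  # < one full cell
        )
        with pytest.raises(ValueError, match="fully-missing"):
            generate(cfg)
        cfg2 = SimulationConfig(
            n_stable=1, n_unstable=0, n_regulated=0, n_per_group=(2, 2),
            n_replicates=3, dropout=DropoutSpec(n_genes=1, total_missing=100),
        )
        with pytest.raises(ValueError, match="exceeds"):
            generate(cfg2)

    def test_explicit_designs_and_regulated_shift(self):
        designs = (
            GeneDesign("Ref", 22.0, 0.0, 0.0, "stable"),
            GeneDesign("Up", 25.0, 0.0, -2.0, "regulated"),
            GeneDesign("Flat", 28.0, 0.0, 0.0, "other"),
        )
        cfg = SimulationConfig(
            gene_designs=designs, n_per_group=(3, 3),
            loading_sd=0.0, technical_sd=0.0, seed=1,
        )
        panel, truth = generate(cfg)
        gi = panel.gene_index("Up")
        infected = [j for j, s in enumerate(panel.samples)
                    if panel.groups[s] == "infected"]
        control = [j for j, s in enumerate(panel.samples)
                   if panel.groups[s] == "control"]
        assert panel.values[gi, infected].mean() == pytest.approx(23.0)
        assert panel.values[gi, control].mean() == pytest.approx(25.0)
        assert truth.genes_in("regulated") == ["Up"]


class TestStudyScenario:
    def test_dimensions_and_bookkeeping(self, study_panel):
        assert study_panel.n_genes == 112
        assert study_panel.n_samples == 47
        assert study_panel.n_replicates == 3
        assert study_panel.n_reactions == 15792
        assert study_panel.n_missing == 1516
        groups = list(study_panel.groups.values())
        assert groups.count("control") == 23 and groups.count("infected") == 24

    def test_qc_retains_71_of_112(self, study_panel):
        matrix, report = run_qc(study_panel)
        assert report.n_genes_input == 112
        assert report.n_genes_excluded == 41
        assert report.n_genes_retained == 71
        assert report.fraction_missing < 0.10
        assert matrix.is_complete

    def test_named_genes_survive_qc(self, study_panel):
        matrix, _ = run_qc(study_panel)
        for g in ("Il2rg", "Itgb2", "Hprt", "Polr2a", "Tbp",
                  "Cxcl10", "Ifng", "Tnf"):
            assert g in matrix.genes

    def test_deterministic(self, study_panel):
        assert study_scenario() == study_panel
        assert not np.array_equal(
            study_scenario(seed=1).values, study_panel.values, equal_nan=True
        )

    def test_structural_counts_hold_for_any_seed(self):
        panel = study_scenario(seed=777)
        _, report = run_qc(panel)
        assert panel.n_missing == 1516
        assert report.n_genes_retained == 71
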