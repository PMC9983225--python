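"""Synthetic-cohort generator: determinism, planted-effect fidelity,
ground-truth containment and configuration validation."""

import numpy as np
import pandas as pd
import pytest

import dmrcascade as dc
from dmrcascade.annotate import promoter_window
from dmrcascade.simulate import GenerationError, build_sample_sheet


class TestConfigValidation:
    def test_dispersion_bounds(self):
        with pytest.raises(ValueError):
            dc.SimConfig(dispersion=0.0)
        with pytest.raises(ValueError):
            dc.SimConfig(dispersion=1.0)

    def test_pairs_cannot_exceed_group(self):
        with pytest.raises(ValueError):
            dc.SimConfig(n_group_a=2, n_pairs_a=3)

    def test_planted_effect_must_be_nonzero(self):
        with pytest.raises(ValueError):
            dc.PlantedDMR("chr1", 0, 100, effect_size=0.0)

    def test_invalid_contrast_token(self):
        with pytest.raises(ValueError):
            dc.PlantedDMR("chr1", 0, 100, effect_size=0.3, contrast=("bogus",))


class TestGeneModels:
    def test_zero_genes_gives_empty_list(self):
        assert dc.simulate_gene_models(dc.SimConfig(n_genes=0)) == []

    def test_deterministic_under_seed(self):
        cfg = dc.SimConfig(seed=7)
        assert dc.simulate_gene_models(cfg) == dc.simulate_gene_models(cfg)

    def test_transcripts_do_not_overlap(self):
        genes = dc.simulate_gene_models(dc.SimConfig(seed=2))
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.tx_start)
            for g1, g2 in zip(gs[:-1], gs[1:]):
                assert g1.tx_end <= g2.tx_start

    def test_minus_strand_promoter_lies_above_tss(self):
        genes = dc.simulate_gene_models(dc.SimConfig(seed=2))
        minus = [g for g in genes if g.strand == "-"]
        assert minus
        for g in minus:
            w = promoter_window(g)
            # upstream 2200 bp sit at coordinates above the TSS
            assert w.end == g.tss + 2201

    def test_too_many_genes_is_configuration_error(self):
        with pytest.raises(GenerationError, match="do not fit"):
            dc.simulate_gene_models(
                dc.SimConfig(n_genes=500, chrom_length=100_000, n_chromosomes=1)
            )


class TestMethylationCohort:
    def test_fixed_seed_gives_identical_counts(self):
        cfg = dc.SimConfig(seed=5, n_cpgs=2_000, n_genes=20, n_group_b=5)
        genes = dc.simulate_gene_models(cfg)
        m1, t1 = dc.simulate_methylation_cohort(cfg, genes)
        m2, t2 = dc.simulate_methylation_cohort(cfg, genes)
        assert np.array_equal(m1.meth, m2.meth)
        assert np.array_equal(m1.total, m2.total)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_cohort_has_small_group_differences(self):
        cfg = dc.SimConfig(
            seed=3,
            n_cpgs=3_000,
            n_genes=20,
            n_group_a=10,
            n_group_b=10,
            n_pairs_a=0,
            n_pairs_b=0,
            include_cell_lines=False,
        )
        genes = dc.simulate_gene_models(cfg)
        matrix, _ = dc.simulate_methylation_cohort(cfg, genes)
        beta = matrix.levels(min_coverage=5)
        grp = matrix.samples["group"].to_numpy()
        d = np.nanmean(beta[:, grp == "t821"], axis=1) - np.nanmean(
            beta[:, grp == "non_t821"], axis=1
        )
        assert np.nanmean(np.abs(d)) < 0.06
        assert np.nanmean(np.abs(d) > 0.15) < 0.01

    def test_planted_hyper_effect_recovered_in_group_means(self):
        cfg = dc.SimConfig(
            seed=4,
            n_chromosomes=1,
            n_cpgs=2_000,
            chrom_length=500_000,
            n_genes=10,
            n_group_a=10,
            n_group_b=10,
            n_pairs_a=0,
            n_pairs_b=0,
            include_cell_lines=False,
            planted_dmrs=(
                dc.PlantedDMR("chr1", 200_000, 203_000, effect_size=+0.4),
            ),
        )
        genes = dc.simulate_gene_models(cfg)
        matrix, truth = dc.simulate_methylation_cohort(cfg, genes)
        beta = matrix.levels(min_coverage=5)
        grp = matrix.samples["group"].to_numpy()
        pos = matrix.sites["pos"].to_numpy()
        inside = (pos >= 200_000) & (pos < 203_000)
        d = np.nanmean(beta[inside][:, grp == "t821"], axis=1) - np.nanmean(
            beta[inside][:, grp == "non_t821"], axis=1
        )
        assert abs(float(np.mean(d)) - 0.4) <= 0.1

    def test_cr_samples_revert_treatment_effects(self):
        cfg = dc.SimConfig(
            seed=9,
            n_chromosomes=1,
            n_cpgs=2_000,
            chrom_length=500_000,
            n_genes=10,
            n_group_a=2,
            n_group_b=3,
            n_pairs_a=2,
            n_pairs_b=3,
            include_cell_lines=False,
            planted_dmrs=(
                dc.PlantedDMR(
                    "chr1", 150_000, 153_000, effect_size=+0.4,
                    contrast=("t821_treatment",),
                ),
            ),
        )
        genes = dc.simulate_gene_models(cfg)
        matrix, _ = dc.simulate_methylation_cohort(cfg, genes)
        beta = matrix.levels(min_coverage=5)
        pos = matrix.sites["pos"].to_numpy()
        inside = (pos >= 150_000) & (pos < 153_000)
        s = matrix.samples
        dn = matrix.columns(
            s.loc[(s.group == "t821") & (s.timepoint == "de_novo"), "sample_id"]
        )
        cr = matrix.columns(
            s.loc[(s.group == "t821") & (s.timepoint == "cr"), "sample_id"]
        )
        d = np.nanmean(beta[inside][:, dn], axis=1) - np.nanmean(
            beta[inside][:, cr], axis=1
        )
        assert abs(float(np.mean(d)) - 0.4) <= 0.1

    def test_every_planted_region_contains_required_cpgs(self, demo_cohort):
        truth = demo_cohort["truth"]
        cfg = demo_cohort["config"]
        required = {
            (r.chrom, r.start, r.end): r.n_cpgs for r in cfg.planted_dmrs
        }
        for t in truth.itertuples(index=False):
            assert t.n_cpgs >= required[(t.chrom, t.start, t.end)]

    def test_region_with_too_few_cpgs_is_generation_error(self):
        cfg = dc.SimConfig(
            seed=1,
            n_chromosomes=1,
            n_cpgs=500,
            chrom_length=500_000,
            n_genes=5,
            planted_dmrs=(
                dc.PlantedDMR("chr1", 400_000, 400_020, effect_size=0.3, n_cpgs=50),
            ),
        )
        genes = dc.simulate_gene_models(cfg)
        with pytest.raises(GenerationError, match="CpGs"):
            dc.simulate_methylation_cohort(cfg, genes)

    def test_linked_gene_must_exist_and_overlap_promoter(self):
        cfg = dc.SimConfig(
            seed=1,
            n_chromosomes=1,
            n_cpgs=500,
            chrom_length=500_000,
            n_genes=5,
            planted_dmrs=(
                dc.PlantedDMR(
                    "chr1", 1000, 4000, effect_size=0.3, linked_gene="nope"
                ),
            ),
        )
        genes = dc.simulate_gene_models(cfg)
        with pytest.raises(GenerationError, match="linked gene"):
            dc.simulate_methylation_cohort(cfg, genes)

    def test_sample_sheet_matches_study_shape(self):
        sheet = build_sample_sheet(dc.SimConfig())
        assert (sheet.timepoint == "de_novo").sum() == 28
        assert ((sheet.group == "t821") & (sheet.timepoint == "de_novo")).sum() == 3
        assert (sheet.timepoint == "cr").sum() == 5
        assert (sheet.group == "cellline").sum() == 2


class TestExpression:
    def test_deterministic_and_linked_genes_silenced(self, demo_cohort):
        cfg = demo_cohort["config"]
        genes = demo_cohort["genes"]
        truth = demo_cohort["truth"]
        e1 = dc.simulate_expression(cfg, genes, truth)
        e2 = dc.simulate_expression(cfg, genes, truth)
        pd.testing.assert_frame_equal(e1, e2)
        a, b = dc.expression_groups(cfg)
        linked = set(truth.loc[truth.linked_gene != "", "linked_gene"])
        gap = e1.loc[sorted(linked), a].mean(axis=1) - e1.loc[
            sorted(linked), b
        ].mean(axis=1)
        assert np.allclose(gap, cfg.linked_log2fc, atol=0.8)

    def test_no_linked_genes_controls_false_positives(self):
        """Mean fraction of genes called down under the null <= 0.07."""
        rates = []
        empty_truth = pd.DataFrame({"linked_gene": []})
        for seed in range(20):
            cfg = dc.SimConfig(seed=seed, n_genes=100, n_cpgs=1000)
            genes = dc.simulate_gene_models(cfg)
            expr = dc.simulate_expression(cfg, genes, empty_truth)
            a, b = dc.expression_groups(cfg)
            de = dc.differential_expression(expr, a, b)
            rates.append((de.status == "down").mean())
        assert float(np.mean(rates)) <= 0.07
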