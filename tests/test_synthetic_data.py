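"""Generator contracts: determinism, conservation, planted-effect calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from histodiff.bin_signal import BinGrid
from histodiff.motif_enrichment import PWM, scan_pwm
from histodiff.pipeline import DEMO_PWM_COUNTS
from histodiff.synthetic_data import (
    CONTROL,
    PlantedTruth,
    SyntheticConfig,
    make_genome,
    plant_truth,
    sample_motif_instance,
    simulate_bin_counts,
    simulate_chip_reads,
    simulate_expression,
    simulate_methylation,
    simulate_regulatory_sequences,
    substream,
)


class TestConfigValidation:
    def test_rejects_single_donor(self):
        with pytest.raises(ValueError, match="n_donors"):
            SyntheticConfig(n_donors=1)

    def test_rejects_unaligned_chromosome_length(self):
        with pytest.raises(ValueError, match="divisible"):
            SyntheticConfig(chrom_length=1001)

    def test_rejects_excessive_differential_fraction(self):
        with pytest.raises(ValueError, match="frac_differential"):
            SyntheticConfig(frac_differential_bins=0.5)


class TestMakeGenome:
    def test_zero_genes_gives_chromosomes_only(self):
        ann = make_genome(SyntheticConfig(n_genes=0, n_chroms=2, chrom_length=100_000))
        assert len(ann.chrom_sizes) == 2
        assert ann.genes.empty and ann.transcripts.empty

    def test_same_seed_reproduces_identical_annotation(self, tiny_config):
        a, b = make_genome(tiny_config), make_genome(tiny_config)
        assert a.sequences == b.sequences
        pd.testing.assert_frame_equal(a.transcripts, b.transcripts)
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_gene_coordinates_contained_in_chromosomes(self):
        cfg = SyntheticConfig(n_chroms=2, chrom_length=1_000_000, n_genes=40)
        ann = make_genome(cfg)
        for t in ann.transcripts.itertuples(index=False):
            assert 0 <= t.start < t.end <= ann.chrom_sizes[t.chrom]

    def test_too_many_genes_for_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            make_genome(SyntheticConfig(n_chroms=1, chrom_length=100_000, n_genes=50))

    def test_tss_spacing_respected(self, tiny_study):
        ann, _ = tiny_study
        tss = np.sort(ann.genes["tss"].to_numpy())
        assert (np.diff(tss) >= 8000).all()

    def test_longest_transcript_designated(self, tiny_study):
        ann, _ = tiny_study
        for gene, sub in ann.transcripts.groupby("gene"):
            spans = sub["end"] - sub["start"]
            assert sub.loc[spans.idxmax(), "is_longest"]


class TestPlantedTruth:
    def test_planted_bins_lie_on_grid(self, tiny_config, tiny_study):
        ann, truth = tiny_study
        n_bins = ann.grid(tiny_config.bin_width).n_bins()
        assert truth.differential_bins["bin"].between(0, n_bins - 1).all()
        assert set(truth.differential_bins["direction"]) <= {"increased", "decreased"}

    def test_zero_effect_size_empties_directional_ledger(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, planted_log2fc=0.0)
        truth = plant_truth(make_genome(cfg), cfg)
        assert truth.differential_bins.empty

    def test_expression_classes_consistent_with_promoter_marks(self, tiny_config, tiny_study):
        ann, truth = tiny_study
        grid = ann.grid(tiny_config.bin_width)
        genes = ann.genes.set_index("gene")
        diff = truth.differential_bins.set_index(["bin", "mark"])["direction"]
        for g in truth.regulated_genes.itertuples(index=False):
            tss_bin = int(grid.bin_index(genes.loc[g.gene, "chrom"], genes.loc[g.gene, "tss"]))
            expected = "increased" if g.expr_class == "up" else "decreased"
            assert diff.loc[(tss_bin, "H3K4me3")] == expected


class TestChipReads:
    def test_read_totals_conserved_exactly(self, tiny_config, tiny_study):
        ann, truth = tiny_study
        cfg = dataclasses.replace(tiny_config, marks=("H3K4me3",))
        counts = simulate_bin_counts(ann, truth, cfg)
        for sid, c in counts.items():
            assert c.sum() == cfg.reads_per_sample

    def test_same_seed_identical_reads(self, tiny_config, tiny_study):
        ann, truth = tiny_study
        cfg = dataclasses.replace(tiny_config, marks=("H3K4me3",), reads_per_sample=2000)
        a = simulate_chip_reads(ann, truth, cfg)
        b = simulate_chip_reads(ann, truth, cfg)
        for sid in a:
            pd.testing.assert_frame_equal(a[sid], b[sid])

    def test_zero_reads_flagged_not_dropped(self, tiny_config, tiny_study, caplog):
        ann, truth = tiny_study
        cfg = dataclasses.replace(tiny_config, marks=("H3K4me3",), reads_per_sample=0)
        import logging

        with caplog.at_level(logging.WARNING, logger="histodiff.synthetic_data"):
            counts = simulate_bin_counts(ann, truth, cfg)
        assert all(c.sum() == 0 for c in counts.values())
        assert len(counts) == cfg.n_donors * cfg.n_states * 2  # mark + control
        assert "reads_per_sample=0" in caplog.text

    def test_planted_ratio_matches_generative_parameter(self):
        """Monte-Carlo: a planted log2FC of 1 yields a mean state1/state0
        count ratio within 15% of 2 over 200 replicate simulations."""
        cfg = SyntheticConfig(
            n_chroms=1, chrom_length=200_000, n_genes=0, marks=("H3K4me3",),
            reads_per_sample=20_000, donor_effect_sd=0.0, n_donors=2,
        )
        ann = make_genome(cfg)
        bin_id = 100
        truth = PlantedTruth(
            pd.DataFrame({"bin": [bin_id], "mark": ["H3K4me3"], "direction": ["increased"]}),
            pd.DataFrame(columns=["gene", "expr_class", "log2fc"]),
        )
        ratios = []
        for rep in range(200):
            counts = simulate_bin_counts(ann, truth, cfg.with_seed(rep))
            s0 = counts[(0, 0, "H3K4me3")][bin_id]
            s1 = counts[(0, 1, "H3K4me3")][bin_id]
            ratios.append(s1 / s0)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)

    def test_control_carries_no_planted_signal(self):
        cfg = SyntheticConfig(
            n_chroms=1, chrom_length=500_000, n_genes=0, marks=("H3K4me3",),
            reads_per_sample=50_000, planted_log2fc=2.0, n_donors=2,
        )
        ann = make_genome(cfg)
        planted = np.arange(0, 100)
        truth = PlantedTruth(
            pd.DataFrame({"bin": planted, "mark": "H3K4me3", "direction": "increased"}),
            pd.DataFrame(columns=["gene", "expr_class", "log2fc"]),
        )
        counts = simulate_bin_counts(ann, truth, cfg)
        ctl_ratio = (
            counts[(0, 1, CONTROL)][planted].sum() / counts[(0, 0, CONTROL)][planted].sum()
        )
        chip_ratio = (
            counts[(0, 1, "H3K4me3")][planted].sum() / counts[(0, 0, "H3K4me3")][planted].sum()
        )
        assert ctl_ratio == pytest.approx(1.0, rel=0.1)
        assert chip_ratio > 2.5


class TestExpression:
    def test_zero_noise_reproduces_planted_fold_change(self, tiny_study, tiny_config):
        ann, truth = tiny_study
        cfg = dataclasses.replace(
            tiny_config, expression_noise_sd=0.0, expression_donor_sd=0.0
        )
        expr = simulate_expression(ann, truth, cfg)
        wide = expr.pivot_table(index="gene", columns=["state", "donor"], values="log2_value")
        fc = (wide[1] - wide[0]).mean(axis=1)
        planted = truth.regulated_genes.set_index("gene")["log2fc"]
        for gene, val in planted.items():
            assert fc[gene] == pytest.approx(val, abs=1e-9)
        unregulated = fc.index.difference(planted.index)
        assert np.allclose(fc[unregulated], 0.0)

    def test_unknown_regulated_gene_rejected(self, tiny_study, tiny_config):
        ann, _ = tiny_study
        bad = PlantedTruth(
            pd.DataFrame(columns=["bin", "mark", "direction"]),
            pd.DataFrame({"gene": ["NOPE"], "expr_class": ["up"], "log2fc": [3.0]}),
        )
        with pytest.raises(ValueError, match="NOPE"):
            simulate_expression(ann, bad, tiny_config)


class TestMethylation:
    def test_null_deltas_centered_at_zero(self, tiny_study, tiny_config):
        ann, truth = tiny_study
        cfg = dataclasses.replace(tiny_config, frac_meth_shift=0.0)
        truth0 = plant_truth(ann, cfg)
        calls = simulate_methylation(ann, truth0, cfg)
        merged = calls[(0, 0)].merge(calls[(0, 1)], on=["chrom", "pos0"])
        assert abs(np.median(merged["fraction_y"] - merged["fraction_x"])) < 0.05

    def test_fixed_low_coverage_disqualifies_every_promoter(self, tiny_study, tiny_config):
        from histodiff.methylation import promoter_methylation_table, state_methylation

        ann, truth = tiny_study
        cfg = dataclasses.replace(tiny_config, cpg_cov_fixed=4)
        calls = simulate_methylation(ann, truth, cfg)
        tss = ann.genes[["gene", "chrom", "tss", "strand"]].rename(columns={"gene": "tss_id"})
        per_donor = promoter_methylation_table(tss, calls)
        assert per_donor["median"].isna().all()
        means = state_methylation(per_donor)
        assert means["mean"].isna().all()

    def test_island_promoters_hypomethylated(self, tiny_study, tiny_config):
        ann, truth = tiny_study
        calls = simulate_methylation(ann, truth, tiny_config)[(0, 0)]
        islands = ann.genes[ann.genes["cpg_island"]]
        nonisl = ann.genes[~ann.genes["cpg_island"]]
        def promoter_mean(g):
            sub = calls[(calls["chrom"] == g["chrom"])
                        & (calls["pos0"].between(g["tss"] - 1000, g["tss"] + 1000))]
            return sub["fraction"].mean()
        isl_means = [promoter_mean(g) for _, g in islands.iterrows()]
        non_means = [promoter_mean(g) for _, g in nonisl.iterrows()]
        assert np.nanmean(isl_means) < 0.25
        assert np.nanmean(non_means) > 0.4


class TestRegulatorySequences:
    def _regions(self, n_up, n_down, length=300):
        return pd.DataFrame(
            {
                "region": [f"u{i}" for i in range(n_up)] + [f"d{i}" for i in range(n_down)],
                "label": ["up"] * n_up + ["down"] * n_down,
                "length": length,
            }
        )

    def test_zero_plant_rate_empty_ledger(self, tiny_config):
        seqs, ledger = simulate_regulatory_sequences(
            self._regions(20, 20), DEMO_PWM_COUNTS, 0.0, tiny_config
        )
        assert ledger.empty
        assert len(seqs) == 40

    def test_full_plant_rate_one_entry_per_up_region(self, tiny_config):
        _, ledger = simulate_regulatory_sequences(
            self._regions(50, 10), DEMO_PWM_COUNTS, 1.0, tiny_config
        )
        assert len(ledger) >= 50
        assert set(ledger["region"]) == {f"u{i}" for i in range(50)}

    def test_short_region_skipped_with_warning(self, tiny_config):
        regions = self._regions(1, 0, length=3)
        with pytest.warns(UserWarning, match="shorter than motif"):
            seqs, ledger = simulate_regulatory_sequences(
                regions, DEMO_PWM_COUNTS, 1.0, tiny_config
            )
        assert ledger.empty and len(seqs["u0"]) == 3

    def test_planted_instances_recovered_by_scan(self, tiny_config):
        # near-deterministic matrix: sampled instances are the consensus
        strong = np.array(
            [[997, 997, 1, 997, 997, 1],
             [1, 1, 997, 1, 1, 1],
             [1, 1, 1, 1, 1, 1],
             [1, 1, 1, 1, 1, 997]],
            dtype=float,
        )
        seqs, ledger = simulate_regulatory_sequences(
            self._regions(20, 0), strong, 1.0, tiny_config
        )
        pwm = PWM("strong", strong)
        for entry in ledger.itertuples(index=False):
            hits = scan_pwm(seqs[entry.region], pwm, 0.80)
            overlapping = hits[
                (hits["position"] <= entry.position)
                & (hits["position"] + len(pwm) > entry.position)
            ]
            assert len(overlapping) >= 1


class TestSubstreams:
    def test_named_substreams_independent_of_sample_addition(self):
        a = substream(42, "chip", 0, 0, "H3K4me3").random(5)
        b = substream(42, "chip", 0, 0, "H3K4me3").random(5)
        other = substream(42, "chip", 3, 1, "H3K9ac").random(5)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, other)


def test_sample_motif_instance_matches_pwm_composition():
    rng = np.random.default_rng(0)
    probs = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0], [0.0, 0.0]])
    assert sample_motif_instance(probs, rng) == "AC"
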