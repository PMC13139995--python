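"""Generator contracts: determinism, planted structure, noiseless
aggregation identity, and serialisation round trips."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from methylant.annotation import read_gff3, read_repeats_bed
from methylant.errors import ConfigError, PackingError
from methylant.simulate import (
    GroundTruth,
    SimulationConfig,
    generate_annotation,
    generate_expression,
    generate_site_calls,
    simulate_dataset,
)
from methylant.site_io import aggregate_frequencies, read_site_table


class TestConfig:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ConfigError):
            SimulationConfig(gbm_fraction=1.2)

    def test_gbm_must_exceed_background(self):
        with pytest.raises(ConfigError):
            SimulationConfig(p_background=0.3, p_gbm_site=0.2)

    def test_coverage_must_be_positive(self):
        with pytest.raises(ConfigError):
            SimulationConfig(coverage_mean=0)


class TestAnnotation:
    def test_gbm_count_follows_floor_rule(self):
        config = small_config(n_genes=30, gbm_fraction=0.3)
        _, _, truth = generate_annotation(config)
        assert len(truth.gbm_gene_ids) == 9  # floor(0.3 * 30)

    def test_no_islands_means_uniform_density(self):
        config = small_config(n_te_islands_per_chrom=0)
        _, repeats, truth = generate_annotation(config)
        assert truth.island_intervals == []
        assert len(repeats) > 0

    def test_gene_bodies_do_not_overlap(self, small_sim):
        genes = sorted(small_sim["genes"], key=lambda g: (g.chrom, g.start))
        for a, b in zip(genes, genes[1:]):
            assert a.chrom != b.chrom or b.start >= a.end

    def test_islands_disjoint_sorted_in_bounds(self, small_sim):
        config = small_sim["config"]
        islands = small_sim["truth"].island_intervals
        assert islands == sorted(islands)
        for (c1, s1, e1), (c2, s2, _) in zip(islands, islands[1:]):
            assert c1 != c2 or s2 >= e1
        for _, s, e in islands:
            assert 0 <= s < e <= config.chrom_length

    def test_planted_genes_exist_in_annotation(self, small_sim):
        ids = {g.gene_id for g in small_sim["genes"]}
        assert small_sim["truth"].gbm_gene_ids <= ids
        assert small_sim["truth"].pmg_gene_ids <= ids

    def test_determinism_and_seed_sensitivity(self):
        a1, r1, _ = generate_annotation(small_config(seed=7))
        a2, r2, _ = generate_annotation(small_config(seed=7))
        a3, r3, _ = generate_annotation(small_config(seed=8))
        pd.testing.assert_frame_equal(r1, r2)
        assert [(g.gene_id, g.start) for g in a1] == [(g.gene_id, g.start) for g in a2]
        assert not r1.equals(r3)

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            generate_annotation(small_config(n_genes=500, gene_length_mean=10_000))


class TestSiteCalls:
    def test_noiseless_llr_aggregation_identity(self):
        """With a tight LLR distribution every read is called correctly,
        so thresholded aggregation reproduces the site truth exactly."""
        config = small_config(llr_mu=5.0, llr_sigma=1e-9, chrom_length=100_000, n_genes=5,
                              n_te_islands_per_chrom=0)
        genes, _, truth = generate_annotation(config)
        reads, sites = generate_site_calls(genes, truth, config)
        recovered = aggregate_frequencies(reads, llr_threshold=2.0)
        merged = recovered.merge(sites, on=["chrom", "pos"], suffixes=("_agg", "_truth"))
        assert len(merged) == len(sites)
        assert (merged["called_reads_agg"] == merged["called_reads_truth"]).all()
        assert (merged["methylated_reads_agg"] == merged["methylated_reads_truth"]).all()

    def test_zero_background_gives_zero_frequencies(self):
        config = small_config(
            p_background=0.0, gbm_fraction=0.0, pmg_fraction=0.0, p_gbm_site=0.3
        )
        genes, _, truth = generate_annotation(config)
        _, sites = generate_site_calls(genes, truth, config, emit_reads=False)
        assert (sites["frequency"] == 0).all()

    def test_background_mean_within_binomial_error(self):
        config = small_config(gbm_fraction=0.0, pmg_fraction=0.0, chrom_length=500_000)
        genes, _, truth = generate_annotation(config)
        _, sites = generate_site_calls(genes, truth, config, emit_reads=False)
        n = len(sites)  # 10k background sites at p = 0.03
        se = np.sqrt(0.03 * 0.97 / (n * config.coverage_mean))
        # beta jitter does not shift the mean, only spreads it
        assert abs(sites["frequency"].mean() - 0.03) <= 3 * se * 2

    def test_site_truth_recorded(self, small_sim):
        truth = small_sim["truth"]
        assert truth.site_truth is not None
        assert {"chrom", "pos", "p_true"} <= set(truth.site_truth.columns)


class TestExpression:
    def test_counts_are_non_negative_integers(self, small_sim):
        counts, _ = generate_expression(
            small_sim["genes"], small_sim["truth"], small_sim["sites"], small_sim["config"]
        )
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)

    def test_noise_free_relationship_is_linear(self):
        from methylant.expression import compute_fpkm, methylation_expression_correlation

        config = small_config(expr_noise_sd=0.0)
        genes, _, truth = generate_annotation(config)
        _, sites = generate_site_calls(genes, truth, config, emit_reads=False)
        counts, lengths = generate_expression(genes, truth, sites, config)
        fpkm = compute_fpkm(counts, lengths)
        res = methylation_expression_correlation(
            fpkm, truth.gene_methylation, transform="log1p"
        )
        assert res.statistic >= 0.999  # exact up to count rounding

    def test_null_slope_gives_null_correlation(self):
        from methylant.expression import compute_fpkm, methylation_expression_correlation

        config = small_config(expr_slope=0.0, n_genes=80, chrom_length=1_000_000)
        genes, _, truth = generate_annotation(config)
        _, sites = generate_site_calls(genes, truth, config, emit_reads=False)
        counts, lengths = generate_expression(genes, truth, sites, config)
        fpkm = compute_fpkm(counts, lengths)
        res = methylation_expression_correlation(fpkm, truth.gene_methylation, "log1p")
        assert abs(res.statistic) <= 3.0 / np.sqrt(80 - 3)

    def test_too_few_samples_rejected(self, small_sim):
        config = small_config(n_expression_samples=1)
        with pytest.raises(ConfigError):
            generate_expression(
                small_sim["genes"], small_sim["truth"], small_sim["sites"], config
            )


class TestSerialisation:
    def test_dataset_round_trip(self, tmp_path):
        config = small_config(chrom_length=300_000, n_genes=8, island_width=50_000)
        paths = simulate_dataset(config, tmp_path / "sim")
        genes, repeats, truth = generate_annotation(config)
        _, sites = generate_site_calls(genes, truth, config)

        back_genes = read_gff3(paths["genes_gff3"])
        assert [(g.gene_id, g.start, g.end, g.strand, g.exons) for g in back_genes] == [
            (g.gene_id, g.start, g.end, g.strand, g.exons) for g in genes
        ]
        pd.testing.assert_frame_equal(read_repeats_bed(paths["repeats_bed"]), repeats)
        pd.testing.assert_frame_equal(read_site_table(paths["sites_tsv"]), sites)
        back_truth = GroundTruth.from_json(paths["truth_json"])
        assert back_truth.gbm_gene_ids == truth.gbm_gene_ids
        assert back_truth.island_intervals == truth.island_intervals

    def test_byte_identical_on_same_seed(self, tmp_path):
        config = small_config(chrom_length=300_000, n_genes=8, island_width=50_000)
        p1 = simulate_dataset(config, tmp_path / "a")
        p2 = simulate_dataset(config, tmp_path / "b")
        for name in p1:
            with open(p1[name], "rb") as f1, open(p2[name], "rb") as f2:
                assert f1.read() == f2.read(), name
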