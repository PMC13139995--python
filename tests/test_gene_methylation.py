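"""Weighted methylation, site binarisation, GBM/promoter classification
and metagene profiles — with exact binomial-tail oracles and planted
ground truth."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import site_table, small_config
from methylant.annotation import GeneModel
from methylant.errors import ConfigError, DataError
from methylant.gene_methylation import (
    ClassificationConfig,
    binarize_sites,
    class_overlap,
    classify_gbm,
    classify_promoters,
    metaprofile,
    weighted_region_methylation,
)
from methylant.simulate import generate_annotation, generate_site_calls


def direct_upper_tail(k, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


class TestWeightedMethylation:
    def test_coverage_weighting(self):
        table = site_table([("chr1", 10, "+", 10, 2), ("chr1", 20, "+", 10, 3)])
        n, k, c, w = weighted_region_methylation(table, [("chr1", 0, 100)])
        assert (n, k, c) == (2, 5, 20)
        assert w == pytest.approx(0.25)

    def test_zero_methylation(self):
        table = site_table([("chr1", 10, "+", 15, 0)])
        assert weighted_region_methylation(table, [("chr1", 0, 100)])[3] == 0.0

    def test_equals_simple_mean_at_equal_coverage(self):
        rng = np.random.default_rng(1)
        rows = [("chr1", 10 * i, "+", 20, int(rng.integers(0, 21))) for i in range(30)]
        table = site_table(rows)
        _, _, _, w = weighted_region_methylation(table, [("chr1", 0, 1000)])
        assert w == pytest.approx(table["frequency"].mean())

    def test_uncovered_region_flagged(self):
        table = site_table([("chr1", 10, "+", 15, 0)])
        assert np.isnan(weighted_region_methylation(table, [("chr2", 0, 100)])[3])

    def test_empty_region_is_error(self):
        with pytest.raises(DataError):
            weighted_region_methylation(site_table([("chr1", 10, "+", 15, 0)]), [])


class TestBinarize:
    def test_site_binomial_oracle(self):
        table = site_table(
            [("chr1", 10, "+", 10, 8), ("chr1", 20, "+", 10, 0), ("chr1", 30, "+", 10, 1)]
        )
        config = ClassificationConfig(site_error_rate=0.05)
        flags = binarize_sites(table, config)
        # the 8/10 site: direct summation gives P ~ 1.6e-9, flagged even after BH
        assert direct_upper_tail(8, 10, 0.05) == pytest.approx(1.605e-9, rel=5e-3)
        assert flags.tolist() == [True, False, False]

    def test_zero_methylated_never_flagged(self):
        table = site_table([("chr1", 10, "+", 10, 0)])
        for mode in ("site-binomial", "frequency-threshold"):
            config = ClassificationConfig(site_mode=mode)
            assert not binarize_sites(table, config).any()

    def test_frequency_threshold_boundary(self):
        table = site_table([("chr1", 10, "+", 100, 49), ("chr1", 20, "+", 100, 50)])
        config = ClassificationConfig(site_mode="frequency-threshold", site_freq_cutoff=0.5)
        assert binarize_sites(table, config).tolist() == [False, True]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            ClassificationConfig(site_mode="magic")


def gene_with_sites(n_sites, k_meth, chrom="chr1", gene_id="g1", coverage=30):
    """One 10 kb gene plus a site table with k methylated sites (reads
    fully methylated) and n-k unmethylated ones."""
    gene = GeneModel(gene_id, chrom, "+", 0, 10_000)
    rows = [
        (chrom, 10 + 40 * i, "+", coverage, coverage if i < k_meth else 0)
        for i in range(n_sites)
    ]
    return gene, site_table(rows)


class TestClassifyGBM:
    def test_strong_signal_called_gbm(self):
        # k=30 of n=100 sites methylated vs p0=0.03: upper tail << 1e-6
        gene, table = gene_with_sites(100, 30)
        config = ClassificationConfig(background_p=0.03)
        out = classify_gbm([gene], table, config)
        assert out.iloc[0]["class"] == "GBM"
        assert out.iloc[0]["p_value"] == pytest.approx(direct_upper_tail(30, 100, 0.03))

    def test_background_level_stays_um(self):
        gene, table = gene_with_sites(100, 3)
        config = ClassificationConfig(background_p=0.03)
        out = classify_gbm([gene], table, config)
        assert out.iloc[0]["class"] == "UM"
        assert out.iloc[0]["p_value"] == pytest.approx(0.5802, abs=1e-3)

    def test_uncovered_gene_unclassified_and_outside_bh_family(self):
        gene, table = gene_with_sites(100, 30)
        lonely = GeneModel("g2", "chr9", "+", 0, 1000)
        config = ClassificationConfig(background_p=0.03)
        out = classify_gbm([gene, lonely], table, config).set_index("gene_id")
        assert out.loc["g2", "class"] == "unclassified"
        assert np.isnan(out.loc["g2", "p_value"])
        # BH family has one member; its q equals its p
        assert out.loc["g1", "q_value"] == pytest.approx(out.loc["g1", "p_value"])

    def test_zero_background_edge(self):
        gene, table = gene_with_sites(50, 5)
        out = classify_gbm([gene], table, ClassificationConfig(background_p=0.0))
        assert out.iloc[0]["p_value"] == 0.0
        assert out.iloc[0]["class"] == "GBM"

    def test_class_counts_partition_genes(self, small_sim):
        out = classify_gbm(small_sim["genes"], small_sim["sites"], ClassificationConfig())
        counts = out["class"].value_counts()
        assert counts.sum() == len(small_sim["genes"])
        assert set(counts.index) <= {"GBM", "UM", "unclassified"}

    def test_invariant_to_site_order_and_chromosome_split(self, small_sim):
        config = ClassificationConfig(background_p=0.05)
        base = classify_gbm(small_sim["genes"], small_sim["sites"], config)
        shuffled = small_sim["sites"].sample(frac=1.0, random_state=0)
        again = classify_gbm(small_sim["genes"], shuffled, config)
        pd.testing.assert_frame_equal(base, again)

    def test_monotone_in_background(self, small_sim):
        lo = classify_gbm(
            small_sim["genes"], small_sim["sites"], ClassificationConfig(background_p=0.02)
        )
        hi = classify_gbm(
            small_sim["genes"], small_sim["sites"], ClassificationConfig(background_p=0.2)
        )
        assert (hi["class"] == "GBM").sum() <= (lo["class"] == "GBM").sum()

    def test_planted_gbm_recovery(self, small_sim):
        out = classify_gbm(small_sim["genes"], small_sim["sites"], ClassificationConfig())
        called = set(out.loc[out["class"] == "GBM", "gene_id"])
        truth = small_sim["truth"].gbm_gene_ids
        sensitivity = len(called & truth) / len(truth)
        fdr = len(called - truth) / max(1, len(called))
        assert sensitivity >= 0.95 and fdr <= 0.05


class TestClassifyPromoters:
    def test_floor_rule_blocks_low_level_promoters(self):
        # significant excess of methylated sites but weighted level below 3%
        gene = GeneModel("g1", "chr1", "+", 1000, 5000)
        rows = [("chr1", 810 + 40 * i, "+", 200, 4) for i in range(4)]  # 2% each
        table = site_table(rows)
        config = ClassificationConfig(
            background_p=0.001, site_mode="frequency-threshold", site_freq_cutoff=0.015
        )
        out = classify_promoters([gene], table, config)
        row = out.iloc[0]
        assert row["q_value"] < config.alpha  # significant by count...
        assert row["weighted_methylation"] < 0.03
        assert row["class"] == "PUM"  # ...but the 3% floor wins

    def test_unmethylated_promoter_is_pum(self):
        gene = GeneModel("g1", "chr1", "+", 1000, 5000)
        table = site_table([("chr1", 850, "+", 30, 0)])
        out = classify_promoters([gene], table, ClassificationConfig(background_p=0.03))
        assert out.iloc[0]["class"] == "PUM"

    def test_planted_pmg_recovery(self, small_sim):
        out = classify_promoters(small_sim["genes"], small_sim["sites"], ClassificationConfig())
        called = set(out.loc[out["class"] == "PMG", "gene_id"])
        truth = small_sim["truth"].pmg_gene_ids
        assert len(called & truth) / len(truth) >= 0.9


class TestClassOverlap:
    def test_shared_fraction_accounting(self):
        def frame(ids_pos, ids_neg):
            return pd.DataFrame(
                {"gene_id": ids_pos + ids_neg,
                 "class": ["GBM"] * len(ids_pos) + ["UM"] * len(ids_neg)}
            )

        stages = {
            "larvae": frame(["a", "b", "c"], ["d"]),
            "pupae": frame(["b", "c", "d"], ["a"]),
        }
        out = class_overlap(stages).set_index("stage")
        assert out.loc["larvae", "n_shared_all"] == 2  # {b, c}
        assert out.loc["larvae", "shared_pct_of_stage"] == pytest.approx(200 / 3)


class TestMetaprofile:
    def test_minus_strand_upstream_bin(self):
        gene = GeneModel("g1", "chr1", "-", 10_000, 20_000)
        # 100 bp 5' of a minus-strand TSS is plus-strand right of the gene end
        table = site_table([("chr1", 20_099, "+", 10, 5)])
        profile = metaprofile([gene], table)
        hit = profile[profile["n_sites"] > 0]
        assert len(hit) == 1
        assert hit.iloc[0]["segment"] == "upstream" and hit.iloc[0]["bin"] == 1

    def test_flat_profile_under_uniform_methylation(self):
        config = small_config(gbm_fraction=0.0, pmg_fraction=0.0, chrom_length=1_000_000,
                              n_genes=80)
        genes, _, truth = generate_annotation(config)
        _, sites = generate_site_calls(genes, truth, config, emit_reads=False)
        profile = metaprofile(genes, sites)
        level = profile["weighted_methylation"].dropna()
        # every bin is a large pooled binomial draw around p = 0.03
        assert level.max() - level.min() < 0.03

    def test_body_exceeds_flanks_with_planted_gbm(self, small_sim):
        profile = metaprofile(small_sim["genes"], small_sim["sites"])
        by_segment = profile.groupby("segment")["weighted_methylation"].mean()
        assert by_segment["body"] > 2 * by_segment["upstream"]
        assert by_segment["body"] > 2 * by_segment["downstream"]

    def test_short_gene_pools_without_error(self):
        gene = GeneModel("g1", "chr1", "+", 1000, 1020)  # 20 bp body, 40 bins
        table = site_table([("chr1", 1010, "+", 10, 5)])
        profile = metaprofile([gene], table)
        assert profile.loc[profile["n_sites"] > 0, "segment"].tolist() == ["body"]
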