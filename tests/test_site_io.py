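"""Dialect parsing, site aggregation, strand merging and filtering."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import site_table
from methylant.errors import ConfigError, DataError
from methylant.site_io import (
    READ_LEVEL_COLUMNS,
    aggregate_frequencies,
    filter_low_call_sequences,
    filter_sites,
    make_site_table,
    merge_complementary_cpg,
    read_bismark_coverage,
    read_read_level_calls,
    read_site_table,
    write_site_table,
)


def reads_tsv(rows, path, header=None):
    header = header or READ_LEVEL_COLUMNS
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path


def read_row(chrom="chr1", start=100, llr=3.0, read="r1", num_motifs=1, seq="ATCGAT"):
    return (chrom, "+", start, start + 1, read, llr, llr, 0.0, 1, num_motifs, seq)


class TestReadLevelParsing:
    def test_group_split_inherits_llr(self, tmp_path):
        # one grouped call spanning three CpGs in its k-mer window
        path = reads_tsv(
            [read_row(start=50, llr=4.2, num_motifs=3, seq="AACGTCGTTACGA")],
            tmp_path / "reads.tsv",
        )
        calls = read_read_level_calls(path)
        assert len(calls) == 3
        assert set(calls["log_lik_ratio"]) == {4.2}
        # CGs at offsets 2, 5, 10 of the sequence -> genomic 50, 53, 58
        assert sorted(calls["start"]) == [50, 53, 58]

    def test_empty_file_with_header(self, tmp_path):
        path = reads_tsv([], tmp_path / "reads.tsv")
        assert read_read_level_calls(path).empty

    def test_missing_column_named(self, tmp_path):
        header = [c for c in READ_LEVEL_COLUMNS if c != "log_lik_ratio"]
        path = reads_tsv([], tmp_path / "reads.tsv", header=header)
        with pytest.raises(DataError, match="log_lik_ratio"):
            read_read_level_calls(path)

    def test_malformed_row_reports_line(self, tmp_path):
        rows = [read_row(), ("chr1", "+", 200, 201, "r2", "oops", 0, 0, 1, 1, "ATCGAT")]
        path = reads_tsv(rows, tmp_path / "reads.tsv")
        with pytest.raises(DataError, match="line 3"):
            read_read_level_calls(path)


class TestAggregate:
    def test_threshold_and_ambiguity(self, tmp_path):
        rows = [
            read_row(llr=3.1, read="r1"),
            read_row(llr=2.5, read="r2"),
            read_row(llr=-4.0, read="r3"),
            read_row(llr=0.1, read="r4"),  # ambiguous, excluded entirely
        ]
        calls = read_read_level_calls(reads_tsv(rows, tmp_path / "r.tsv"))
        table = aggregate_frequencies(calls, llr_threshold=2.0)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.called_reads, row.methylated_reads) == (3, 2)
        assert row.frequency == pytest.approx(2 / 3)

    def test_all_unmethylated(self, tmp_path):
        rows = [read_row(llr=-5.0, read=f"r{i}") for i in range(4)]
        calls = read_read_level_calls(reads_tsv(rows, tmp_path / "r.tsv"))
        assert aggregate_frequencies(calls).iloc[0].frequency == 0.0

    def test_empty_input(self):
        assert aggregate_frequencies(pd.DataFrame(columns=READ_LEVEL_COLUMNS)).empty

    def test_threshold_must_be_positive(self):
        with pytest.raises(ConfigError):
            aggregate_frequencies(pd.DataFrame(columns=READ_LEVEL_COLUMNS), llr_threshold=0)

    def test_permutation_invariance(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = [
            read_row(start=int(rng.integers(0, 5)) * 10, llr=float(rng.normal(0, 4)), read=f"r{i}")
            for i in range(60)
        ]
        calls = read_read_level_calls(reads_tsv(rows, tmp_path / "r.tsv"))
        shuffled = calls.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            aggregate_frequencies(calls), aggregate_frequencies(shuffled)
        )

    def test_recovers_true_rate_within_binomial_error(self, tmp_path):
        # 1000 reads at one site, true p = 0.25, well-separated LLRs
        rng = np.random.default_rng(42)
        state = rng.random(1000) < 0.25
        rows = [
            read_row(llr=float(rng.normal(5 if s else -5, 1)), read=f"r{i}")
            for i, s in enumerate(state)
        ]
        calls = read_read_level_calls(reads_tsv(rows, tmp_path / "r.tsv"))
        freq = aggregate_frequencies(calls).iloc[0].frequency
        assert abs(freq - 0.25) <= 3 * np.sqrt(0.25 * 0.75 / 1000)


class TestBismark:
    def make(self, text, tmp_path):
        path = tmp_path / "cov.tsv"
        path.write_text(text)
        return path

    def test_coordinates_and_counts(self, tmp_path):
        table = read_bismark_coverage(self.make("chr1\t101\t101\t50.0\t5\t5\n", tmp_path))
        row = table.iloc[0]
        assert (row.pos, row.called_reads, row.methylated_reads) == (100, 10, 5)
        assert row.frequency == 0.5

    def test_zero_coverage_dropped_with_warning(self, tmp_path):
        with pytest.warns(UserWarning, match="zero-coverage"):
            table = read_bismark_coverage(
                self.make("chr1\t101\t101\t0.0\t0\t0\nchr1\t201\t201\t100.0\t3\t0\n", tmp_path)
            )
        assert len(table) == 1

    def test_counts_win_over_percentage(self, tmp_path):
        with pytest.warns(UserWarning, match="counts win"):
            table = read_bismark_coverage(self.make("chr1\t101\t101\t40.0\t5\t5\n", tmp_path))
        assert table.iloc[0].frequency == 0.5


class TestMerge:
    def test_complementary_pair_merges(self):
        table = site_table([("chr1", 100, "+", 10, 5), ("chr1", 101, "-", 10, 3)])
        merged = merge_complementary_cpg(table)
        assert len(merged) == 1
        row = merged.iloc[0]
        assert (row.pos, row.called_reads, row.methylated_reads) == (100, 20, 8)
        assert row.frequency == pytest.approx(0.4)
        assert row.strand == "."

    def test_unpaired_site_retained(self):
        merged = merge_complementary_cpg(site_table([("chr1", 200, "+", 10, 2)]))
        assert (merged.iloc[0].pos, merged.iloc[0].methylated_reads) == (200, 2)

    def test_read_counts_conserved(self, tiny_table):
        merged = merge_complementary_cpg(tiny_table)
        for col in ("called_reads", "methylated_reads"):
            assert merged[col].sum() == tiny_table[col].sum()


class TestFilters:
    def test_min_coverage_boundary(self):
        table = site_table(
            [("chr1", p, "+", c, 0) for p, c in [(10, 9), (20, 10), (30, 11)]]
        )
        kept, removed = filter_sites(table, min_coverage=10)
        assert list(kept["called_reads"]) == [10, 11]
        assert removed == 1

    def test_min_coverage_one_is_identity(self, tiny_table):
        kept, removed = filter_sites(tiny_table, min_coverage=1)
        assert removed == 0 and len(kept) == len(tiny_table)

    def test_all_below_threshold(self, tiny_table):
        kept, removed = filter_sites(tiny_table, min_coverage=100)
        assert kept.empty and removed == len(tiny_table)

    def test_low_call_sequence_dropped(self):
        table = site_table([("chrA", 10 * i, "+", 12, 1) for i in range(5)])
        kept, dropped = filter_low_call_sequences(table, {"chrA": 100}, min_fraction=0.10)
        assert kept.empty and dropped == {"chrA": pytest.approx(0.05)}

    def test_exactly_at_threshold_retained(self):
        table = site_table([("chrA", 10 * i, "+", 12, 1) for i in range(10)])
        kept, dropped = filter_low_call_sequences(table, {"chrA": 100}, min_fraction=0.10)
        assert len(kept) == 10 and not dropped

    def test_unknown_chromosome_is_error(self, tiny_table):
        with pytest.raises(DataError, match="chr2"):
            filter_low_call_sequences(tiny_table, {"chr1": 10})


class TestRoundTrip:
    def test_site_tsv_round_trip(self, tmp_path, tiny_table):
        path = tmp_path / "sites.tsv"
        write_site_table(tiny_table, path)
        back = read_site_table(path)
        pd.testing.assert_frame_equal(back, tiny_table)

    @given(
        st.lists(
            st.tuples(st.integers(0, 1000), st.integers(1, 50), st.integers(0, 50)),
            min_size=1,
            max_size=20,
            unique_by=lambda t: t[0],
        )
    )
    def test_frequency_consistent_with_counts(self, rows):
        table = make_site_table(
            pd.DataFrame(
                [("chr1", p, "+", c, min(m, c)) for p, c, m in rows],
                columns=["chrom", "pos", "strand", "called_reads", "methylated_reads"],
            )
        )
        err = (table.frequency * table.called_reads - table.methylated_reads).abs()
        assert (err <= 1e-9).all()
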