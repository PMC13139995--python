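"""Parsing, aggregation and filtering of per-CpG methylation calls.

The canonical in-memory currency is the *site table*: a frame with one
row per (chrom, pos, strand) carrying ``called_reads``,
``methylated_reads`` and ``frequency`` = methylated/called. Positions
are 0-based; after strand merging ``pos`` is the plus-strand C of the
CpG and ``strand`` is ``"."``.

Two input dialects are supported: per-read nanopore methylation calls
(tab-separated, one log-likelihood ratio per read per CpG group) and
the bisulfite per-cytosine coverage report (1-based, counts of
methylated/unmethylated reads). Frequencies are always recomputed from
counts; a stated percentage column is never trusted.
"""

from __future__ import annotations

import os
import re
import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

SITE_COLUMNS = ["chrom", "pos", "strand", "called_reads", "methylated_reads", "frequency"]

READ_LEVEL_COLUMNS = [
    "chromosome", "strand", "start", "end", "read_name", "log_lik_ratio",
    "log_lik_methylated", "log_lik_unmethylated", "num_calling_strands",
    "num_motifs", "sequence",
]


def make_site_table(df: pd.DataFrame, recompute_frequency: bool = True) -> pd.DataFrame:
    """Validate, canonicalise and sort a site table."""
    missing = [c for c in SITE_COLUMNS if c not in df.columns and c != "frequency"]
    if missing:
        raise DataError(f"site table missing columns: {missing}")
    out = df.copy()
    out["pos"] = out["pos"].astype(np.int64)
    out["called_reads"] = out["called_reads"].astype(np.int64)
    out["methylated_reads"] = out["methylated_reads"].astype(np.int64)
    if (out["methylated_reads"] > out["called_reads"]).any() or (
        out["methylated_reads"] < 0
    ).any():
        raise DataError("require 0 <= methylated_reads <= called_reads")
    if recompute_frequency or "frequency" not in out.columns:
        with np.errstate(invalid="ignore"):
            out["frequency"] = np.where(
                out["called_reads"] > 0,
                out["methylated_reads"] / out["called_reads"].replace(0, 1),
                np.nan,
            )
    out = out[SITE_COLUMNS].sort_values(["chrom", "pos", "strand"], ignore_index=True)
    if out.duplicated(["chrom", "pos", "strand"]).any():
        raise DataError("duplicate (chrom, pos, strand) rows in site table")
    return out


def write_site_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_site_table(path: str | os.PathLike) -> pd.DataFrame:
    return make_site_table(pd.read_csv(path, sep="\t"))


def read_read_level_calls(
    path: str | os.PathLike, split_groups: bool = True
) -> pd.DataFrame:
    """Read a per-read nanopore methylation-call table.

    Rows with ``num_motifs > 1`` are grouped calls covering several CpGs
    within one k-mer window; with ``split_groups`` each is expanded into
    one record per CG in ``sequence``, all inheriting the group's
    log-likelihood ratio. Malformed numeric fields are reported with
    their line number (header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in READ_LEVEL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    for col in ("start", "end", "num_motifs"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise DataError(
                f"{path}: non-numeric {col} at line {int(np.flatnonzero(bad)[0]) + 2}"
            )
        df[col] = vals.astype(np.int64)
    for col in ("log_lik_ratio", "log_lik_methylated", "log_lik_unmethylated"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise DataError(
                f"{path}: non-numeric {col} at line {int(np.flatnonzero(bad)[0]) + 2}"
            )
        df[col] = vals.astype(float)
    if (df["num_motifs"] < 1).any():
        raise DataError(f"{path}: num_motifs must be >= 1")
    if (df["end"] <= df["start"]).any():
        raise DataError(f"{path}: end must exceed start")

    if not split_groups or not (df["num_motifs"] > 1).any():
        return df.reset_index(drop=True)

    singles = df[df["num_motifs"] == 1]
    grouped = df[df["num_motifs"] > 1]
    parts = [singles]
    for row in grouped.itertuples(index=False):
        offsets = [m.start() for m in re.finditer("CG", row.sequence)]
        if len(offsets) != row.num_motifs:
            raise DataError(
                f"{path}: sequence {row.sequence!r} has {len(offsets)} CGs "
                f"but num_motifs={row.num_motifs}"
            )
        rec = pd.DataFrame([row._asdict()] * len(offsets))
        rec["start"] = row.start + np.array(offsets) - offsets[0]
        rec["end"] = rec["start"] + 1
        rec["num_motifs"] = 1
        parts.append(rec)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["chromosome", "start", "read_name"], ignore_index=True)


def aggregate_frequencies(calls: pd.DataFrame, llr_threshold: float = 2.0) -> pd.DataFrame:
    """Collapse per-read calls into per-site methylation frequencies.

    A read contributes to a site only if its |LLR| exceeds the
    threshold (ambiguous calls are excluded from numerator and
    denominator alike); it counts as methylated if LLR > +threshold.
    """
    if llr_threshold <= 0:
        raise ConfigError("llr_threshold must be positive")
    if calls.empty:
        return make_site_table(
            pd.DataFrame(columns=SITE_COLUMNS).astype(
                {"pos": np.int64, "called_reads": np.int64, "methylated_reads": np.int64}
            ),
        )
    confident = calls[calls["log_lik_ratio"].abs() > llr_threshold]
    if confident.empty:
        return aggregate_frequencies(calls.iloc[0:0], llr_threshold)
    flags = (confident["log_lik_ratio"] > llr_threshold).astype(np.int64)
    grouped = (
        confident.assign(methylated=flags)
        .groupby(["chromosome", "start"], sort=True)
        .agg(called_reads=("methylated", "size"), methylated_reads=("methylated", "sum"))
    )
    out = grouped.reset_index().rename(columns={"chromosome": "chrom", "start": "pos"})
    out["strand"] = "+"
    return make_site_table(out)


def read_bismark_coverage(path: str | os.PathLike) -> pd.DataFrame:
    """Read a bisulfite coverage report into a site table.

    Dialect: chrom, start (1-based), end, methylation percentage,
    methylated count, unmethylated count. Counts win over the percentage
    column (a >0.5 point disagreement raises a warning); zero-coverage
    rows are dropped with a warning. Strand is not encoded in this
    dialect; use :func:`assign_cpg_strand` with a genome CpG index before
    strand merging.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "pct", "count_m", "count_u"],
    )
    called = df["count_m"] + df["count_u"]
    zero = called == 0
    if zero.any():
        warnings.warn(f"{path}: dropping {int(zero.sum())} zero-coverage rows")
        df, called = df[~zero], called[~zero]
    freq = df["count_m"] / called
    disagrees = (df["pct"] - 100.0 * freq).abs() > 0.5
    if disagrees.any():
        warnings.warn(
            f"{path}: percentage column disagrees with counts on "
            f"{int(disagrees.sum())} rows; counts win"
        )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["start"].astype(np.int64) - 1,
            "strand": "+",
            "called_reads": called.astype(np.int64),
            "methylated_reads": df["count_m"].astype(np.int64),
        }
    )
    return make_site_table(out)


def assign_cpg_strand(table: pd.DataFrame, cpg_index: dict[str, np.ndarray]) -> pd.DataFrame:
    """Resolve per-cytosine strands against a genome CpG index.

    ``cpg_index`` maps chromosome → sorted plus-strand C positions of
    every CpG. A row at an indexed position is the plus-strand C; a row
    one bp right of an indexed position is its minus-strand mate.
    """
    out = table.copy()
    strands = []
    for row in out.itertuples(index=False):
        positions = cpg_index.get(row.chrom)
        if positions is None:
            raise DataError(f"chromosome {row.chrom} absent from CpG index")
        if _in_sorted(positions, row.pos):
            strands.append("+")
        elif _in_sorted(positions, row.pos - 1):
            strands.append("-")
        else:
            raise DataError(f"position {row.chrom}:{row.pos} is not part of an indexed CpG")
    out["strand"] = strands
    return make_site_table(out)


def _in_sorted(arr: np.ndarray, value: int) -> bool:
    i = np.searchsorted(arr, value)
    return bool(i < len(arr) and arr[i] == value)


def merge_complementary_cpg(table: pd.DataFrame) -> pd.DataFrame:
    """Merge the two strands of each CpG into one record.

    Minus-strand rows (C at plus-strand pos+1) are folded onto the
    plus-strand C position; counts are summed and the frequency
    recomputed. Unpaired rows are retained. The output carries the
    merged-strand marker ``"."`` throughout, and total read counts are
    conserved exactly.
    """
    df = table.copy()
    minus = df["strand"] == "-"
    df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
    grouped = (
        df.groupby(["chrom", "pos"], sort=True)[["called_reads", "methylated_reads"]]
        .sum()
        .reset_index()
    )
    grouped["strand"] = "."
    return make_site_table(grouped)


def filter_sites(table: pd.DataFrame, min_coverage: int = 10) -> tuple[pd.DataFrame, int]:
    """Drop sites below the minimum read count; returns (table, n_removed)."""
    if min_coverage < 1:
        raise ConfigError("min_coverage must be >= 1")
    keep = table["called_reads"] >= min_coverage
    return table[keep].reset_index(drop=True), int((~keep).sum())


def filter_low_call_sequences(
    table: pd.DataFrame,
    index: dict[str, int] | dict[str, np.ndarray],
    min_fraction: float = 0.10,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Drop every site of a sequence whose called-CpG fraction is too low.

    A chromosome (or contig) where fewer than ``min_fraction`` of its
    indexed CpGs received a call is excluded wholesale (strictly less
    than: exactly the threshold is retained). Returns the filtered table
    and the per-chromosome called fractions of the dropped sequences.
    """
    counts = {
        chrom: (len(v) if hasattr(v, "__len__") else int(v)) for chrom, v in index.items()
    }
    dropped: dict[str, float] = {}
    keep_chroms = []
    for chrom, sub in table.groupby("chrom", sort=False):
        if chrom not in counts:
            raise DataError(f"chromosome {chrom} absent from CpG index")
        total = counts[chrom]
        fraction = len(sub) / total if total > 0 else 1.0
        if fraction < min_fraction:
            dropped[str(chrom)] = fraction
        else:
            keep_chroms.append(chrom)
    out = table[table["chrom"].isin(keep_chroms)].reset_index(drop=True)
    return out, dropped


def read_cpg_index_bed(path: str | os.PathLike) -> dict[str, np.ndarray]:
    """Read a genome-wide CpG BED3 (plus-strand C positions) into an index."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby(0, sort=False):
        out[str(chrom)] = np.sort(sub[1].astype(np.int64).to_numpy())
    return out


def write_cpg_index_bed(index: dict[str, np.ndarray], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, positions in index.items():
            for p in positions:
                fh.write(f"{chrom}\t{p}\t{p + 2}\n")
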