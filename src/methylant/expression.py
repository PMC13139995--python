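"""Expression quantification (FPKM) and its link to methylation.

FPKM = counts * 1e9 / (total mapped reads * gene length in bp) — the
standard form, in which doubling all counts and totals leaves the value
unchanged. A "printed" variant dividing by the length in kb together
with the 1e9 factor (dimensionally 1000x the standard value) is kept
behind ``variant="printed"`` for comparability with reports that state
the formula that way; every scale-free statistic downstream (rank-sum,
correlation) is identical under either variant.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .stats import TestResult, pearson_correlation, wilcoxon_rank_sum

__all__ = [
    "read_counts",
    "compute_fpkm",
    "compare_expression_by_class",
    "methylation_expression_correlation",
]


def read_counts(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.Series]:
    """Read a counts TSV (gene_id, length, one column per sample).

    Returns (counts frame indexed by gene_id, gene length series).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise DataError(f"{path}: counts table needs a 'length' column")
    lengths = df["length"].astype(np.int64)
    counts = df.drop(columns=["length"])
    if (counts.to_numpy() < 0).any():
        raise DataError(f"{path}: negative read counts")
    return counts, lengths


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: pd.Series | None = None,
    variant: str = "standard",
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``totals`` defaults to the column sums of the counts matrix (total
    mapped reads per sample). Zero gene lengths are an error; the result
    is linear in counts at fixed totals and lengths.
    """
    if variant not in ("standard", "printed"):
        raise ConfigError(f"unknown FPKM variant {variant!r}")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise DataError("gene length missing for some genes")
    if (lengths <= 0).any():
        raise DataError("gene lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise DataError("per-sample totals must be positive")
    denom_length = lengths.to_numpy()[:, None].astype(float)
    if variant == "printed":
        denom_length = denom_length / 1000.0
    fpkm = counts.to_numpy() * 1e9 / (totals.to_numpy()[None, :] * denom_length)
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def compare_expression_by_class(
    expr: pd.DataFrame,
    classes: pd.DataFrame,
    positive: str = "GBM",
    negative: str = "UM",
) -> dict[str, float | TestResult]:
    """Rank-sum test of per-gene mean FPKM between two methylation classes.

    ``classes`` is a classification frame (gene_id, class, ...); both
    classes must be non-empty among genes present in the expression
    table.
    """
    mean_fpkm = expr.mean(axis=1)
    by_class = classes.set_index("gene_id")["class"].reindex(mean_fpkm.index)
    x = mean_fpkm[by_class == positive].to_numpy()
    y = mean_fpkm[by_class == negative].to_numpy()
    if x.size == 0 or y.size == 0:
        raise DataError(f"class {positive if x.size == 0 else negative} is empty")
    result = wilcoxon_rank_sum(x, y)
    return {
        "test": result,
        f"median_{positive}": float(np.median(x)),
        f"median_{negative}": float(np.median(y)),
        f"n_{positive}": int(x.size),
        f"n_{negative}": int(y.size),
    }


def methylation_expression_correlation(
    expr: pd.DataFrame,
    gene_meth: pd.DataFrame | pd.Series,
    transform: str = "identity",
) -> TestResult:
    """Pearson correlation of gene-body methylation with expression.

    ``gene_meth`` is either a classification frame carrying
    ``weighted_methylation`` per gene_id or a plain per-gene series.
    ``transform`` applies to the per-gene mean FPKM: identity (the
    default) or log1p.
    """
    if transform not in ("identity", "log1p"):
        raise ConfigError(f"unknown transform {transform!r}")
    if isinstance(gene_meth, pd.DataFrame):
        meth = gene_meth.set_index("gene_id")["weighted_methylation"]
    else:
        meth = gene_meth
    mean_fpkm = expr.mean(axis=1)
    joined = pd.concat([meth.rename("m"), mean_fpkm.rename("e")], axis=1).dropna()
    if len(joined) < 3:
        raise DataError("need at least 3 genes with both methylation and expression")
    e = joined["e"].to_numpy()
    if transform == "log1p":
        e = np.log1p(e)
    return pearson_correlation(joined["m"].to_numpy(), e)
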