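"""Cross-technology agreement between two site tables.

Joins sites by exact genomic position (an optional ±1 bp tolerance
absorbs dialect disagreement about whether the C or the CpG start is
anchored), then quantifies agreement with Pearson correlation on the
shared per-site frequencies and, optionally, on window-averaged
frequencies — window averaging absorbs binomial sampling noise, so the
windowed correlation is expected to exceed the per-site one on paired
data with a common truth. p-values are reported, never thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .stats import pearson_correlation

__all__ = ["ConcordanceReport", "join_sites", "concordance_report"]


@dataclass
class ConcordanceReport:
    n_shared: int
    n_unique_a: int
    n_unique_b: int
    pearson_r: float
    r_p_value: float
    windowed_r: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "n_unique_a": self.n_unique_a,
            "n_unique_b": self.n_unique_b,
            "pearson_r": self.pearson_r,
            "r_p_value": self.r_p_value,
            "windowed_r": {str(k): v for k, v in self.windowed_r.items()},
        }


def _strand_convention(table: pd.DataFrame) -> str:
    strands = set(table["strand"].unique())
    return "merged" if strands <= {"."} else "stranded"


def join_sites(
    a: pd.DataFrame, b: pd.DataFrame, tolerance: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Match two site tables on (chrom, pos).

    Returns (shared, unique_a, unique_b); shared carries both
    frequencies as frequency_a / frequency_b. Tables must share a strand
    convention (both strand-merged or both stranded). With
    ``tolerance=1``, rows of b still unmatched after the exact join are
    retried at pos ± 1.
    """
    if len(a) and len(b) and _strand_convention(a) != _strand_convention(b):
        raise DataError("site tables use different strand-merge conventions")
    shared = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    matched_a = set(zip(shared["chrom"], shared["pos"]))
    matched_b = set(matched_a)
    if tolerance:
        rest_b = b[~pd.MultiIndex.from_frame(b[["chrom", "pos"]]).isin(matched_b)]
        for shift in (-1, 1):
            shifted = rest_b.assign(pos=rest_b["pos"] + shift)
            extra = a.merge(shifted, on=["chrom", "pos"], suffixes=("_a", "_b"))
            extra = extra[~pd.MultiIndex.from_frame(extra[["chrom", "pos"]]).isin(matched_a)]
            if len(extra):
                shared = pd.concat([shared, extra], ignore_index=True)
                matched_a |= set(zip(extra["chrom"], extra["pos"]))
                matched_b |= set(zip(extra["chrom"], extra["pos"] - shift))
    unique_a = a[~pd.MultiIndex.from_frame(a[["chrom", "pos"]]).isin(matched_a)]
    unique_b = b[~pd.MultiIndex.from_frame(b[["chrom", "pos"]]).isin(matched_b)]
    shared = shared.sort_values(["chrom", "pos"], ignore_index=True)
    return shared, unique_a.reset_index(drop=True), unique_b.reset_index(drop=True)


def concordance_report(
    a: pd.DataFrame,
    b: pd.DataFrame,
    window_sizes: tuple[int, ...] = (1_000, 10_000, 100_000),
    tolerance: int = 0,
) -> ConcordanceReport:
    """Full agreement report between two site tables."""
    shared, unique_a, unique_b = join_sites(a, b, tolerance=tolerance)
    if len(shared) < 3:
        raise DataError("fewer than 3 shared sites; correlation undefined")
    result = pearson_correlation(
        shared["frequency_a"].to_numpy(), shared["frequency_b"].to_numpy()
    )
    windowed: dict[int, float] = {}
    for w in window_sizes:
        grouped = (
            shared.assign(window=shared["pos"] // w)
            .groupby(["chrom", "window"])[["frequency_a", "frequency_b"]]
            .mean()
        )
        if len(grouped) >= 3 and grouped["frequency_a"].nunique() > 1 and (
            grouped["frequency_b"].nunique() > 1
        ):
            windowed[w] = pearson_correlation(
                grouped["frequency_a"].to_numpy(), grouped["frequency_b"].to_numpy()
            ).statistic
        else:
            windowed[w] = float("nan")
    return ConcordanceReport(
        n_shared=len(shared),
        n_unique_a=len(unique_a),
        n_unique_b=len(unique_b),
        pearson_r=result.statistic,
        r_p_value=result.p_value,
        windowed_r=windowed,
    )
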