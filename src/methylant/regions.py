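"""Region assignment and region-level methylation summaries.

Each CpG site receives exactly one label from {exon, intron, promoter,
TE, intergenic}, by a fixed precedence (exon > intron > promoter > TE >
intergenic) chosen so that the dominant genic methylation signal is
never masked by repeat copies nested inside genes. Exonic sites
additionally carry the exon's rank (1 = 5'-most exon of its gene).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel
from .intervals import flatten_intervals, interval_intersect, total_bp
from .stats import pearson_correlation

REGION_LABELS = ["exon", "intron", "promoter", "TE", "intergenic"]


@dataclass(frozen=True)
class RegionLabel:
    label: str
    exon_rank: int | None = None


class RegionIndex:
    """Interval indexes over genes, promoters and repeats for point queries."""

    def __init__(
        self,
        genes: list[GeneModel],
        repeats: pd.DataFrame,
        promoter_bp: int = 200,
        precedence: tuple[str, ...] = ("exon", "intron", "promoter", "TE"),
    ) -> None:
        self.promoter_bp = promoter_bp
        self.precedence = precedence
        self._exons: dict[str, IntervalTree] = {}
        self._introns: dict[str, IntervalTree] = {}
        self._promoters: dict[str, IntervalTree] = {}
        self._tes: dict[str, IntervalTree] = {}
        for g in genes:
            ex = self._exons.setdefault(g.chrom, IntervalTree())
            for rank, (s, e) in enumerate(g.exons, start=1):
                ex.addi(s, e, (g.gene_id, rank))
            intr = self._introns.setdefault(g.chrom, IntervalTree())
            for rank, (s, e) in enumerate(g.introns(), start=1):
                intr.addi(s, e, (g.gene_id, rank))
            ps, pe = g.promoter(promoter_bp)
            if pe > ps:
                self._promoters.setdefault(g.chrom, IntervalTree()).addi(
                    ps, pe, g.gene_id
                )
        for row in repeats.itertuples(index=False):
            self._tes.setdefault(row.chrom, IntervalTree()).addi(
                row.start, row.end, row.te_class
            )

    def label(self, chrom: str, pos: int) -> RegionLabel:
        for kind in self.precedence:
            tree = {
                "exon": self._exons,
                "intron": self._introns,
                "promoter": self._promoters,
                "TE": self._tes,
            }[kind].get(chrom)
            if tree is None:
                continue
            hits = tree[pos]
            if hits:
                if kind == "exon":
                    _, rank = min(hits, key=lambda iv: iv.begin).data
                    return RegionLabel("exon", rank)
                if kind == "intron":
                    return RegionLabel("intron")
                return RegionLabel(kind)
        return RegionLabel("intergenic")


def assign_region(
    chrom: str,
    pos: int,
    genes: list[GeneModel],
    repeats: pd.DataFrame,
    promoter_bp: int = 200,
) -> RegionLabel:
    """Label a single site (convenience wrapper; batch use goes through
    :class:`RegionIndex` / :func:`assign_regions`)."""
    return RegionIndex(genes, repeats, promoter_bp).label(chrom, pos)


def assign_regions(
    table: pd.DataFrame,
    genes: list[GeneModel],
    repeats: pd.DataFrame,
    promoter_bp: int = 200,
) -> pd.DataFrame:
    """Label every site of a site table; adds label and exon_rank columns."""
    index = RegionIndex(genes, repeats, promoter_bp)
    labels = np.empty(len(table), dtype=object)
    ranks = np.full(len(table), -1, dtype=np.int64)
    for i, (chrom, pos) in enumerate(zip(table["chrom"], table["pos"])):
        lab = index.label(chrom, pos)
        labels[i] = lab.label
        if lab.exon_rank is not None:
            ranks[i] = lab.exon_rank
    out = table.copy()
    out["label"] = labels
    out["exon_rank"] = ranks
    return out


def region_methylation_summary(
    table: pd.DataFrame,
    genes: list[GeneModel],
    repeats: pd.DataFrame,
    promoter_bp: int = 200,
) -> pd.DataFrame:
    """Per-region-label site counts, mean frequency and weighted methylation.

    Weighted methylation is sum(methylated reads) / sum(called reads)
    within the label; labels with no sites are flagged with n_sites = 0
    and undefined means.
    """
    labelled = assign_regions(table, genes, repeats, promoter_bp)
    rows = []
    for label in REGION_LABELS:
        sub = labelled[labelled["label"] == label]
        called = int(sub["called_reads"].sum())
        rows.append(
            {
                "label": label,
                "n_sites": len(sub),
                "mean_frequency": float(sub["frequency"].mean()) if len(sub) else np.nan,
                "weighted_methylation": (
                    float(sub["methylated_reads"].sum() / called) if called else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def exon_rank_profile(
    table: pd.DataFrame,
    genes: list[GeneModel],
    max_rank: int = 10,
    repeats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean methylation frequency by exon and intron rank (5'→3').

    Ranks above ``max_rank`` are pooled into the last bucket. Returns
    one row per (feature, rank) with site count, mean and SD of the
    per-site frequencies.
    """
    if repeats is None:
        repeats = pd.DataFrame(columns=["chrom", "start", "end", "te_class"])
    labelled = assign_regions(table, genes, repeats)
    rows = []
    for feature in ("exon", "intron"):
        if feature == "exon":
            sub = labelled[labelled["label"] == "exon"].copy()
            sub["rank"] = sub["exon_rank"].clip(upper=max_rank)
        else:
            sub = labelled[labelled["label"] == "intron"].copy()
            sub["rank"] = _intron_ranks(sub, genes).clip(upper=max_rank)
        for rank in range(1, max_rank + 1):
            vals = sub.loc[sub["rank"] == rank, "frequency"]
            rows.append(
                {
                    "feature": feature,
                    "rank": rank,
                    "n_sites": len(vals),
                    "mean_frequency": float(vals.mean()) if len(vals) else np.nan,
                    "sd_frequency": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _intron_ranks(sub: pd.DataFrame, genes: list[GeneModel]) -> pd.Series:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for rank, (s, e) in enumerate(g.introns(), start=1):
            tree.addi(s, e, rank)
    ranks = []
    for chrom, pos in zip(sub["chrom"], sub["pos"]):
        hits = trees.get(chrom, IntervalTree())[pos]
        ranks.append(min(iv.data for iv in hits) if hits else 1)
    return pd.Series(ranks, index=sub.index, dtype=np.int64)


def te_context_classify(
    repeats: pd.DataFrame,
    genes: list[GeneModel],
    table: pd.DataFrame | None = None,
    upstream_bp: int = 2_000,
) -> pd.DataFrame:
    """Assign each TE copy a genomic context and summarise methylation.

    Context is one of intronic / upstream2kb / intergenic, by majority
    base-pair overlap with ties broken toward the gene-proximal class
    (intronic first). When a site table is given, per-context (and
    per-TE-class) weighted methylation over sites inside TEs is added.
    """
    introns_by_chrom: dict[str, list[tuple[int, int]]] = {}
    upstream_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        introns_by_chrom.setdefault(g.chrom, []).extend(g.introns())
        if g.strand == "+":
            upstream_by_chrom.setdefault(g.chrom, []).append(
                (max(0, g.start - upstream_bp), g.start)
            )
        else:
            upstream_by_chrom.setdefault(g.chrom, []).append((g.end, g.end + upstream_bp))
    introns_by_chrom = {c: flatten_intervals(v) for c, v in introns_by_chrom.items()}
    upstream_by_chrom = {c: flatten_intervals(v) for c, v in upstream_by_chrom.items()}

    contexts = []
    for row in repeats.itertuples(index=False):
        te = [(row.start, row.end)]
        length = row.end - row.start
        bp_intron = total_bp(interval_intersect(te, introns_by_chrom.get(row.chrom, [])))
        bp_up = total_bp(interval_intersect(te, upstream_by_chrom.get(row.chrom, [])))
        bp_inter = length - bp_intron - bp_up
        best = max(
            [("intronic", bp_intron), ("upstream2kb", bp_up), ("intergenic", bp_inter)],
            key=lambda kv: (kv[1], -["intronic", "upstream2kb", "intergenic"].index(kv[0])),
        )
        contexts.append(best[0])
    out = repeats.copy()
    out["context"] = contexts

    if table is not None:
        meth = np.zeros(len(out))
        called = np.zeros(len(out))
        by_chrom = {c: s.sort_values("pos") for c, s in table.groupby("chrom")}
        for i, row in enumerate(out.itertuples(index=False)):
            sub = by_chrom.get(row.chrom)
            if sub is None:
                continue
            pos = sub["pos"].to_numpy()
            lo, hi = np.searchsorted(pos, [row.start, row.end])
            meth[i] = sub["methylated_reads"].to_numpy()[lo:hi].sum()
            called[i] = sub["called_reads"].to_numpy()[lo:hi].sum()
        out["methylated_reads"] = meth.astype(np.int64)
        out["called_reads"] = called.astype(np.int64)
    return out


def te_context_summary(classified: pd.DataFrame, by: str = "context") -> pd.DataFrame:
    """Weighted methylation per TE context (or per TE class)."""
    rows = []
    for key, sub in classified.groupby(by, sort=True):
        called = int(sub["called_reads"].sum())
        rows.append(
            {
                by: key,
                "n_te": len(sub),
                "weighted_methylation": (
                    float(sub["methylated_reads"].sum() / called) if called else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def rank_trend_slope(profile: pd.DataFrame, feature: str = "exon"):
    """OLS slope (with its test) of mean frequency against rank — used to
    check for, or rule out, a 5'→3' methylation gradient."""
    sub = profile[(profile["feature"] == feature) & (profile["n_sites"] > 0)]
    return pearson_correlation(sub["rank"].to_numpy(), sub["mean_frequency"].to_numpy())
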