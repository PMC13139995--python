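"""Gene-body and promoter methylation: weighted levels, binomial
classification, and metagene profiles.

Classification follows the two-stage construction of Takuno & Gaut's
binomial test as used across insect methylomes. Sites are first
binarised to methylated / unmethylated — by default a one-sided binomial
test of each site's methylated read count against a sequencing-error
rate ε, BH-corrected across sites. Each gene body (TSS–TTS) is then
tested for an excess of methylated sites over the genome-wide
methylated-site fraction p₀ with an upper-tail binomial test,
BH-corrected across genes within the stage: GBM if q < α, else UM;
genes with no covered sites are unclassified and excluded from the BH
family. Promoters (200 bp upstream of the TSS) run the same machinery
with one extra floor: a promoter only counts as methylated (PMG) if its
weighted methylation also exceeds 3%.

Both the binarisation mode (site-binomial vs. plain frequency cutoff)
and the per-gene counting unit (methylated sites, or raw reads) are
switchable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .errors import ConfigError, DataError
from .stats import bh_adjust, binomial_upper_tail

__all__ = [
    "ClassificationConfig",
    "weighted_region_methylation",
    "binarize_sites",
    "classify_gbm",
    "classify_promoters",
    "metaprofile",
    "class_overlap",
]


@dataclass(frozen=True)
class ClassificationConfig:
    """Parameters of the methylation classification for one stage.

    ``background_p`` is the genome-wide methylated-site fraction p₀ of
    the stage; None means: estimate it from the stage's own table (the
    fraction of binarised-methylated sites). ``site_mode`` selects the
    binarisation; ``gene_unit`` switches the per-gene binomial between
    counting methylated sites (default) and raw methylated reads.
    """

    alpha: float = 0.05
    background_p: float | None = None
    site_mode: str = "site-binomial"  # or "frequency-threshold"
    site_error_rate: float = 0.05
    site_freq_cutoff: float = 0.5
    upstream_bp: int = 4_000
    downstream_bp: int = 4_000
    promoter_bp: int = 200
    promoter_floor: float = 0.03
    gene_unit: str = "methylated-sites"  # or "reads"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.background_p is not None and not 0.0 <= self.background_p <= 1.0:
            raise ConfigError("background_p must be in [0, 1]")
        if self.site_mode not in ("site-binomial", "frequency-threshold"):
            raise ConfigError(f"unknown site_mode {self.site_mode!r}")
        if self.gene_unit not in ("methylated-sites", "reads"):
            raise ConfigError(f"unknown gene_unit {self.gene_unit!r}")


def weighted_region_methylation(
    table: pd.DataFrame, intervals: list[tuple[str, int, int]]
) -> tuple[int, int, int, float]:
    """Coverage-weighted methylation over a set of intervals.

    Returns (n_sites, sum methylated reads, sum called reads, weighted
    methylation); the level is NaN (flagged) when no reads cover the
    region.
    """
    if not intervals:
        raise DataError("weighted_region_methylation requires a non-empty region")
    n_sites = meth = called = 0
    by_chrom = {c: s.sort_values("pos") for c, s in table.groupby("chrom")}
    for chrom, start, end in intervals:
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [start, end])
        n_sites += hi - lo
        meth += int(sub["methylated_reads"].to_numpy()[lo:hi].sum())
        called += int(sub["called_reads"].to_numpy()[lo:hi].sum())
    weighted = meth / called if called else float("nan")
    return n_sites, meth, called, weighted


def binarize_sites(table: pd.DataFrame, config: ClassificationConfig) -> pd.Series:
    """Per-site methylated flag.

    site-binomial mode: one-sided binomial test of methylated reads out
    of called reads against the error rate ε, BH across all sites, flag
    where q < α. frequency-threshold mode: frequency >= cutoff.
    """
    if config.site_mode == "frequency-threshold":
        return (table["frequency"] >= config.site_freq_cutoff).rename("methylated")
    p = binomial_upper_tail(
        table["methylated_reads"].to_numpy(),
        table["called_reads"].to_numpy(),
        config.site_error_rate,
    )
    q = bh_adjust(np.atleast_1d(p))
    return pd.Series(q < config.alpha, index=table.index, name="methylated")


def _gene_intervals(
    genes: list[GeneModel], region: str, config: ClassificationConfig
) -> list[tuple[str, str, int, int]]:
    out = []
    for g in genes:
        if region == "body":
            s, e = g.start, g.end
        elif region == "promoter":
            s, e = g.promoter(config.promoter_bp)
        elif region == "upstream4k":
            s, e = (
                (max(0, g.start - config.upstream_bp), g.start)
                if g.strand == "+"
                else (g.end, g.end + config.upstream_bp)
            )
        elif region == "downstream4k":
            s, e = (
                (g.end, g.end + config.downstream_bp)
                if g.strand == "+"
                else (max(0, g.start - config.downstream_bp), g.start)
            )
        else:
            raise ConfigError(f"unknown region {region!r}")
        out.append((g.gene_id, g.chrom, s, e))
    return out


def _classify_regions(
    genes: list[GeneModel],
    table: pd.DataFrame,
    config: ClassificationConfig,
    region: str,
    positive_label: str,
    negative_label: str,
    floor: float | None = None,
) -> pd.DataFrame:
    flags = binarize_sites(table, config).to_numpy()
    p0 = config.background_p
    if p0 is None:
        if config.gene_unit == "reads":
            p0 = float(table["methylated_reads"].sum() / max(1, table["called_reads"].sum()))
        else:
            p0 = float(flags.mean()) if len(flags) else 0.0

    by_chrom: dict[str, dict[str, np.ndarray]] = {}
    for chrom, sub in table.assign(flag=flags).groupby("chrom"):
        sub = sub.sort_values("pos")
        by_chrom[str(chrom)] = {
            "pos": sub["pos"].to_numpy(),
            "flag": np.concatenate([[0], np.cumsum(sub["flag"].to_numpy())]),
            "meth": np.concatenate([[0], np.cumsum(sub["methylated_reads"].to_numpy())]),
            "called": np.concatenate([[0], np.cumsum(sub["called_reads"].to_numpy())]),
        }

    rows = []
    for gene_id, chrom, start, end in _gene_intervals(genes, region, config):
        data = by_chrom.get(chrom)
        if data is None:
            rows.append((gene_id, 0, 0, 0, 0))
            continue
        lo, hi = np.searchsorted(data["pos"], [start, end])
        rows.append(
            (
                gene_id,
                int(hi - lo),
                int(data["flag"][hi] - data["flag"][lo]),
                int(data["meth"][hi] - data["meth"][lo]),
                int(data["called"][hi] - data["called"][lo]),
            )
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "n_sites", "n_methylated_sites", "meth_reads", "called_reads"]
    )
    df["region"] = region
    df["weighted_methylation"] = np.where(
        df["called_reads"] > 0, df["meth_reads"] / df["called_reads"].replace(0, 1), np.nan
    )

    covered = df["n_sites"] > 0
    if config.gene_unit == "reads":
        k = df.loc[covered, "meth_reads"].to_numpy()
        n = df.loc[covered, "called_reads"].to_numpy()
    else:
        k = df.loc[covered, "n_methylated_sites"].to_numpy()
        n = df.loc[covered, "n_sites"].to_numpy()
    p = binomial_upper_tail(k, n, p0)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    q = bh_adjust(p) if p.size else p

    df["p_value"] = np.nan
    df["q_value"] = np.nan
    df.loc[covered, "p_value"] = p
    df.loc[covered, "q_value"] = q
    significant = covered & (df["q_value"] < config.alpha)
    if floor is not None:
        significant &= df["weighted_methylation"] > floor
    df["class"] = np.where(
        ~covered, "unclassified", np.where(significant, positive_label, negative_label)
    )
    df["background_p"] = p0
    return df[
        [
            "gene_id", "region", "n_sites", "n_methylated_sites", "meth_reads",
            "called_reads", "weighted_methylation", "p_value", "q_value", "class",
            "background_p",
        ]
    ]


def classify_gbm(
    genes: list[GeneModel], table: pd.DataFrame, config: ClassificationConfig
) -> pd.DataFrame:
    """Classify every gene body as GBM / UM / unclassified for one stage."""
    return _classify_regions(genes, table, config, "body", "GBM", "UM")


def classify_promoters(
    genes: list[GeneModel], table: pd.DataFrame, config: ClassificationConfig
) -> pd.DataFrame:
    """Classify promoters as PMG / PUM, with the weighted-methylation floor."""
    return _classify_regions(
        genes, table, config, "promoter", "PMG", "PUM", floor=config.promoter_floor
    )


def class_overlap(classifications: dict[str, pd.DataFrame], label: str = "GBM") -> pd.DataFrame:
    """Pairwise and overall sharing of a class across stages.

    Shared percentages are reported against each stage's own positive
    count (the set-intersection view of a Venn diagram).
    """
    sets = {
        stage: set(df.loc[df["class"] == label, "gene_id"])
        for stage, df in classifications.items()
    }
    common = set.intersection(*sets.values()) if sets else set()
    rows = []
    for stage, ids in sets.items():
        rows.append(
            {
                "stage": stage,
                f"n_{label}": len(ids),
                "n_shared_all": len(common),
                "shared_pct_of_stage": 100.0 * len(common) / len(ids) if ids else np.nan,
            }
        )
    return pd.DataFrame(rows)


def metaprofile(
    genes: list[GeneModel],
    table: pd.DataFrame,
    config: ClassificationConfig | None = None,
    n_body_bins: int = 40,
    flank_bin_bp: int = 200,
) -> pd.DataFrame:
    """Metagene methylation profile: fixed-width flanks, scaled body.

    The upstream flank (4 kb by default) is cut into fixed bins of
    ``flank_bin_bp``; bin 1 abuts the TSS and bin indices grow away from
    the gene. The body is scaled per gene into ``n_body_bins`` bins
    (bin 1 at the TSS end); the downstream flank mirrors the upstream
    one from the TTS outward. All coordinates are strand-aware: upstream
    means 5' of the TSS on the gene's own strand. Bin levels are
    coverage-weighted and pooled across genes; genes shorter than
    ``n_body_bins`` bp simply spread their sites over proportional bins.

    Returns one row per bin with a plotting ``order`` column running
    5'→3' (upstream reversed, then body, then downstream).
    """
    config = config or ClassificationConfig()
    n_flank = config.upstream_bp // flank_bin_bp
    meth = {
        ("upstream", i): 0 for i in range(1, n_flank + 1)
    } | {("body", i): 0 for i in range(1, n_body_bins + 1)} | {
        ("downstream", i): 0 for i in range(1, n_flank + 1)
    }
    called = dict.fromkeys(meth, 0)
    sites = dict.fromkeys(meth, 0)

    by_chrom = {c: s.sort_values("pos") for c, s in table.groupby("chrom")}
    for g in genes:
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        span_lo = g.start - config.upstream_bp
        span_hi = g.end + config.downstream_bp
        lo, hi = np.searchsorted(pos, [span_lo, span_hi])
        if hi == lo:
            continue
        p = pos[lo:hi]
        m = sub["methylated_reads"].to_numpy()[lo:hi]
        c = sub["called_reads"].to_numpy()[lo:hi]
        for pi, mi, ci in zip(p, m, c):
            key = _profile_bin(g, int(pi), config, n_body_bins, flank_bin_bp, n_flank)
            if key is None:
                continue
            meth[key] += int(mi)
            called[key] += int(ci)
            sites[key] += 1

    rows = []
    order = 0
    for segment, indices in (
        ("upstream", range(n_flank, 0, -1)),
        ("body", range(1, n_body_bins + 1)),
        ("downstream", range(1, n_flank + 1)),
    ):
        for i in indices:
            key = (segment, i)
            rows.append(
                {
                    "order": order,
                    "segment": segment,
                    "bin": i,
                    "n_sites": sites[key],
                    "weighted_methylation": (
                        meth[key] / called[key] if called[key] else np.nan
                    ),
                }
            )
            order += 1
    return pd.DataFrame(rows)


def _profile_bin(
    g: GeneModel,
    pos: int,
    config: ClassificationConfig,
    n_body_bins: int,
    flank_bin_bp: int,
    n_flank: int,
) -> tuple[str, int] | None:
    """Map a plus-strand position to a strand-aware profile bin."""
    if g.start <= pos < g.end:
        rel = (pos - g.start) / g.length if g.strand == "+" else (g.end - 1 - pos) / g.length
        return ("body", min(n_body_bins, int(rel * n_body_bins) + 1))
    if g.strand == "+":
        if pos < g.start:  # upstream of TSS
            dist = g.start - pos
            segment = "upstream"
        else:  # past the TTS
            dist = pos - g.end + 1
            segment = "downstream"
    else:
        if pos >= g.end:  # upstream of a minus-strand TSS
            dist = pos - g.end + 1
            segment = "upstream"
        else:
            dist = g.start - pos
            segment = "downstream"
    bin_idx = (dist - 1) // flank_bin_bp + 1
    if bin_idx < 1 or bin_idx > n_flank:
        return None
    return (segment, bin_idx)
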