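"""Ground-truthed methylome simulator.

Generates a small multi-chromosome genome with non-overlapping annotated
genes, transposable-element copies clustered into planted high-density
islands, per-CpG coverage and methylation with a low (~3%) background
and elevated methylation inside a planted set of gene bodies and
promoters, per-read log-likelihood-ratio calls consistent with the site
truth, and gene expression counts whose log level is linear in gene-body
methylation. Every planted quantity is recorded in a
:class:`GroundTruth` manifest so recovery can be scored exactly.

CpG sites live on a regular grid (only positions and counts matter
downstream; no sequence is simulated). Site methylation probability is a
two-level step function (background vs. planted regions) with
beta-distributed per-site jitter, mimicking the overdispersion of real
methylomes. All randomness flows from per-purpose streams keyed on
(seed, stream, chromosome), so identical config + seed reproduces
byte-identical outputs and partial regeneration is stable.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    write_chrom_sizes,
    write_gff3,
    write_repeats_bed,
)
from .errors import ConfigError, PackingError
from .site_io import make_site_table, write_cpg_index_bed, write_site_table

TE_CLASSES = ["DNA", "LINE", "LTR", "SINE"]
TE_CLASS_WEIGHTS = [0.35, 0.30, 0.20, 0.15]

# stream ids for the keyed random streams
_S_GENES, _S_TES, _S_SITES, _S_READS, _S_EXPR, _S_PLANT = range(6)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of the simulated methylome study.

    Defaults describe a desk-scale stand-in for an ant genome: two 2 Mb
    chromosomes, 300 genes of ~5 kb, TE islands of 200 kb at 60% TE
    density over a 10% background (genome TE fraction ~0.25), 3%
    background CpG methylation with 30% of genes planted as gene-body
    methylated at a 30% per-site level, ~30x coverage, and 22 expression
    samples whose log expression tracks gene methylation.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 300
    gene_length_mean: int = 5_000
    exons_per_gene_mean: float = 4.0
    n_te_islands_per_chrom: int = 3
    island_width: int = 200_000
    te_density_island: float = 0.60
    te_density_background: float = 0.10
    p_background: float = 0.03
    gbm_fraction: float = 0.30
    p_gbm_site: float = 0.30
    pmg_fraction: float = 0.07
    p_pmg_site: float = 0.50
    coverage_mean: float = 30.0
    llr_mu: float = 5.0
    llr_sigma: float = 2.0
    cpg_spacing: int = 50
    beta_concentration: float = 100.0
    promoter_bp: int = 200
    expr_intercept: float = 3.0
    expr_slope: float = 2.1
    expr_noise_sd: float = 0.7
    n_expression_samples: int = 22
    island_grid_bp: int = 50_000
    te_length_mean: float = 800.0

    def __post_init__(self) -> None:
        fractions = {
            "te_density_island": self.te_density_island,
            "te_density_background": self.te_density_background,
            "p_background": self.p_background,
            "gbm_fraction": self.gbm_fraction,
            "p_gbm_site": self.p_gbm_site,
            "pmg_fraction": self.pmg_fraction,
            "p_pmg_site": self.p_pmg_site,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.p_gbm_site <= self.p_background:
            raise ConfigError("p_gbm_site must exceed p_background")
        for name in ("n_chrom", "chrom_length", "cpg_spacing", "island_grid_bp"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_genes < 0 or self.n_te_islands_per_chrom < 0:
            raise ConfigError("feature counts must be non-negative")
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be positive")
        if self.beta_concentration <= 0:
            raise ConfigError("beta_concentration must be positive")

    def rng(self, stream: int, index: int = 0) -> np.random.Generator:
        """A generator keyed on (seed, stream, index)."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), int(stream), int(index)])
        )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def chrom_sizes(self) -> dict[str, int]:
        return {name: self.chrom_length for name in self.chrom_names()}


@dataclass
class GroundTruth:
    """Simulation manifest: everything the recovery tests score against."""

    gbm_gene_ids: set[str]
    pmg_gene_ids: set[str]
    island_intervals: list[tuple[str, int, int]]
    expr_slope: float
    expr_noise_sd: float
    site_truth: pd.DataFrame | None = None  # chrom, pos, p_true
    gene_methylation: pd.Series | None = field(default=None, repr=False)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "gbm_gene_ids": sorted(self.gbm_gene_ids),
            "pmg_gene_ids": sorted(self.pmg_gene_ids),
            "island_intervals": [list(iv) for iv in self.island_intervals],
            "expr_slope": self.expr_slope,
            "expr_noise_sd": self.expr_noise_sd,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            gbm_gene_ids=set(payload["gbm_gene_ids"]),
            pmg_gene_ids=set(payload["pmg_gene_ids"]),
            island_intervals=[tuple(iv) for iv in payload["island_intervals"]],
            expr_slope=payload["expr_slope"],
            expr_noise_sd=payload["expr_noise_sd"],
        )


def _place_genes(config: SimulationConfig) -> list[GeneModel]:
    chroms = config.chrom_names()
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1
    margin = 2_200  # inter-gene gap >= 2 margins: promoter + 2 kb upstream clearance
    genes: list[GeneModel] = []
    gene_no = 0
    for ci, (chrom, n_c) in enumerate(zip(chroms, per_chrom)):
        if n_c == 0:
            continue
        rng = config.rng(_S_GENES, ci)
        slot = config.chrom_length // n_c
        max_len = int(1.5 * config.gene_length_mean)
        if max_len + 2 * margin > slot:
            raise PackingError(
                f"{n_c} genes of up to {max_len} bp plus {margin} bp flanks do not "
                f"fit in {config.chrom_length} bp of {chrom} "
                f"(slot {slot} bp; reduce n_genes or gene_length_mean)"
            )
        for j in range(n_c):
            length = int(
                np.clip(
                    round(rng.normal(config.gene_length_mean, 0.15 * config.gene_length_mean)),
                    max(200, config.gene_length_mean // 2),
                    max_len,
                )
            )
            lo = j * slot + margin
            hi = (j + 1) * slot - margin - length
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _split_exons(rng, start, start + length, config.exons_per_gene_mean)
            genes.append(
                GeneModel(
                    gene_id=f"g{gene_no:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=start + length,
                    exons=exons,
                )
            )
            gene_no += 1
    return genes


def _split_exons(
    rng: np.random.Generator, start: int, end: int, exons_mean: float
) -> list[tuple[int, int]]:
    length = end - start
    n_exons = 1 + int(rng.poisson(max(0.0, exons_mean - 1.0)))
    n_exons = max(1, min(n_exons, (length // 40 + 1) // 2))
    n_pieces = 2 * n_exons - 1
    if n_pieces == 1:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_pieces - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    return [
        (start + int(bounds[i]), start + int(bounds[i + 1]))
        for i in range(0, n_pieces, 2)
    ]


def _place_islands(config: SimulationConfig) -> list[tuple[str, int, int]]:
    """Plant TE islands aligned to the analysis window grid."""
    if config.n_te_islands_per_chrom == 0:
        return []
    grid = config.island_grid_bp
    width_windows = max(1, math.ceil(config.island_width / grid))
    n_windows = config.chrom_length // grid
    part = n_windows // config.n_te_islands_per_chrom
    # two background windows on each side keep neighbouring islands
    # separated by >= 4 windows, so each is identifiable as its own
    # segment rather than merging across a narrow dip
    gap = 2
    if part < width_windows + 2 * gap:
        raise PackingError(
            f"{config.n_te_islands_per_chrom} islands of {width_windows} windows "
            f"need at least {(width_windows + 2 * gap) * config.n_te_islands_per_chrom} "
            f"windows of {grid} bp; chromosome has {n_windows}"
        )
    islands: list[tuple[str, int, int]] = []
    for ci, chrom in enumerate(config.chrom_names()):
        rng = config.rng(_S_TES, ci)
        for k in range(config.n_te_islands_per_chrom):
            lo = k * part + gap
            hi = (k + 1) * part - width_windows - gap
            w0 = int(rng.integers(lo, hi + 1))
            islands.append((chrom, w0 * grid, (w0 + width_windows) * grid))
    return islands


def _fill_tes(
    rng: np.random.Generator, chrom: str, start: int, end: int, density: float,
    mean_len: float,
) -> list[tuple[str, int, int, str]]:
    if density <= 0 or end - start < 50:
        return []
    mean_gap = mean_len * (1.0 - density) / max(density, 1e-9)
    out = []
    pos = start + rng.exponential(mean_gap)
    while pos < end:
        length = max(50.0, rng.exponential(mean_len))
        te_end = min(end, pos + length)
        if te_end - pos >= 50:
            klass = TE_CLASSES[int(rng.choice(len(TE_CLASSES), p=TE_CLASS_WEIGHTS))]
            out.append((chrom, int(pos), int(te_end), klass))
        pos = te_end + rng.exponential(mean_gap)
    return out


def generate_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], pd.DataFrame, GroundTruth]:
    """Generate genes, repeats and the ground-truth manifest.

    Gene bodies never overlap; TE copies are laid down at the island
    density inside planted islands and the background density elsewhere.
    """
    genes = _place_genes(config)
    islands = _place_islands(config)

    te_rows: list[tuple[str, int, int, str]] = []
    for ci, chrom in enumerate(config.chrom_names()):
        rng = config.rng(_S_TES, config.n_chrom + ci)
        chrom_islands = sorted(
            (s, e) for c, s, e in islands if c == chrom
        )
        cursor = 0
        for s, e in chrom_islands:
            te_rows += _fill_tes(
                rng, chrom, cursor, s, config.te_density_background, config.te_length_mean
            )
            te_rows += _fill_tes(
                rng, chrom, s, e, config.te_density_island, config.te_length_mean
            )
            cursor = e
        te_rows += _fill_tes(
            rng, chrom, cursor, config.chrom_length,
            config.te_density_background, config.te_length_mean,
        )
    repeats = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "te_class"])
    repeats = repeats.sort_values(["chrom", "start", "end"], ignore_index=True)

    rng = config.rng(_S_PLANT)
    ids = [g.gene_id for g in genes]
    n_gbm = int(math.floor(config.gbm_fraction * len(ids)))
    n_pmg = int(math.floor(config.pmg_fraction * len(ids)))
    gbm = set(rng.choice(ids, size=n_gbm, replace=False)) if n_gbm else set()
    pmg = set(rng.choice(ids, size=n_pmg, replace=False)) if n_pmg else set()

    truth = GroundTruth(
        gbm_gene_ids=gbm,
        pmg_gene_ids=pmg,
        island_intervals=sorted(islands),
        expr_slope=config.expr_slope,
        expr_noise_sd=config.expr_noise_sd,
    )
    return genes, repeats, truth


def cpg_positions(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Regular-grid CpG positions per chromosome."""
    offset = config.cpg_spacing // 2
    grid = np.arange(offset, config.chrom_length - 1, config.cpg_spacing, dtype=np.int64)
    return {chrom: grid.copy() for chrom in config.chrom_names()}


def _site_probabilities(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: GroundTruth,
    positions: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    out = {}
    for chrom, pos in positions.items():
        p = np.full(pos.size, config.p_background)
        out[chrom] = p
    for g in genes:
        pos = positions[g.chrom]
        if g.gene_id in truth.gbm_gene_ids:
            lo, hi = np.searchsorted(pos, [g.start, g.end])
            out[g.chrom][lo:hi] = config.p_gbm_site
    for g in genes:  # promoter planting after bodies: the promoter call is its own axis
        if g.gene_id in truth.pmg_gene_ids:
            pos = positions[g.chrom]
            ps, pe = g.promoter(config.promoter_bp)
            lo, hi = np.searchsorted(pos, [ps, pe])
            out[g.chrom][lo:hi] = config.p_pmg_site
    return out


def generate_site_calls(
    genes: list[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    emit_reads: bool = True,
) -> tuple[pd.DataFrame | None, pd.DataFrame]:
    """Draw per-site coverage and methylation, optionally with reads.

    Per site, the true methylation probability is the planted step
    function jittered by a beta draw; coverage is Poisson; each read is
    Bernoulli(p_site) and, when reads are emitted, carries an LLR drawn
    from Normal(+llr_mu, llr_sigma) if methylated and Normal(-llr_mu,
    llr_sigma) otherwise. The returned site table is the exact
    aggregation of the read-level truth. Zero-coverage sites are
    unobserved and omitted. ``truth.site_truth`` is populated with the
    per-site probabilities.
    """
    positions = cpg_positions(config)
    probs = _site_probabilities(config, genes, truth, positions)
    c = config.beta_concentration

    read_frames: list[pd.DataFrame] = []
    site_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    read_no = 0
    for ci, chrom in enumerate(config.chrom_names()):
        pos = positions[chrom]
        p_base = probs[chrom]
        rng = config.rng(_S_SITES, ci)
        with np.errstate(divide="ignore"):
            p_site = np.where(
                (p_base > 0) & (p_base < 1),
                rng.beta(np.maximum(c * p_base, 1e-9), np.maximum(c * (1 - p_base), 1e-9)),
                p_base,
            )
        coverage = rng.poisson(config.coverage_mean, size=pos.size)
        truth_frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "p_true": p_site}))

        if emit_reads:
            rrng = config.rng(_S_READS, ci)
            site_idx = np.repeat(np.arange(pos.size), coverage)
            state = rrng.random(site_idx.size) < p_site[site_idx]
            llr = rrng.normal(
                np.where(state, config.llr_mu, -config.llr_mu),
                config.llr_sigma,
            )
            meth = np.bincount(site_idx, weights=state, minlength=pos.size).astype(np.int64)
            read_frames.append(
                pd.DataFrame(
                    {
                        "chromosome": chrom,
                        "strand": "+",
                        "start": pos[site_idx],
                        "end": pos[site_idx] + 1,
                        "read_name": [
                            f"r{read_no + i:08d}" for i in range(site_idx.size)
                        ],
                        "log_lik_ratio": llr,
                        "log_lik_methylated": llr,
                        "log_lik_unmethylated": 0.0,
                        "num_calling_strands": 1,
                        "num_motifs": 1,
                        "sequence": "ATCGAT",
                    }
                )
            )
            read_no += site_idx.size
        else:
            meth = rng.binomial(coverage, p_site).astype(np.int64)

        observed = coverage > 0
        site_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[observed],
                    "strand": "+",
                    "called_reads": coverage[observed].astype(np.int64),
                    "methylated_reads": meth[observed],
                }
            )
        )

    truth.site_truth = pd.concat(truth_frames, ignore_index=True)
    site_table = make_site_table(pd.concat(site_frames, ignore_index=True))
    reads = pd.concat(read_frames, ignore_index=True) if emit_reads else None
    return reads, site_table


def gene_body_methylation(
    genes: list[GeneModel], site_table: pd.DataFrame
) -> pd.Series:
    """Per-gene weighted body methylation from a site table."""
    values = {}
    by_chrom = {
        chrom: sub.sort_values("pos") for chrom, sub in site_table.groupby("chrom")
    }
    for g in genes:
        sub = by_chrom.get(g.chrom)
        if sub is None:
            values[g.gene_id] = 0.0
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [g.start, g.end])
        called = sub["called_reads"].to_numpy()[lo:hi].sum()
        meth = sub["methylated_reads"].to_numpy()[lo:hi].sum()
        values[g.gene_id] = float(meth / called) if called else 0.0
    return pd.Series(values, name="gene_methylation")


def generate_expression(
    genes: list[GeneModel],
    truth: GroundTruth,
    site_table: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Plant a linear log-expression ~ methylation relationship.

    log(1 + FPKM_true) = intercept + slope * m_gene + Normal(0, sd); raw
    counts are back-computed per sample from FPKM_true through the FPKM
    formula with library sizes drawn uniformly in [8e6, 12e6] reads.
    Returns (counts frame indexed by gene, gene length series).
    """
    if config.n_expression_samples < 2:
        raise ConfigError("n_expression_samples must be >= 2")
    rng = config.rng(_S_EXPR)
    m = gene_body_methylation(genes, site_table)
    truth.gene_methylation = m
    noise = rng.normal(0.0, config.expr_noise_sd, size=len(genes)) if (
        config.expr_noise_sd > 0
    ) else np.zeros(len(genes))
    log_expr = config.expr_intercept + config.expr_slope * m.to_numpy() + noise
    fpkm_true = np.expm1(np.clip(log_expr, 0.0, 50.0))
    lengths = pd.Series(
        {g.gene_id: g.length for g in genes}, name="length", dtype=np.int64
    )
    totals = rng.integers(8_000_000, 12_000_000, size=config.n_expression_samples)
    counts = np.rint(
        np.outer(fpkm_true * lengths.to_numpy(), totals) / 1e9
    ).astype(np.int64)
    cols = [f"sample_{i + 1:02d}" for i in range(config.n_expression_samples)]
    counts_df = pd.DataFrame(counts, index=lengths.index, columns=cols)
    counts_df.index.name = "gene_id"
    return counts_df, lengths


def simulate_dataset(config: SimulationConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Run the full generator and serialise every artifact.

    Writes GFF3 genes, repeat BED6, island BED3, genome CpG index BED,
    per-read call TSV, site TSV (exact truth aggregation), counts TSV,
    chromosome sizes, and the ground-truth JSON manifest. Returns a map
    of artifact name → path.
    """
    os.makedirs(outdir, exist_ok=True)
    genes, repeats, truth = generate_annotation(config)
    reads, sites = generate_site_calls(genes, truth, config, emit_reads=True)
    counts, lengths = generate_expression(genes, truth, sites, config)

    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("genes_gff3", "genes.gff3"),
        ("repeats_bed", "repeats.bed"),
        ("islands_bed", "true_islands.bed"),
        ("cpg_index_bed", "cpg_index.bed"),
        ("reads_tsv", "reads.tsv"),
        ("sites_tsv", "sites.tsv"),
        ("counts_tsv", "counts.tsv"),
        ("chrom_sizes", "chrom_sizes.tsv"),
        ("truth_json", "truth.json"),
    ]}
    write_gff3(genes, paths["genes_gff3"])
    write_repeats_bed(repeats, paths["repeats_bed"])
    with open(paths["islands_bed"], "w") as fh:
        for chrom, s, e in truth.island_intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    write_cpg_index_bed(cpg_positions(config), paths["cpg_index_bed"])
    reads.to_csv(paths["reads_tsv"], sep="\t", index=False, float_format="%.4f")
    write_site_table(sites, paths["sites_tsv"])
    out_counts = counts.copy()
    out_counts.insert(0, "length", lengths)
    out_counts.to_csv(paths["counts_tsv"], sep="\t")
    write_chrom_sizes(config.chrom_sizes(), paths["chrom_sizes"])
    truth.to_json(paths["truth_json"])
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
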