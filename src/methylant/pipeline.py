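"""End-to-end orchestration: one config, deterministic seeding, a run
report with per-stage counts and artifact checksums.

Stages run in dependency order: simulate? → aggregate → filter →
regions → gene-meth → promoters → islands → concordance? → expression?.
With the simulate stage enabled every downstream input comes from the
generator; otherwise the config must point at existing files, which is
checked before any stage runs. Identical config + seed reproduces
byte-identical outputs (reports contain no timestamps; all floats are
written with fixed formatting).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import tomllib
from dataclasses import dataclass, field

import pandas as pd

from .annotation import read_chrom_sizes, read_gff3, read_repeats_bed, write_bed3
from .concordance import concordance_report
from .errors import ConfigError
from .expression import (
    compare_expression_by_class,
    compute_fpkm,
    methylation_expression_correlation,
    read_counts,
)
from .gene_methylation import (
    ClassificationConfig,
    binarize_sites,
    classify_gbm,
    classify_promoters,
    metaprofile,
)
from .regions import region_methylation_summary
from .simulate import SimulationConfig, simulate_dataset
from .site_io import (
    aggregate_frequencies,
    filter_low_call_sequences,
    filter_sites,
    read_cpg_index_bed,
    read_read_level_calls,
    read_site_table,
    write_site_table,
)
from .te_islands import call_te_islands, compare_island_methylation, te_signal

log = logging.getLogger("methylant")

ALL_STAGES = (
    "simulate", "aggregate", "filter", "regions", "gene_meth", "promoters",
    "islands", "concordance", "expression",
)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "methylant_run"
    stages: tuple[str, ...] = ALL_STAGES
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    llr_threshold: float = 2.0
    min_coverage: int = 10
    min_call_fraction: float = 0.10
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    window_bp: int = 50_000
    penalty: float = 40.0
    drop_cutoff: float = 0.2
    penalty_scale: str = "variance"
    expression_transform: str = "identity"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_toml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known_sections = {"run", "simulate", "filter", "classify", "islands", "inputs", "expression"}
        unknown = set(raw) - known_sections
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

        def take(section: str, allowed: set[str]) -> dict:
            d = raw.get(section, {})
            extra = set(d) - allowed
            if extra:
                raise ConfigError(f"unknown key(s) in [{section}]: {sorted(extra)}")
            return d

        run = take("run", {"seed", "outdir", "stages"})
        filt = take("filter", {"llr_threshold", "min_coverage", "min_call_fraction"})
        classify = take(
            "classify",
            {f.name for f in dataclasses.fields(ClassificationConfig)},
        )
        islands = take("islands", {"window_bp", "penalty", "drop_cutoff", "penalty_scale"})
        expression = take("expression", {"transform"})
        inputs = take(
            "inputs",
            {"reads_tsv", "sites_tsv", "sites_b_tsv", "genes_gff3", "repeats_bed",
             "cpg_index_bed", "counts_tsv", "chrom_sizes"},
        )

        sim_cfg = None
        if "simulate" in raw:
            sim_raw = take(
                "simulate", {f.name for f in dataclasses.fields(SimulationConfig)}
            )
            sim_raw.setdefault("seed", run.get("seed", 0))
            sim_cfg = SimulationConfig(**sim_raw)

        stages = tuple(run.get("stages", ALL_STAGES))
        if sim_cfg is None:
            stages = tuple(s for s in stages if s != "simulate")
        return cls(
            seed=run.get("seed", 0),
            outdir=run.get("outdir", "methylant_run"),
            stages=stages,
            simulate=sim_cfg,
            inputs=dict(inputs),
            classification=ClassificationConfig(**classify),
            expression_transform=expression.get("transform", "identity"),
            **filt,
            **islands,
        )


@dataclass
class RunReport:
    seed: int
    stages: list[str]
    counts: dict[str, dict] = field(default_factory=dict)
    summary: dict[str, float | int] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


_STAGE_NEEDS = {
    "aggregate": ["reads_tsv"],
    "filter": ["cpg_index_bed"],
    "regions": ["genes_gff3", "repeats_bed"],
    "gene_meth": ["genes_gff3"],
    "promoters": ["genes_gff3"],
    "islands": ["repeats_bed", "chrom_sizes"],
    "concordance": ["sites_tsv"],
    "expression": ["counts_tsv", "genes_gff3"],
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages and write every artifact under outdir."""
    os.makedirs(config.outdir, exist_ok=True)
    enabled = [s for s in ALL_STAGES if s in config.stages]
    report = RunReport(seed=config.seed, stages=enabled)
    inputs = dict(config.inputs)

    if "simulate" not in enabled:
        missing = []
        for stage in enabled:
            for need in _STAGE_NEEDS.get(stage, []):
                path = inputs.get(need)
                if path is None or not os.path.exists(path):
                    missing.append((stage, need))
        if missing:
            raise ConfigError(
                "missing inputs for enabled stages (enable simulate or provide paths): "
                + ", ".join(f"{stage} needs {need}" for stage, need in missing)
            )

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    if "simulate" in enabled:
        if config.simulate is None:
            raise ConfigError("simulate stage enabled but no [simulate] section given")
        log.info("stage simulate: seed=%d", config.simulate.seed)
        paths = simulate_dataset(config.simulate, os.path.join(config.outdir, "sim"))
        inputs.update(paths)
        report.counts["simulate"] = {"artifacts": len(paths)}
        report.artifacts.update(paths)

    site_table: pd.DataFrame | None = None
    if "aggregate" in enabled:
        calls = read_read_level_calls(inputs["reads_tsv"])
        site_table = aggregate_frequencies(calls, llr_threshold=config.llr_threshold)
        write_site_table(site_table, out("sites_called.tsv"))
        report.artifacts["sites_called"] = out("sites_called.tsv")
        report.counts["aggregate"] = {
            "read_records": len(calls), "sites": len(site_table),
            "llr_threshold": config.llr_threshold,
        }
        log.info("stage aggregate: %d records -> %d sites", len(calls), len(site_table))
    elif inputs.get("sites_tsv"):
        site_table = read_site_table(inputs["sites_tsv"])

    if "filter" in enabled and site_table is not None:
        filtered, n_low_cov = filter_sites(site_table, config.min_coverage)
        index = read_cpg_index_bed(inputs["cpg_index_bed"])
        filtered, dropped = filter_low_call_sequences(
            filtered, index, config.min_call_fraction
        )
        write_site_table(filtered, out("sites_filtered.tsv"))
        report.artifacts["sites_filtered"] = out("sites_filtered.tsv")
        report.counts["filter"] = {
            "input_sites": len(site_table),
            "removed_low_coverage": n_low_cov,
            "dropped_sequences": sorted(dropped),
            "output_sites": len(filtered),
        }
        log.info("stage filter: %d -> %d sites", len(site_table), len(filtered))
        site_table = filtered

    genes = read_gff3(inputs["genes_gff3"]) if inputs.get("genes_gff3") else None
    repeats = (
        read_repeats_bed(inputs["repeats_bed"]) if inputs.get("repeats_bed") else None
    )

    if "regions" in enabled and site_table is not None:
        summary = region_methylation_summary(site_table, genes, repeats,
                                             config.classification.promoter_bp)
        summary.to_csv(out("region_summary.tsv"), sep="\t", index=False,
                       float_format="%.6g")
        report.artifacts["region_summary"] = out("region_summary.tsv")
        report.counts["regions"] = {
            row["label"]: int(row["n_sites"]) for _, row in summary.iterrows()
        }
        log.info("stage regions: %s", report.counts["regions"])

    gbm = None
    if "gene_meth" in enabled and site_table is not None:
        gbm = classify_gbm(genes, site_table, config.classification)
        gbm.to_csv(out("gene_methylation.tsv"), sep="\t", index=False,
                   float_format="%.6g")
        profile = metaprofile(genes, site_table, config.classification)
        profile.to_csv(out("metaprofile.tsv"), sep="\t", index=False,
                       float_format="%.6g")
        report.artifacts["gene_methylation"] = out("gene_methylation.tsv")
        report.artifacts["metaprofile"] = out("metaprofile.tsv")
        counts = gbm["class"].value_counts().to_dict()
        report.counts["gene_meth"] = {k: int(v) for k, v in counts.items()}
        log.info("stage gene_meth: %s", report.counts["gene_meth"])

    if "promoters" in enabled and site_table is not None:
        prom = classify_promoters(genes, site_table, config.classification)
        prom.to_csv(out("promoter_methylation.tsv"), sep="\t", index=False,
                    float_format="%.6g")
        report.artifacts["promoter_methylation"] = out("promoter_methylation.tsv")
        counts = prom["class"].value_counts().to_dict()
        report.counts["promoters"] = {k: int(v) for k, v in counts.items()}
        log.info("stage promoters: %s", report.counts["promoters"])

    if "islands" in enabled:
        sizes = read_chrom_sizes(inputs["chrom_sizes"])
        signals = te_signal(sizes, repeats, config.window_bp)
        islands = call_te_islands(
            signals, penalty=config.penalty, drop_cutoff=config.drop_cutoff,
            penalty_scale=config.penalty_scale,
        )
        write_bed3(
            list(zip(islands["chrom"], islands["start"], islands["end"])),
            out("te_islands.bed"),
            scores=list(islands["mean_te_fraction"]),
        )
        report.artifacts["te_islands"] = out("te_islands.bed")
        report.counts["islands"] = {"n_islands": len(islands)}
        if site_table is not None and len(islands):
            cmp = compare_island_methylation(site_table, islands)
            report.counts["islands"].update(
                {
                    "wilcoxon_W": cmp["test"].statistic,
                    "p_value": cmp["test"].p_value,
                    "median_inside": cmp["median_inside"],
                    "median_outside": cmp["median_outside"],
                }
            )
        log.info("stage islands: %s", report.counts["islands"])

    if "concordance" in enabled and site_table is not None:
        other_path = inputs.get("sites_b_tsv") or inputs.get("sites_tsv")
        other = read_site_table(other_path)
        rep = concordance_report(site_table, other)
        with open(out("concordance.json"), "w") as fh:
            json.dump(rep.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        report.artifacts["concordance"] = out("concordance.json")
        report.counts["concordance"] = {
            "n_shared": rep.n_shared, "pearson_r": round(rep.pearson_r, 6),
        }
        log.info("stage concordance: r=%.3f over %d sites", rep.pearson_r, rep.n_shared)

    if "expression" in enabled and gbm is not None:
        counts_df, lengths = read_counts(inputs["counts_tsv"])
        fpkm = compute_fpkm(counts_df, lengths)
        by_class = compare_expression_by_class(fpkm, gbm)
        corr = methylation_expression_correlation(
            fpkm, gbm, transform=config.expression_transform
        )
        payload = {
            "rank_sum_W": by_class["test"].statistic,
            "rank_sum_p": by_class["test"].p_value,
            "median_GBM": by_class["median_GBM"],
            "median_UM": by_class["median_UM"],
            "pearson_r": corr.statistic,
            "pearson_p": corr.p_value,
            "transform": config.expression_transform,
        }
        with open(out("expression_report.json"), "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        report.artifacts["expression_report"] = out("expression_report.json")
        report.counts["expression"] = {
            "n_genes": len(fpkm), "pearson_r": round(corr.statistic, 6),
        }
        log.info("stage expression: r=%.3f", corr.statistic)

    if site_table is not None:
        flags = binarize_sites(site_table, config.classification)
        report.summary = {
            "total_called_sites": int(len(site_table)),
            "methylated_sites": int(flags.sum()),
            "mean_methylation": round(
                float(
                    site_table["methylated_reads"].sum()
                    / max(1, site_table["called_reads"].sum())
                ),
                6,
            ),
        }
        if gbm is not None:
            vc = gbm["class"].value_counts()
            report.summary["GBM_genes"] = int(vc.get("GBM", 0))
            report.summary["UM_genes"] = int(vc.get("UM", 0))

    report.checksums = {
        name: _sha256(path)
        for name, path in sorted(report.artifacts.items())
        if os.path.isfile(path)
    }
    report.to_json(os.path.join(config.outdir, "run_report.json"))
    return report


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[methylant %(levelname)s] %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
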