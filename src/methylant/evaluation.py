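"""Recovery scoring of the pipeline against simulated ground truth.

Each function generates a dataset under a given configuration, runs the
relevant stage, and scores the result against the
:class:`~methylant.simulate.GroundTruth` manifest: classifier
sensitivity and false-discovery rate for planted gene-body and promoter
methylation, boundary error of called TE islands, recovered vs. planted
methylation-expression correlation, and the false-positive rate under a
fully null genome.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .expression import compute_fpkm, methylation_expression_correlation
from .gene_methylation import ClassificationConfig, classify_gbm, classify_promoters
from .simulate import (
    SimulationConfig,
    generate_annotation,
    generate_expression,
    generate_site_calls,
)
from .te_islands import call_te_islands, te_signal


def _with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return dataclasses.replace(config, seed=seed)


def gbm_recovery(
    config: SimulationConfig,
    classification: ClassificationConfig | None = None,
    promoters: bool = False,
) -> dict[str, float]:
    """Sensitivity and FDR of the gene-body (or promoter) classifier
    against the planted gene sets."""
    classification = classification or ClassificationConfig()
    genes, _, truth = generate_annotation(config)
    _, sites = generate_site_calls(genes, truth, config, emit_reads=False)
    if promoters:
        out = classify_promoters(genes, sites, classification)
        called = set(out.loc[out["class"] == "PMG", "gene_id"])
        planted = truth.pmg_gene_ids
    else:
        out = classify_gbm(genes, sites, classification)
        called = set(out.loc[out["class"] == "GBM", "gene_id"])
        planted = truth.gbm_gene_ids
    tp = len(called & planted)
    return {
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "fdr": (len(called) - tp) / len(called) if called else 0.0,
        "n_true": len(planted),
        "n_called": len(called),
        "true_positives": tp,
        "false_positives": len(called) - tp,
    }


def island_recovery(
    config: SimulationConfig,
    penalty: float = 40.0,
    drop_cutoff: float = 0.2,
) -> dict[str, float]:
    """Boundary error (in windows) of called vs. planted TE islands."""
    _, repeats, truth = generate_annotation(config)
    signals = te_signal(config.chrom_sizes(), repeats, config.island_grid_bp)
    called = call_te_islands(signals, penalty=penalty, drop_cutoff=drop_cutoff)
    window = config.island_grid_bp
    errors = []
    for chrom, s, e in truth.island_intervals:
        sub = called[called["chrom"] == chrom]
        if sub.empty:
            errors.append(float("inf"))
            continue
        errors.append(
            min(
                max(abs(int(row.start) - s), abs(int(row.end) - e)) / window
                for row in sub.itertuples()
            )
        )
    return {
        "n_true": len(truth.island_intervals),
        "n_called": len(called),
        "max_boundary_error_windows": max(errors) if errors else 0.0,
        "mean_boundary_error_windows": float(np.mean(errors)) if errors else 0.0,
    }


def expression_recovery(config: SimulationConfig) -> dict[str, float]:
    """Measured vs. planted methylation-(log-)expression correlation.

    The planted correlation follows from the generative model:
    r = b*sd(m) / sqrt(b^2 var(m) + sigma^2) with b the planted slope,
    sigma the log-expression noise, and m the realised per-gene
    methylation levels.
    """
    genes, _, truth = generate_annotation(config)
    _, sites = generate_site_calls(genes, truth, config, emit_reads=False)
    counts, lengths = generate_expression(genes, truth, sites, config)
    fpkm = compute_fpkm(counts, lengths)
    measured = methylation_expression_correlation(
        fpkm, truth.gene_methylation, transform="log1p"
    ).statistic
    m = truth.gene_methylation.to_numpy()
    signal = config.expr_slope * float(np.std(m))
    planted = signal / np.hypot(signal, config.expr_noise_sd) if (
        signal or config.expr_noise_sd
    ) else float("nan")
    return {"measured_r": measured, "planted_r": float(planted),
            "error": measured - float(planted)}


def null_gbm_rate(
    config: SimulationConfig, classification: ClassificationConfig | None = None
) -> dict[str, float]:
    """Fraction of genes called GBM on a genome with no planted signal."""
    null_config = dataclasses.replace(config, gbm_fraction=0.0, pmg_fraction=0.0)
    classification = classification or ClassificationConfig()
    genes, _, truth = generate_annotation(null_config)
    _, sites = generate_site_calls(genes, truth, null_config, emit_reads=False)
    out = classify_gbm(genes, sites, classification)
    tested = out["class"].isin(["GBM", "UM"]).sum()
    return {
        "n_tested": int(tested),
        "n_called": int((out["class"] == "GBM").sum()),
    }


def recovery_over_seeds(config: SimulationConfig, seeds) -> dict[str, float]:
    """Pooled recovery metrics of every planted structure across seeds."""
    gbm_tp = gbm_fp = gbm_true = 0
    pmg_tp = pmg_true = 0
    island_err = 0.0
    expr_errors = []
    measured_rs = []
    for seed in seeds:
        cfg = _with_seed(config, seed)
        g = gbm_recovery(cfg)
        gbm_tp += g["true_positives"]
        gbm_fp += g["false_positives"]
        gbm_true += g["n_true"]
        p = gbm_recovery(cfg, promoters=True)
        pmg_tp += p["true_positives"]
        pmg_true += p["n_true"]
        isl = island_recovery(cfg)
        island_err = max(island_err, isl["max_boundary_error_windows"])
        ex = expression_recovery(cfg)
        expr_errors.append(ex["error"])
        measured_rs.append(ex["measured_r"])
    return {
        "gbm_sensitivity": gbm_tp / gbm_true,
        "gbm_fdr": gbm_fp / max(1, gbm_tp + gbm_fp),
        "pmg_sensitivity": pmg_tp / pmg_true,
        "island_max_boundary_error_windows": island_err,
        "expression_r_mean_error": float(np.mean(expr_errors)),
        "expression_r_mean": float(np.mean(measured_rs)),
        "n_seeds": len(list(seeds)),
    }
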