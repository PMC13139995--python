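# methylant

CpG methylome analysis for compact insect genomes — from per-read or
per-site methylation calls to gene-body and promoter methylation
classes, metagene profiles, transposable-element (TE) islands,
cross-technology concordance, and the methylation–expression link.

Insect methylomes are sparse: only a few percent of CpGs are methylated,
and the signal concentrates in the bodies of a conserved subset of
genes. The questions a methylome study asks are therefore set-valued and
positional — *which* genes are gene-body methylated (GBM), *where* TE
density forms islands, how well two measurement technologies agree per
CpG, and whether body methylation tracks expression. `methylant`
implements that downstream analysis as a tested library, with a
synthetic-data generator that plants every structure with known ground
truth so each stage is verifiable without sequencing data.

## The statistics at the core

**Weighted methylation** of a region is coverage-weighted, not a mean of
frequencies: W = Σᵢ mᵢ / Σᵢ cᵢ over CpG sites i with mᵢ methylated of cᵢ
called reads.

**Gene-body / promoter classification** is a two-stage binomial
construction. Each site is first binarised: a one-sided binomial test of
mᵢ out of cᵢ against an error rate ε = 0.05, Benjamini–Hochberg (BH)
corrected across sites. Each gene body (TSS–TTS; promoters use 200 bp
upstream of the TSS) is then tested for an excess of methylated sites:
with k methylated of n covered sites and genome-wide methylated-site
fraction p₀,

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ k), X ~ Binomial(n, p₀),

BH-corrected across genes; GBM (or PMG) where q < α = 0.05. Promoters
additionally require weighted methylation above 3%. Genes with no
covered sites are unclassified and sit outside the BH family.

**TE islands** come from exact penalized changepoint segmentation of the
TE coverage fraction in 50 kb windows: optimal partitioning minimises
Σ_segments SSE + β·(#changepoints) exactly (O(n²) dynamic program), with
the conventional penalty β = 40 applied on its likelihood scale (SSE in
units of the estimated window-noise variance). Segments elevated ≥ 0.2
above the median segment mean are islands; methylation inside vs outside
is compared with a Wilcoxon rank-sum test.

**Concordance** between two site tables (e.g. nanopore vs bisulfite
dialects) joins sites by exact position and reports Pearson r of the
shared frequencies, per-site and window-averaged.

**Expression** uses FPKM = counts·10⁹ / (total mapped reads · gene
length in bp), a rank-sum test of GBM vs UM expression, and the Pearson
correlation of gene methylation with (optionally log1p) mean FPKM.

## Worked example

```python
from methylant import (SimulationConfig, generate_annotation,
                       generate_site_calls, classify_gbm, ClassificationConfig)

config = SimulationConfig(seed=3)           # 2 x 2 Mb, 300 genes, 30% GBM
genes, repeats, truth = generate_annotation(config)
_, sites = generate_site_calls(genes, truth, config, emit_reads=False)
gbm = classify_gbm(genes, sites, ClassificationConfig())
print(gbm["class"].value_counts().to_dict())
```

Running `python examples/03_gene_body_methylation.py` (this exact flow
plus promoters and the metagene profile) prints:

```
GBM: 90, UM: 210 (p0 estimated at 0.104)
sensitivity 1.000, false discoveries 0
promoter-methylated (PMG): 21 of 300 (floor: weighted methylation > 3%)
metagene profile: upstream 0.032, body 0.114, downstream 0.029
```

All 90 planted GBM genes are recovered with no false calls; the metagene
profile shows the body-over-flank elevation characteristic of insect
gene-body methylation. The other `examples/` scripts walk the remaining
capabilities the same way (aggregation and filtering, TE islands,
concordance, expression); `06_expression_link.py` ends with

```
median FPKM: GBM 797 vs UM 447 (W = 13205, p = 5.0e-08)
methylation vs log-expression: r = 0.318 (planted 0.349, p = 1.8e-08)
```

A thin CLI mirrors the library (`methylant simulate|aggregate|filter|
regions|gene-meth|promoters|profile|te-islands|concordance|expression|
run`); `methylant run --config run.toml` executes the whole pipeline
from one TOML file with deterministic seeding and a JSON run report.

## Layout

```
src/methylant/      library (simulate, site_io, annotation, regions,
                    gene_methylation, te_islands, concordance,
                    expression, stats, intervals, evaluation, pipeline, cli)
examples/           one narrative script per capability
tests/              pytest suite (unit, hypothesis property, acceptance)
docs/methods.md     models, parameters, numerical choices, limitations
scripts/acceptance.py
```
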