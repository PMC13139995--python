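"""Generate a ground-truthed synthetic methylome and look at its layout.

The generator plants everything downstream stages are asked to recover:
a set of gene-body-methylated (GBM) genes, promoter-methylated genes,
TE islands, and a methylation-expression relationship.
"""

from methylant import SimulationConfig, generate_annotation, generate_site_calls

config = SimulationConfig(seed=1)  # two 2 Mb chromosomes, 300 genes
genes, repeats, truth = generate_annotation(config)
reads, sites = generate_site_calls(genes, truth, config, emit_reads=False)

te_bp = int((repeats["end"] - repeats["start"]).sum())
genome_bp = config.n_chrom * config.chrom_length
print(f"genes: {len(genes)}, TE copies: {len(repeats)} "
      f"({100 * te_bp / genome_bp:.1f}% of the genome)")
print(f"planted GBM genes: {len(truth.gbm_gene_ids)}, "
      f"promoter-methylated: {len(truth.pmg_gene_ids)}, "
      f"TE islands: {len(truth.island_intervals)}")
print(f"CpG sites with coverage: {len(sites)}, "
      f"mean methylation frequency: {sites['frequency'].mean():.3f}")
# The mean sits well above the 3% background because planted GBM gene
# bodies (30% of genes at a 30% per-site level) pull it up — exactly the
# structure the classifiers downstream are supposed to find.
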