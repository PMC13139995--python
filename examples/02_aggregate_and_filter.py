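"""From per-read log-likelihood-ratio calls to a filtered site table.

Reads with |LLR| below the threshold are ambiguous and dropped from
numerator and denominator alike; sites then pass a minimum-coverage
filter (10 reads), and whole sequences with too few called CpGs
(<10% of the genome index) are excluded.
"""

from methylant import SimulationConfig, generate_annotation, generate_site_calls
from methylant.simulate import cpg_positions
from methylant.site_io import aggregate_frequencies, filter_low_call_sequences, filter_sites

config = SimulationConfig(seed=2, n_chrom=1, chrom_length=500_000, n_genes=40,
                          island_width=100_000, n_te_islands_per_chrom=1)
genes, _, truth = generate_annotation(config)
reads, site_truth = generate_site_calls(genes, truth, config)

table = aggregate_frequencies(reads, llr_threshold=2.0)
print(f"{len(reads)} read-level calls -> {len(table)} sites")

table, n_low = filter_sites(table, min_coverage=10)
print(f"coverage filter removed {n_low} sites below 10 reads")

table, dropped = filter_low_call_sequences(table, cpg_positions(config))
print(f"low-call-sequence filter dropped {len(dropped)} sequences")
print(f"final mean methylation frequency: {table['frequency'].mean():.3f}")
# Aggregated frequencies track the generating truth: each site is a
# binomial draw around its true methylation probability, thinned only
# by the few reads whose LLR fell inside the ambiguous band.
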