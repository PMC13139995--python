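"""Classify gene bodies as methylated (GBM) vs unmethylated (UM) and
check the calls against the planted truth.

Sites are first binarised by a one-sided binomial test against a 5%
error rate (BH-corrected across sites); each gene body is then tested
for an excess of methylated sites over the genome-wide fraction p0 with
an upper-tail binomial test, BH-corrected across genes.
"""

from methylant import (
    ClassificationConfig,
    SimulationConfig,
    classify_gbm,
    classify_promoters,
    generate_annotation,
    generate_site_calls,
    metaprofile,
)

config = SimulationConfig(seed=3)
genes, _, truth = generate_annotation(config)
_, sites = generate_site_calls(genes, truth, config, emit_reads=False)

ccfg = ClassificationConfig()
gbm = classify_gbm(genes, sites, ccfg)
counts = gbm["class"].value_counts()
print(f"GBM: {counts.get('GBM', 0)}, UM: {counts.get('UM', 0)} "
      f"(p0 estimated at {gbm['background_p'].iloc[0]:.3f})")

called = set(gbm.loc[gbm["class"] == "GBM", "gene_id"])
tp = len(called & truth.gbm_gene_ids)
print(f"sensitivity {tp / len(truth.gbm_gene_ids):.3f}, "
      f"false discoveries {len(called) - tp}")

prom = classify_promoters(genes, sites, ccfg)
print(f"promoter-methylated (PMG): {(prom['class'] == 'PMG').sum()} "
      f"of {len(prom)} (floor: weighted methylation > 3%)")

profile = metaprofile(genes, sites)
by_seg = profile.groupby("segment")["weighted_methylation"].mean()
print(f"metagene profile: upstream {by_seg['upstream']:.3f}, "
      f"body {by_seg['body']:.3f}, downstream {by_seg['downstream']:.3f}")
# The body level dominates both flanks — the metagene shape that marks
# gene-body methylation in insect methylomes.
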