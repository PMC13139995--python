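# Methods

This note records the models behind each stage, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical and design choices made where the design was open. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Site tables and coordinate conventions

All internal coordinates are 0-based half-open on the plus strand. GFF3
(1-based closed) and the bisulfite coverage dialect (1-based) are
converted at the boundary; nothing downstream ever sees a 1-based
coordinate. The canonical site table has one row per (chrom, pos,
strand) with `called_reads`, `methylated_reads`, and `frequency` =
methylated/called; frequencies are always recomputed from counts, never
trusted from an input percentage column (counts win, with a warning,
when they disagree by more than half a percentage point).

Per-read nanopore-style calls carry one log-likelihood ratio (LLR) per
read per CpG group. Aggregation counts a read at a site only when
|LLR| > threshold (default 2.0, the convention of the upstream helper
script; positive LLR supports methylation); ambiguous reads leave both
numerator and denominator. Grouped calls (`num_motifs > 1`) split into
one record per CG of the group's k-mer sequence, each inheriting the
group LLR. Strand merging folds the minus-strand C of a CpG (plus-pos
+1) onto the plus-strand C, summing counts; the merged table carries
strand "`.`" and conserves total reads exactly.

Two filters follow the field's practice: a minimum of 10 reads per CpG,
and exclusion of whole sequences (chromosomes/contigs by default) where
fewer than 10% of the indexed CpGs received calls — "strictly less
than", so a sequence at exactly 10% is retained.

## Gene-body and promoter classification

The unit of evidence is deliberately two-staged (the construction used
throughout insect gene-body methylation work):

1. **Site binarisation.** One-sided binomial test of `methylated_reads`
   of `called_reads` against an error rate ε (default 0.05), BH across
   all sites, methylated where q < α. A plain frequency cutoff
   (≥ 0.5) is available as an alternative mode.
2. **Gene test.** For each gene body (TSS–TTS, introns included;
   promoters: 200 bp upstream of the TSS, strand-adjusted), k
   methylated of n covered sites is tested against Binomial(n, p₀)
   upper-tail, BH across genes *within the stage*; positive where
   q < α (default 0.05). p₀ defaults to the stage's own genome-wide
   methylated-site fraction, matching per-stage backgrounds; it can be
   overridden. An alternative unit — raw methylated reads vs total
   reads — sits behind `gene_unit="reads"`.

Promoter calls carry one extra floor: weighted methylation must exceed
3% (`promoter_floor=0.03`), so a promoter cannot be called methylated on
count significance alone at a negligible absolute level. Genes with no
covered sites are `unclassified` and excluded from the BH family, so
GBM + UM + unclassified always equals the gene count.

Edge cases: p₀ = 0 with k > 0 yields an exact p of 0 (reported as such,
classed positive); a single-gene BH family returns q = p.

**Metagene profile.** 4 kb flanks in fixed 200 bp bins (bin 1 abuts the
TSS/TTS and indices grow outward), the body scaled to 40 bins, all
strand-aware; bin levels are coverage-weighted sums pooled across genes.
Genes shorter than the bin count simply spread their sites over
proportional bins.

## Region annotation

Each site receives exactly one label by the fixed precedence
exon > intron > promoter > TE > intergenic. The precedence is not forced
by anything upstream; it is chosen so the dominant genic signal is never
masked by repeats nested inside genes, and it is configurable.
Multi-transcript genes collapse to their longest transcript, since every
computation here is per gene. Exon ranks run 5'→3' on the gene's own
strand. TE copies get a genomic context (intronic / 2 kb-upstream /
intergenic) by majority base-pair overlap, ties broken toward the
gene-proximal class.

Interval arithmetic (fixed windows with a truncated last window,
coverage fractions over flattened intervals, subtract/intersect) is
exact integer bookkeeping; subtract and intersect partition their input
base pairs, which the property tests assert.

## TE islands

The per-chromosome signal is the TE coverage fraction of consecutive
50 kb windows. `segment_changepoints` is an exact optimal-partitioning
dynamic program for

  total cost = Σ_segments SSE(segment) + β · (#changepoints),

O(n²) with cost ties broken toward fewer changepoints (then the earliest
split). A segment is island-labelled when its mean is at least
`drop_cutoff` (0.2) above a baseline — the median segment mean by
default, so the abundant background segments define the reference level;
adjacent island segments merge and window indices convert to bp.

**Penalty scale.** The conventional penalty of 40 for a windowed mean
model originates from changepoint engines whose manual penalty applies
to a −2·log-likelihood cost, i.e. SSE measured in units of the noise
variance. Applied to raw SSE of a [0,1] fraction signal it would forbid
every changepoint (a whole chromosome's SSE is an order of magnitude
below 40). The island caller therefore rescales: β_raw = 40 · σ̂², with
σ̂² the within-segment noise variance of the signal. σ̂² is estimated in
two passes — a diff-quantile floor (25th percentile of |first
differences|, half-normal calibrated: q25 = 0.3186 σ_d, σ̂² = σ_d²/2,
robust to level shifts and to the extra variability of high-density
segments), seeding a deliberately liberal BIC-like first segmentation
(penalty 2σ̂₀²·log n), whose within-segment residual variance is the
final estimate. `penalty_scale="raw"` disables the rescaling for users
who pre-normalise their tracks.

The island–background methylation contrast is a two-sided Wilcoxon
rank-sum test on per-site frequencies, with medians and group sizes
reported.

## Statistics core

- **Binomial tails** go through the regularised incomplete beta
  (exact in log space at any n used here); `k = 0` gives 1, `p₀ = 0`
  with `k > 0` gives exactly 0, and upper(k) + lower(k−1) = 1 to 1e−12.
- **BH step-up** is the literal order-statistic definition,
  order-preserving and clipped to 1.
- **Wilcoxon rank-sum** uses midranks; the statistic is the
  Mann-Whitney U of the first sample (the W convention of common
  statistical software). For combined n ≤ 10 the two-sided p is exact
  enumeration of all rank assignments (2·min of the tails, capped at
  1); beyond that, the tie-corrected normal approximation with a 0.5
  continuity correction. The switchover matters: the normal
  approximation itself deviates from exact enumeration by up to ~0.04
  at n₁ = n₂ = 3 (verified exhaustively over all U outcomes), while the
  dispatched p-value stays within 0.02 of exact for all equal groups up
  to n = 8.
- **Pearson r** reports the t-based two-sided p on n−2 degrees of
  freedom; constant input is an error, not a NaN.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
not sequencing physics. What it plants, and the defaults (chosen once as
a desk-scale version of a compact ant methylome study, and used as-is by
the tests and the acceptance script):

| Parameter | Default | Why |
|---|---|---|
| genome | 2 chromosomes × 2 Mb | desk-scale stand-in for a 16-chromosome assembly |
| genes | 300, mean 5 kb, ~4 exons | gene density ≈ 37% of the genome |
| CpG grid | every 50 bp | only positions/counts matter; a 200 bp promoter holds 4 CpGs |
| background methylation | p = 0.03 | the low genome-wide level typical of ant methylomes |
| GBM planting | 30% of genes at p = 0.30 per site | matches the ~one-third GBM gene fraction such studies report |
| promoter planting | 7% of genes at p = 0.50 | PMG fractions of 6–9%; the higher per-site level reflects the short (4-CpG) window |
| per-site jitter | Beta, concentration 100 | real methylomes are overdispersed; frequencies must not be degenerate |
| coverage | Poisson, mean 30 | long-read depths of such studies |
| LLR | Normal(±5, 2) per read | well-separated but overlapping call distributions |
| TE layout | background density 0.10, islands 0.60, 3 × 200 kb per chromosome | genome TE fraction ≈ 0.25 |
| expression | log(1+FPKM) = 3.0 + 2.1·m + N(0, 0.7), 22 samples | implies a planted methylation–expression r ≈ 0.35 |

Randomness flows from streams keyed on (seed, purpose, chromosome), so
identical config + seed is byte-identical end to end and partial
regeneration is stable. GBM and promoter gene sets are drawn
independently (the two classifications are independent axes). Counts are
back-computed from true FPKM through the FPKM formula with library sizes
drawn uniformly in [8, 12] million reads and rounded — so the noise-free
methylation–expression correlation is 1 only up to count rounding
(≥ 0.999 in practice).

**Island identifiability.** Islands are aligned to the 50 kb analysis
grid and placed with at least a 2-window background margin on each side
(≥ 4 windows between islands). Without that margin two islands can sit
across a 2-window dip that no changepoint engine at the conventional
penalty would split, making boundary-accurate recovery structurally
impossible rather than statistically hard; the margin mirrors the
well-separated island layout of real compact genomes.

**What passing tests do not show.** The generator has no sequence, no
alignment or mapping bias, no bisulfite conversion failure, no
copy-number variation, no correlated methylation along reads
(read-level states are independent given the site probability), and CpG
density is uniform rather than elevated in promoters. Recovery results
on this generator therefore validate the statistical machinery — they
do not certify performance on real libraries, where coverage and error
are structured.

## Pipeline

`run_pipeline` executes simulate? → aggregate → filter → regions →
gene-meth → promoters → islands → concordance? → expression? from one
TOML config (unknown keys rejected), with logging to stderr and a JSON
run report carrying per-stage row counts, a per-stage summary (total and
methylated sites, mean methylation, GBM/UM counts) and SHA-256 checksums
of every artifact. Reports contain no timestamps and all floats use
fixed formatting, so identical config + seed reproduces byte-identical
outputs. Missing inputs for enabled stages fail before any stage runs.
CLI exit codes: 0 ok, 2 configuration error, 3 data error.

## Problem sizes used by tests and the acceptance script

Recovery and type-I runs use the default 2 × 2 Mb genome (80,000 CpGs)
across 10–20 seeds without read-level emission; the end-to-end
determinism check and the acceptance pipeline pass use 2 × 0.6–1 Mb with
full read-level output; solver–oracle equivalence enumerates all
segmentations for 200 random signals of length ≤ 12. These sizes are the
package's chosen study conditions for its own verification and are
stated here so results are interpretable, not tunable knobs.

## Known limitations

- The exact-position concordance join treats dialect off-by-one as a
  flag (±1 bp tolerance), not an inference; mixed-convention tables are
  rejected rather than reconciled.
- The 10%-of-CpGs sequence filter is per chromosome/contig; no
  sub-chromosomal region filtering.
- `segment_changepoints` is O(n²); fine for windowed chromosome tracks
  (n ≲ 10⁴), not for per-base signals.
- Promoter classification inherits the CpG sparsity of its 200 bp
  window: with few covered CpGs the binomial test has limited
  resolution, which is why the floor rule exists.
- No GO-term enrichment and no repeat discovery; repeat intervals and
  gene annotations are inputs.
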