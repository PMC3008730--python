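# Methods

This note documents the models, conventions and design choices behind
`retromap`, in the order of the analysis chain.

## Read processing

LAM-PCR amplifies the 5′-LTR vector–genome junction from DNA digested
with three 4-cutters (Tsp509I `AATT`, HpyCH4IV `ACGT`, HinP1I `GCGC`), so
a read is `barcode + LTR tail + genomic flank up to the first recognition
site in the read direction`. Processing steps and their conventions:

- **Demultiplexing** is exact prefix matching. Barcodes must be mutually
  non-prefixing; a barcode set violating this is a configuration error,
  not a per-read rejection.
- **Validation** requires the exact LTR tail, ending in the CA
  integration dinucleotide, followed by at least `min_genomic_len = 20`
  genomic bases. Matching is exact: tolerating mismatches in the tail
  would need an error model for the sequencing chemistry that this
  package deliberately does not carry; with the default 454-style
  amplicon lengths the practical loss is reads with errors inside the
  first ~20 bases.
- **Redundancy collapse** merges *exact* duplicate genomic sequences and
  records the duplicate count as `support`. Near-identity merging would
  require an arbitrary similarity cutoff; exact collapse is deterministic
  and the downstream unique-site merge absorbs residual redundancy.
- **Alignment filtering** consumes BLAT PSL records. Identity is
  `[matches − (mismatches + query gaps + tile gaps)] / query size`,
  floored at zero; "tile gaps" are target-gap bases per PSL semantics.
  A hit must start within the first three query bases (0-based offsets
  0–2) and reach 90% identity; if the two best surviving hits differ by
  less than 2% identity the query is discarded as multi-mapped. A
  difference of exactly 2% keeps the best hit (with a 1e-9 epsilon so the
  boundary is stable under binary rounding of the fractions).
- **Junction coordinates** are 0-based half-open. The site position is
  the first aligned genomic base on the provirus strand: `target_start`
  for plus-strand hits, `target_end − 1` for minus-strand hits. Sites are
  unique on (chrom, position, strand, sample, timepoint) with summed read
  support.

## Gene annotation

Sites are classified against transcript models with **at-least-one-gene
semantics**: TSS-proximal if any TSS lies within ±2.5 kb, else intragenic
if inside any transcript span, else intergenic. Proximity wins over being
inside a different gene — a site 1 kb from gene A's promoter but deep
inside overlapping gene B is a promoter-proximal event.

Target genes are all genes with a TSS within ±50 kb; a multi-isoform gene
is represented by the isoform whose TSS is nearest the site, with ties
broken by lower transcript start coordinate (determinism). Signed TSS
distances are negative upstream / positive downstream *in the gene's
reading direction*, which makes the distance histogram interpretable for
genes on either strand.

Provirus orientation (forward = same strand as the enclosing transcript)
is defined for every site lying inside a transcript, including
TSS-proximal ones — so the forward+reverse denominator can exceed the
intragenic category count. This is the denominator that makes published
orientation tallies internally consistent (category counts and
orientation counts are otherwise irreconcilable). Printed percentages are
rounded half-up to one decimal.

## Random controls

Two distinct constructs, both restriction-aware:

- **Random pool** (default n = 40,000): uniform positions (chromosomes
  weighted by length, strands uniform) kept when the distance to the
  nearest recognition site of any of the three enzymes is within
  [20, 500] bp — below 20 bp the flank cannot be mapped, above ~500 bp
  the amplicon sequences inefficiently. Used as the background for
  cluster-threshold estimation and genomic-distribution comparisons.
- **Matched controls** (default 3 per site): positions whose distance to
  the nearest recognition site equals the experimental site's
  d<sub>RE</sub> *exactly*. Candidates are enumerated genome-wide as
  r ± d over all recognition-site coordinates r, verified, and sampled
  without replacement. The distance is measured to the recognition-site
  start on either side; restricting to the read-direction side would
  halve the candidate set without changing the matching property, and the
  recovery bias being corrected is symmetric in the pool construction.

All three motifs are palindromic, so a single forward scan covers both
strands; overlapping occurrences are counted; windows containing N never
match. Enzymes (name → motif) are configurable in the pipeline YAML.

## Cluster analysis

Spacings are successive differences of sorted, deduplicated positions per
chromosome, strand ignored (clusters are about local density, not
orientation). The threshold for a dataset of n sites is estimated by
drawing n pool sites without replacement, 1,000 times, pooling all
resampled spacings, and taking the left-continuous empirical quantile at
the FDR: the largest observed distance d with fraction(distances < d) ≤
FDR. Resampling without replacement mirrors how a real dataset of n
distinct sites behaves; the quantile is computed on raw (unbinned)
distances. For an unconstrained uniform pool the estimate converges to
the exponential-spacing closed form −ln(1−FDR)·L/n, which the test suite
verifies to within 10% — the data-driven estimate on a real
restriction-constrained pool differs precisely because the pool is not
uniform.

Clusters are single-linkage chains: maximal runs of ≥ 2 sites with every
adjacent gap ≤ threshold. This is the only pairwise-threshold definition
that can produce the long (up to ~dozens of sites) clusters seen in dense
datasets; pairwise-only windows cannot. Cluster target genes are genes
with any isoform TSS within ±50 kb of the cluster interval.

Dataset comparisons at different depths subsample the larger dataset to
the smaller one's size (10×, without replacement) and compare spacing
distributions with the two-sample Kolmogorov–Smirnov test. Gene-set
over-representation (e.g. cancer-gene compilations among cluster targets)
uses the 2×2 chi-square with Yates continuity correction, equivalent to
the standard two-sample proportion test with continuity correction.

## Epigenetic association

Feature tracks are reduced to midpoints (floor((start+end)/2); point
features keep their coordinate). Counts are taken in a ±500 bp window,
inclusive at both edges. Each site with its k matched controls forms a
stratum; the stratum score is the mid-rank probability that the
experimental count exceeds a control count, and the ROC area is the mean
score. This is the standard stratified Mann–Whitney estimator of the
area under the ROC curve for site-vs-matched-control discrimination: it
is 0.5 in expectation under exchangeability, bounded in [0, 1], invariant
under any strictly monotone transform of counts, and antisymmetric under
role swap for k = 1. Ties take mid-ranks. Significance is an empirical
two-sided p-value from B within-stratum label permutations (default
1,000 in the library, 200 in the pipeline for speed), with the +1
small-sample correction; family-wise adjustment is left to the caller.
Empty site categories yield results flagged `insufficient_data` rather
than being dropped, so association matrices keep a stable shape.

## Expression classes

Detected genes are split at the 25th/75th percentiles (linear
interpolation) into low / intermediate / high; undetected genes are
`absent` regardless of value. Percentiles are computed over *detected*
genes only: "absent" is a detection call, and including absents would
couple the class boundaries to the detection rate. Values exactly on a
boundary are intermediate. Enrichment of target genes for active (any
detected class) or high expression uses the continuity-corrected
two-proportion test; gene ids missing from the expression table are
counted as unmapped and excluded from denominators.

## Synthetic data

The generator emulates the features of a LAM-PCR insertion-site study
that the analysis depends on:

- **Genome**: i.i.d. uniform nucleotides (each 4-bp motif at ~L/256), so
  restriction-fragment lengths are approximately geometric with mean
  ~85 bp across the three enzymes. Defaults: 2 Mb over 2 chromosomes.
- **Genes**: non-overlapping spans with log-normal lengths (median 6 kb),
  random strands, optional second isoform with an offset TSS; log-normal
  expression with an 80% detection rate.
- **Sites**: a configurable fraction (default 0.3, matching the ~30%
  TSS-proximal share typical of gamma-retroviral maps) placed
  Normal(TSS, 1 kb) around random genes, the rest uniform; strand inside
  a gene reversed with probability `orientation_reverse_prob` (0.5
  pre-infusion-like, 0.63 for the post-infusion-like counterselection
  scenario); an optional `cluster_boost` fraction re-placed near existing
  sites. Positions are unique per (chrom, position, strand).
- **Reads**: barcode + LTR tail (ending CA) + the reference flank from
  the junction to the nearest recognition site in the read direction,
  with substitution errors at `error_rate`. Companion *ideal* PSL records
  are emitted (mismatch counts equal to planted substitutions), so the
  filtering logic is exercised without an external aligner — the
  deliberate trade-off is that alignment *search* errors (spurious
  multi-mapping, soft-clipping) are out of scope.
- **Tracks**: point features, a fraction 1 − 1/enrichment_factor placed
  Normal(anchor, 200 bp) around anchor positions, the rest uniform.

What passing tests on this generator do **not** show: behaviour on real
genomes with repeats, GC isochores and CpG-depleted HpyCH4IV sites;
454-specific homopolymer errors; aligner artefacts; cross-sample barcode
bleed. The generator's truth tables make recovery exact to score, which
is the point.

## Pipeline and problem sizes

The end-to-end synthetic run uses, by default, 1,000 pre- and 250
post-timepoint sites on a 2 Mb genome with a 40,000-site pool, 1,000
threshold resamples and 200 association permutations — sizes chosen so a
full run, including all resampling, completes in seconds on one core
while keeping every estimate's sampling error well inside the tolerances
the tests assert. Outputs are plain TSV/BED/FASTA/PSL plus a
`manifest.json` recording the config, seed, input checksums and per-stage
record counts; identical config + seed reproduces byte-identical tables.
Stage conservation (records in = accepted + rejected by tagged reason)
is asserted in tests.

The pre/post comparison report emits both a one-sample binomial test of
the reverse-orientation fraction against 0.5 within each dataset and a
two-sample proportion test between datasets, because the two questions —
"is this dataset biased?" and "did the bias change?" — are distinct;
p-values come with a Bonferroni-corrected alpha for the emitted family.

## Known limitations

- Exact-match LTR validation discards reads with errors in the tail.
- Matched-control enumeration is exact and fast on desk-scale genomes;
  on a full mammalian genome the per-distance candidate enumeration is
  still linear in the number of recognition sites (~10⁷) per distinct
  distance, which is tractable but memory-heavy if many distances are
  cached at once.
- The cluster threshold depends on the pool honestly representing the
  recoverable genome; a mis-specified enzyme list shifts thresholds.
- Expression classes assume one value per gene; probe-to-gene collapsing
  is upstream input.
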