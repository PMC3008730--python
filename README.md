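# retromap

Genome-wide analysis of retroviral vector integration sites, built for
insertional-genotoxicity surveillance of gene-modified T cells.
`retromap` takes LAM-PCR amplicon reads through validation, alignment
filtering and annotation to unique vector–genome junctions, builds
restriction-matched random controls, calls integration clusters at a
data-size-dependent false-discovery threshold, quantifies the association
of integration with epigenetic feature tracks, and compares datasets
(e.g. T cells before and after infusion into a patient) for clonal
dynamics such as orientation-biased loss of gene-disrupting insertions.

## Who it is for

Groups mapping gamma-retroviral (MLV-derived) or similar vector insertion
sites from LAM-PCR / pyrosequencing experiments, and anyone needing the
statistical machinery around such maps: matched random controls that
neutralise the restriction-digest recovery bias, cluster definitions that
stay comparable across datasets of different depth, and stratified ROC
statistics for chromatin-feature enrichment.

## The core methods

**Read validation.** A valid read is `barcode + LTR tail + genomic flank`,
where the LTR tail must end in the invariant CA integration dinucleotide
and the flank must be ≥ 20 bp. BLAT alignments are scored as

```
identity = [matches − (mismatches + query gap bases + tile gap bases)] / query size
```

and a query is kept only if its best hit starts within the first three
query bases, reaches ≥ 90% identity, and beats the runner-up by ≥ 2%
identity (otherwise it is discarded as multi-mapped). The junction base is
the first aligned genomic base on the provirus strand.

**Matched random controls.** Because LAM-PCR only recovers junctions with
a nearby Tsp509I/HpyCH4IV/HinP1I recognition site, uniform random
controls are biased. The package draws a 40,000-site pool restricted to
20–500 bp from the nearest recognition site, and, for the epigenetic
statistics, matches each experimental site with 3 controls lying at
*exactly* the same distance d<sub>RE</sub> from a recognition site.

**Cluster calling.** For a dataset of *n* sites, equal-sized sets are
resampled 1,000 times from the random pool; the threshold is the 1%
quantile of the pooled consecutive-spacing distribution (the FDR), and a
cluster is a maximal run of ≥ 2 sites whose adjacent gaps all stay below
it. For uniform spacings at density λ the threshold approaches the
closed form −ln(1−FDR)/λ.

**Stratified ROC association.** With experimental count e<sub>i</sub> and
matched-control counts c<sub>ij</sub> in a ±500 bp window, each stratum
scores s<sub>i</sub> = [#(c<sub>ij</sub> < e<sub>i</sub>) + ½·#(c<sub>ij</sub> = e<sub>i</sub>)]/k
and the ROC area is the mean over strata: 0.5 means no association,
> 0.5 enrichment, < 0.5 depletion; significance comes from within-stratum
label permutation.

## Worked example

The synthetic end-to-end run simulates a genome, genes, pre-/post-infusion
integration sites and LAM-PCR reads, then analyses them:

```bash
retromap run-all --seed 11 --outdir out/
```

prints (abridged):

```json
"read_processing_pre":  {"reads_in": 1000, "too_short": 210, "accepted_reads": 790},
"sites_pre":            {"n_sites": 790},
"random_pool":          {"n_sites": 40000},
"clusters_pre":         {"threshold_bp": 17, "n_clusters": 10, "n_cluster_genes": 46},
"epigenetic_association": {"roc_all_site_associated": 0.79, "roc_all_unrelated": 0.49},
"comparison":           {"orientation_post_binomial_p": 0.063, "shared_positions": 0}
```

Reading this: of 1,000 simulated reads, 210 had restriction fragments
shorter than 20 bp and were rejected, and every remaining read was mapped
back to its true junction (790 unique sites). At this depth the 1% FDR
spacing threshold on a 2 Mb genome is 17 bp, yielding 10 clusters. The
track planted with a 3× enrichment at integration sites scores ROC 0.79;
an unrelated track scores ≈ 0.5. The post-infusion dataset was simulated
with a 63% reverse-orientation probability, visible as a low (but at
n = 199 not yet significant) binomial p-value. `out/distribution_pre.tsv`
holds the Table-style category/orientation summary:

```
sample_id timepoint n_sites intergenic_pct TSS_proximal_pct intragenic_pct forward_pct reverse_pct
S1        pre       790     31.4           53.4             15.2           49.6        50.4
```

Subcommands (`simulate`, `reads`, `map`, `annotate`, `controls`,
`clusters`, `epimap`, `express`, `compare`) expose each stage separately
on the standard text formats (FASTA, PSL, refFlat-like TSV, BED, TSV);
see `retromap --help`. All stages are importable from Python
(`from retromap import filter_alignments, estimate_cluster_threshold, ...`).

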