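"""End-to-end orchestration of the integration-site analysis.

``run_pipeline`` drives the stage chain on a synthetic study — genome,
gene models, pre/post integration sites, LAM-PCR reads — through read
processing, annotation, random controls, cluster calling, expression and
epigenetic association, writing every summary table plus a run manifest
with per-stage record counts.  ``compare_timepoints`` produces the
clonal-dynamics report contrasting two annotated datasets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from retromap import io
from retromap.cluster_analysis import (
    call_clusters,
    cluster_target_genes,
    compare_cluster_frequency,
    estimate_cluster_threshold,
)
from retromap.epigenetic_association import association_matrix
from retromap.expression_association import class_distribution, classify_expression
from retromap.genome_annotation import (
    AnnotationRecord,
    GeneIndex,
    annotate_sites,
    summarize_distribution,
)
from retromap.random_controls import (
    ENZYMES,
    generate_random_pool,
    match_controls_batch,
)
from retromap.read_processing import (
    IntegrationSite,
    Rejection,
    TrimmedFragment,
    alignments_to_sites,
    collapse_redundant,
    demultiplex_reads,
    filter_alignments,
    validate_and_trim,
)
from retromap.synthetic_data import (
    DEFAULT_LTR_TAIL,
    SyntheticConfig,
    simulate_genes,
    simulate_genome,
    simulate_lampcr_reads,
    simulate_sites,
    simulate_track,
)

logger = logging.getLogger("retromap")

__all__ = ["PipelineConfig", "run_pipeline", "process_reads", "compare_timepoints"]


@dataclass
class PipelineConfig:
    """All pipeline parameters with their standard defaults.

    Analysis defaults: ±2.5 kb TSS window, ±50 kb target-gene window,
    ±500 bp epigenetic window, 90% minimum alignment identity with a 2%
    multi-mapper margin, >=20 bp genomic flank, a 40,000-site random pool
    constrained to 20-500 bp from a restriction site, 1% cluster FDR with
    1,000 resamples, 3 matched controls per site and 10 subsamples for the
    equal-complexity KS comparison.  The synthetic block controls the
    simulated study; ``pool_size`` is scaled in small runs via overrides.
    """

    seed: int = 0
    tss_window: int = 2_500
    target_window: int = 50_000
    half_window: int = 500
    min_identity: float = 0.90
    ambiguity_margin: float = 0.02
    max_query_start: int = 3
    min_genomic_len: int = 20
    pool_size: int = 40_000
    min_d_re: int = 20
    max_d_re: int = 500
    fdr: float = 0.01
    n_resamples: int = 1_000
    k_controls: int = 3
    n_subsamples: int = 10
    n_permutations: int = 200
    ltr_tail: str = DEFAULT_LTR_TAIL
    # synthetic-study block
    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    n_genes: int = 120
    n_sites_pre: int = 1_000
    n_sites_post: int = 250
    tss_bias_fraction: float = 0.3
    tss_sd: float = 1_000.0
    orientation_reverse_prob_pre: float = 0.5
    orientation_reverse_prob_post: float = 0.63
    cluster_boost: float = 0.1
    error_rate: float = 0.0
    track_enrichment: float = 3.0
    n_track_features: int = 2_000
    # digestion enzymes (name -> recognition motif), overridable in YAML
    enzymes: dict = field(default_factory=lambda: dict(ENZYMES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def synthetic(self, timepoint: str) -> SyntheticConfig:
        pre = timepoint == "pre"
        return SyntheticConfig(
            seed=self.seed + (10 if pre else 20),
            genome_length=self.genome_length,
            n_chromosomes=self.n_chromosomes,
            n_genes=self.n_genes,
            n_sites=self.n_sites_pre if pre else self.n_sites_post,
            tss_bias_fraction=self.tss_bias_fraction,
            tss_sd=self.tss_sd,
            orientation_reverse_prob=(
                self.orientation_reverse_prob_pre
                if pre
                else self.orientation_reverse_prob_post
            ),
            cluster_boost=self.cluster_boost,
            error_rate=self.error_rate,
        )


def process_reads(
    reads,
    barcodes: Mapping[str, str],
    alignments,
    ltr_tail: str,
    timepoint: str,
    min_genomic_len: int = 20,
    min_identity: float = 0.90,
    max_query_start: int = 3,
    ambiguity_margin: float = 0.02,
) -> tuple[list[IntegrationSite], dict]:
    """Raw reads + PSL hits -> unique integration sites, with stage counts.

    Runs demultiplexing, LTR validation/trimming, redundancy collapsing and
    alignment filtering; the returned counts satisfy input = accepted +
    rejected at every stage.
    """
    reads = list(reads)
    by_query: dict[str, list] = {}
    for a in alignments:
        by_query.setdefault(a.query_id, []).append(a)
    assigned, unassigned = demultiplex_reads(reads, barcodes)
    counts = {
        "reads_in": len(reads),
        "unassigned": len(unassigned),
        "no_ltr": 0,
        "too_short": 0,
        "unaligned": 0,
        "multi_mapped": 0,
        "accepted_reads": 0,
    }
    sites: list[IntegrationSite] = []
    for sample_id, sample_reads in assigned.items():
        fragments: list[TrimmedFragment] = []
        for read in sample_reads:
            res = validate_and_trim(read, ltr_tail, min_genomic_len, sample_id)
            if isinstance(res, Rejection):
                counts[res.reason] += 1
            else:
                fragments.append(res)
        collapsed = collapse_redundant(fragments)
        accepted = []
        support: dict[str, int] = {}
        for frag in collapsed:
            hits = by_query.get(frag.read_id, [])
            res = filter_alignments(
                hits, min_identity, max_query_start, ambiguity_margin
            )
            if isinstance(res, Rejection):
                counts[res.reason or "unaligned"] += frag.support
            else:
                accepted.append(res)
                support[res.query_id] = frag.support
                counts["accepted_reads"] += frag.support
        sites.extend(alignments_to_sites(accepted, sample_id, timepoint, support))
    return sorted(sites), counts


def _sha1(path: Path) -> str:
    h = hashlib.sha1()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the synthetic end-to-end analysis and write all outputs.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage genome: simulating %d bp", config.genome_length)
    genome, rmap = simulate_genome(config.synthetic("pre"), config.enzymes)
    genes, expression = simulate_genes(genome, config.synthetic("pre"))
    index = GeneIndex(genes)
    io.write_fasta(genome, out / "genome.fa")
    io.write_refflat(genes, out / "genes.refflat.tsv")
    io.write_expression_tsv(expression, out / "expression.tsv")

    manifest: dict = {"config": asdict(config), "stages": {}}
    barcodes = {"S1": "ACGTAC", "S2": "TGCATG"}
    datasets: dict[str, dict] = {}
    for timepoint in ("pre", "post"):
        scfg = config.synthetic(timepoint)
        true_sites, truth = simulate_sites(genome, genes, scfg, "S1", timepoint)
        reads, alignments, read_truth = simulate_lampcr_reads(
            true_sites, genome, rmap, config.ltr_tail, barcodes, scfg
        )
        sites, counts = process_reads(
            reads,
            barcodes,
            alignments,
            config.ltr_tail,
            timepoint,
            config.min_genomic_len,
            config.min_identity,
            config.max_query_start,
            config.ambiguity_margin,
        )
        annotations = annotate_sites(sites, index, config.tss_window, config.target_window)
        io.write_sites_tsv(sites, out / f"sites_{timepoint}.tsv")
        io.write_sites_bed(sites, out / f"sites_{timepoint}.bed")
        truth.to_csv(out / f"truth_{timepoint}.tsv", sep="\t", index=False)
        summary = summarize_distribution(annotations)
        summary.to_csv(out / f"distribution_{timepoint}.tsv", sep="\t", index=False)
        manifest["stages"][f"read_processing_{timepoint}"] = counts
        manifest["stages"][f"sites_{timepoint}"] = {"n_sites": len(sites)}
        datasets[timepoint] = {
            "sites": sites,
            "annotations": annotations,
            "truth": truth,
        }
        logger.info("stage %s: %d sites from %d reads", timepoint, len(sites), counts["reads_in"])

    logger.info("stage controls: pool of %d", config.pool_size)
    pool = generate_random_pool(
        genome, rmap, config.pool_size, config.min_d_re, config.max_d_re, config.seed + 30
    )
    io.write_pool(pool, out / "random_pool.tsv")
    manifest["stages"]["random_pool"] = {"n_sites": len(pool)}

    cluster_report = {}
    for timepoint, data in datasets.items():
        n = len(data["sites"])
        est = estimate_cluster_threshold(
            n, pool, config.fdr, config.n_resamples, config.seed + 40
        )
        clusters = call_clusters(data["sites"], est.threshold_bp)
        per_cluster, union = cluster_target_genes(clusters, index, config.target_window)
        io.write_clusters_bed(clusters, out / f"clusters_{timepoint}.bed")
        rows = [
            {
                "cluster": f"cluster{i:04d}",
                "chrom": cl.chrom,
                "start": cl.start,
                "end": cl.end,
                "size": cl.size,
                "target_genes": ",".join(sorted(per_cluster[i])),
            }
            for i, cl in enumerate(clusters)
        ]
        pd.DataFrame(rows).to_csv(out / f"clusters_{timepoint}.tsv", sep="\t", index=False)
        cluster_report[timepoint] = {
            "threshold_bp": est.threshold_bp,
            "n_clusters": len(clusters),
            "cluster_genes": sorted(union),
        }
        manifest["stages"][f"clusters_{timepoint}"] = {
            "threshold_bp": est.threshold_bp,
            "n_clusters": len(clusters),
            "n_cluster_genes": len(union),
        }

    logger.info("stage expression")
    classing = classify_expression(expression)
    pool_sites = [
        IntegrationSite(c, int(p), s, "pool", "random")
        for c, p, s in zip(pool.chroms[:2000], pool.positions[:2000], pool.strands[:2000])
    ]
    pool_ann = annotate_sites(pool_sites, index, config.tss_window, config.target_window)
    background_genes = {tg.gene_id for a in pool_ann for tg in a.target_genes}
    expr_rows = []
    for timepoint, data in datasets.items():
        for cat in ("all", "TSS_proximal", "intragenic"):
            recs = [
                a
                for a in data["annotations"]
                if cat == "all" or a.category == cat
            ]
            targets = {tg.gene_id for a in recs for tg in a.target_genes}
            if not targets:
                continue
            dist = class_distribution(targets, classing, background_genes)
            expr_rows.append(
                {
                    "timepoint": timepoint,
                    "category": cat,
                    "n_genes": dist["n_target"],
                    **{f"{c}_pct": dist["target_pct"][c] for c in dist["target_pct"]},
                    "active_pct": 100 * dist["active_fraction_target"],
                    "background_active_pct": 100 * dist["active_fraction_background"],
                    "active_pvalue": dist["active_test"]["pvalue"],
                }
            )
    pd.DataFrame(expr_rows).to_csv(out / "expression_classes.tsv", sep="\t", index=False)

    logger.info("stage epigenetic association")
    pre = datasets["pre"]
    anchors = [(s.chrom, s.position) for s in pre["sites"]]
    track_enriched = simulate_track(
        genome, anchors, "site_associated", config.n_track_features,
        config.track_enrichment, seed=config.seed + 50,
    )
    track_null = simulate_track(
        genome, [], "unrelated", config.n_track_features, 1.0, seed=config.seed + 51
    )
    io.write_track_bed(track_enriched, out / "track_site_associated.bed")
    io.write_track_bed(track_null, out / "track_unrelated.bed")
    matched = match_controls_batch(
        pre["sites"], rmap, config.k_controls, config.seed + 60
    )
    by_cat: dict[str, list] = {"all": list(matched)}
    ann_by_key = {
        (a.site.chrom, a.site.position, a.site.strand): a.category
        for a in pre["annotations"]
    }
    for cat in ("TSS_proximal", "intragenic", "intergenic"):
        by_cat[cat] = [
            m
            for m in matched
            if ann_by_key.get((m.site.chrom, m.site.position, m.site.strand)) == cat
        ]
    results, matrix = association_matrix(
        by_cat,
        [track_enriched, track_null],
        config.half_window,
        config.n_permutations,
        config.seed + 70,
    )
    matrix.to_csv(out / "association_matrix.tsv", sep="\t")
    manifest["stages"]["epigenetic_association"] = {
        "n_results": len(results),
        "roc_all_site_associated": matrix.loc["site_associated", "all"],
        "roc_all_unrelated": matrix.loc["unrelated", "all"],
    }

    logger.info("stage comparison")
    comparison = compare_timepoints(
        datasets["pre"]["annotations"],
        datasets["post"]["annotations"],
        cluster_report["pre"]["cluster_genes"],
        cluster_report["post"]["cluster_genes"],
        n_subsamples=config.n_subsamples,
        seed=config.seed + 80,
    )
    (out / "comparison.json").write_text(json.dumps(comparison, indent=2))
    manifest["stages"]["comparison"] = {
        "orientation_post_binomial_p": comparison["orientation"]["post_binomial_pvalue"],
        "shared_positions": comparison["shared_positions"]["n_shared"],
    }

    manifest["inputs"] = {
        p.name: _sha1(p) for p in sorted(out.glob("*.fa")) + sorted(out.glob("*.refflat.tsv"))
    }
    manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def compare_timepoints(
    pre_annotations: Sequence[AnnotationRecord],
    post_annotations: Sequence[AnnotationRecord],
    pre_cluster_genes: Sequence[str] = (),
    post_cluster_genes: Sequence[str] = (),
    n_subsamples: int = 10,
    seed: int = 0,
) -> dict:
    """Clonal-dynamics report contrasting two annotated datasets.

    Emits category-proportion tests (pre vs post, per category), both
    orientation tests (one-sample binomial of the reverse fraction vs 0.5
    within each dataset, and a two-sample proportion test pre vs post),
    Bonferroni-corrected over the emitted family, the fraction of
    post-infusion cluster genes also hit by pre-infusion clusters, the KS
    comparison of spacing distributions at equal complexity, and the
    identical-position site intersection.
    """
    pre_sites = [a.site for a in pre_annotations]
    post_sites = [a.site for a in post_annotations]

    def cat_counts(annotations) -> dict[str, int]:
        c = {"TSS_proximal": 0, "intragenic": 0, "intergenic": 0}
        for a in annotations:
            c[a.category] += 1
        return c

    def safe_chi2(table: np.ndarray) -> tuple[float, float]:
        # a zero margin (e.g. a category absent from both datasets) carries
        # no evidence of a difference
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return float("nan"), 1.0
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        return float(chi2), float(p)

    pre_c, post_c = cat_counts(pre_annotations), cat_counts(post_annotations)
    n_pre, n_post = len(pre_annotations), len(post_annotations)
    category_tests = {}
    for cat in pre_c:
        table = np.array(
            [[pre_c[cat], n_pre - pre_c[cat]], [post_c[cat], n_post - post_c[cat]]]
        )
        chi2, p = safe_chi2(table)
        category_tests[cat] = {
            "pre_pct": 100 * pre_c[cat] / n_pre,
            "post_pct": 100 * post_c[cat] / n_post,
            "chi2": float(chi2),
            "pvalue": float(p),
        }

    def orient(annotations) -> tuple[int, int]:
        fwd = sum(1 for a in annotations if a.orientation == "forward")
        rev = sum(1 for a in annotations if a.orientation == "reverse")
        return fwd, rev

    pre_f, pre_r = orient(pre_annotations)
    post_f, post_r = orient(post_annotations)
    orientation = {
        "pre_forward": pre_f,
        "pre_reverse": pre_r,
        "post_forward": post_f,
        "post_reverse": post_r,
        "pre_binomial_pvalue": float(
            stats.binomtest(pre_r, pre_f + pre_r, 0.5).pvalue
        )
        if pre_f + pre_r
        else float("nan"),
        "post_binomial_pvalue": float(
            stats.binomtest(post_r, post_f + post_r, 0.5).pvalue
        )
        if post_f + post_r
        else float("nan"),
    }
    if (pre_f + pre_r) and (post_f + post_r):
        chi2, p = safe_chi2(np.array([[pre_r, pre_f], [post_r, post_f]]))
        orientation["two_sample_chi2"] = chi2
        orientation["two_sample_pvalue"] = p

    n_tests = len(category_tests) + 3
    bonferroni = {
        "family_size": n_tests,
        "alpha_corrected": 0.05 / n_tests,
    }

    shared = sorted(
        {(s.chrom, s.position) for s in pre_sites}
        & {(s.chrom, s.position) for s in post_sites}
    )
    cluster_overlap = (
        len(set(post_cluster_genes) & set(pre_cluster_genes)) / len(set(post_cluster_genes))
        if post_cluster_genes
        else float("nan")
    )
    ks = (
        compare_cluster_frequency(pre_sites, post_sites, n_subsamples, seed)
        if len(pre_sites) >= len(post_sites) >= 2
        else None
    )
    return {
        "category_tests": category_tests,
        "orientation": orientation,
        "bonferroni": bonferroni,
        "cluster_gene_overlap_fraction": cluster_overlap,
        "spacing_ks": ks,
        "shared_positions": {
            "n_shared": len(shared),
            "positions": [f"{c}:{p}" for c, p in shared],
        },
    }
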