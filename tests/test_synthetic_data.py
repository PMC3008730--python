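"""The synthetic-study generator: determinism, planted structure, truth tables."""

import numpy as np
import pytest

from retromap.genome_annotation import GeneIndex, annotate_sites
from retromap.pipeline import process_reads
from retromap.read_processing import Rejection, validate_and_trim
from retromap.synthetic_data import (
    DEFAULT_LTR_TAIL,
    SyntheticConfig,
    simulate_genes,
    simulate_genome,
    simulate_lampcr_reads,
    simulate_sites,
)


class TestGenome:
    def test_seed_determinism(self, small_config):
        g1, _ = simulate_genome(small_config)
        g2, _ = simulate_genome(small_config)
        assert g1 == g2

    def test_motif_count_near_binomial_expectation(self):
        cfg = SyntheticConfig(seed=3, genome_length=1_000_000, n_chromosomes=1)
        genome, rmap = simulate_genome(cfg)
        expect = 1_000_000 / 256
        sd = np.sqrt(1_000_000 / 256)
        for enzyme in rmap.sites:
            n = sum(len(v) for v in rmap.sites[enzyme].values())
            assert abs(n - expect) < 5 * sd

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, genome_length=5_000)


class TestGenes:
    def test_valid_nonoverlapping_models(self, small_genes):
        genes, _ = small_genes
        by_chrom = {}
        for g in genes:
            assert g.tx_start < g.tx_end
            if g.transcript_id.endswith(".1"):
                by_chrom.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_gene_count_and_expression_table(self, small_genes, small_config):
        genes, expression = small_genes
        gene_ids = {g.gene_id for g in genes}
        assert len(gene_ids) == small_config.n_genes
        assert set(expression.values) == gene_ids

    def test_full_detection_rate(self, small_genome):
        genome, _ = small_genome
        cfg = SyntheticConfig(seed=5, genome_length=200_000, n_chromosomes=2,
                              n_genes=15, expression_detection_rate=1.0)
        _, expression = simulate_genes(genome, cfg)
        assert all(expression.detected.values())

    def test_strand_balance(self):
        cfg = SyntheticConfig(seed=13, genome_length=3_000_000, n_chromosomes=2, n_genes=300)
        genome, _ = simulate_genome(cfg)
        genes, _ = simulate_genes(genome, cfg)
        primary = [g for g in genes if g.transcript_id.endswith(".1")]
        frac_plus = np.mean([g.strand == "+" for g in primary])
        assert abs(frac_plus - 0.5) < 4 * np.sqrt(0.25 / len(primary))


class TestSites:
    def test_unbiased_placement_matches_uniform_expectation(self, small_genome, small_genes):
        """With no TSS bias the TSS-proximal fraction equals the exact
        coverage of the union of +/-2.5 kb TSS windows."""
        genome, _ = small_genome
        genes, _ = small_genes
        cfg = SyntheticConfig(seed=19, genome_length=200_000, n_chromosomes=2,
                              n_genes=20, n_sites=2_000, tss_bias_fraction=0.0)
        sites, truth = simulate_sites(genome, genes, cfg)
        # exact union coverage of TSS windows (the analytic expectation)
        covered = 0
        for chrom, seq in genome.items():
            mask = np.zeros(len(seq), dtype=bool)
            for g in genes:
                if g.chrom == chrom:
                    mask[max(0, g.tss - 2_500) : g.tss + 2_501] = True
            covered += mask.sum()
        expected = covered / sum(len(s) for s in genome.values())
        observed = (truth["category"] == "TSS_proximal").mean()
        assert abs(observed - expected) < 4 * np.sqrt(expected * (1 - expected) / len(sites))

    def test_full_tss_bias_concentrates_sites(self, small_genome, small_genes):
        genome, _ = small_genome
        genes, _ = small_genes
        cfg = SyntheticConfig(seed=23, genome_length=200_000, n_chromosomes=2,
                              n_genes=20, n_sites=500, tss_bias_fraction=1.0, tss_sd=500.0)
        _, truth = simulate_sites(genome, genes, cfg)
        assert (truth["category"] == "TSS_proximal").mean() >= 0.95

    def test_orientation_bias_recovered_by_annotation(self, small_genome, small_genes):
        genome, _ = small_genome
        genes, _ = small_genes
        cfg = SyntheticConfig(seed=29, genome_length=200_000, n_chromosomes=2,
                              n_genes=20, n_sites=1_500, tss_bias_fraction=0.5,
                              tss_sd=800.0, orientation_reverse_prob=0.63)
        sites, _ = simulate_sites(genome, genes, cfg)
        ann = annotate_sites(sites, GeneIndex(genes))
        fwd = sum(1 for a in ann if a.orientation == "forward")
        rev = sum(1 for a in ann if a.orientation == "reverse")
        rec = rev / (fwd + rev)
        assert abs(rec - 0.63) < 4 * np.sqrt(0.63 * 0.37 / (fwd + rev))

    def test_cluster_boost_tightens_spacings(self, small_genome, small_genes):
        genome, _ = small_genome
        genes, _ = small_genes
        base = dict(seed=31, genome_length=200_000, n_chromosomes=2, n_genes=20, n_sites=400)
        from retromap.cluster_analysis import consecutive_distances

        _, t0 = simulate_sites(genome, genes, SyntheticConfig(**base, cluster_boost=0.0))
        _, t1 = simulate_sites(genome, genes, SyntheticConfig(**base, cluster_boost=0.5))

        from retromap.read_processing import IntegrationSite

        def spacing(truth):
            sites = [
                IntegrationSite(r.chrom, int(r.position), r.strand, "s", "pre")
                for r in truth.itertuples()
            ]
            return np.median(consecutive_distances(sites).distances)

        assert spacing(t1) < spacing(t0)

    def test_truth_table_consistent_with_sites(self, small_genome, small_genes):
        genome, _ = small_genome
        genes, _ = small_genes
        cfg = SyntheticConfig(seed=37, genome_length=200_000, n_chromosomes=2,
                              n_genes=20, n_sites=300)
        sites, truth = simulate_sites(genome, genes, cfg)
        assert len(sites) == len(truth) == 300
        for s, r in zip(sites, truth.itertuples()):
            assert (s.chrom, s.position, s.strand) == (r.chrom, r.position, r.strand)


class TestReads:
    def test_error_free_fragment_matches_reference(self, small_genome, small_genes, small_config):
        genome, rmap = small_genome
        genes, _ = small_genes
        sites, _ = simulate_sites(genome, genes, small_config)
        reads, alignments, truth = simulate_lampcr_reads(
            sites[:50], genome, rmap, error_rate=0.0, seed=1
        )
        for read, row in zip(reads, truth.itertuples()):
            frag = read.sequence[len(DEFAULT_LTR_TAIL):]
            if row.strand == "+":
                ref = genome[row.chrom][row.position : row.position + row.fragment_len]
                assert frag == ref
            assert row.n_errors == 0

    def test_short_fragment_rejected_downstream(self):
        genome = {"c": "TTTT" + "AATT" + "GGGGGGGGGGGGGGG" + "AATT" + "T" * 30}
        from retromap.random_controls import build_restriction_map
        from retromap.read_processing import IntegrationSite, RawRead

        rmap = build_restriction_map(genome)
        site = IntegrationSite("c", 8, "+", "s", "pre")  # 15 bp to next AATT
        reads, alignments, truth = simulate_lampcr_reads([site], genome, rmap)
        assert truth.loc[0, "fragment_len"] == 15
        res = validate_and_trim(reads[0], DEFAULT_LTR_TAIL)
        assert isinstance(res, Rejection) and res.reason == "too_short"

    def test_planted_errors_mirrored_in_psl(self, small_genome, small_genes, small_config):
        genome, rmap = small_genome
        genes, _ = small_genes
        sites, _ = simulate_sites(genome, genes, small_config)
        _, alignments, truth = simulate_lampcr_reads(
            sites[:200], genome, rmap, error_rate=0.02, seed=2
        )
        by_id = {a.query_id: a for a in alignments}
        planted = truth[truth["fragment_len"] >= 1]
        assert (planted["n_errors"] > 0).any()
        for r in planted.itertuples():
            assert by_id[r.read_id].mismatches == r.n_errors

    def test_end_to_end_recovery_at_zero_error(self, small_genome, small_genes, small_config):
        """The full read-processing chain recovers every site whose
        restriction fragment is >= 20 bp, with no false positions."""
        genome, rmap = small_genome
        genes, _ = small_genes
        sites, _ = simulate_sites(genome, genes, small_config)
        barcodes = {"s1": "ACGTAC"}
        sites = [
            type(s)(s.chrom, s.position, s.strand, "s1", "pre") for s in sites
        ]
        reads, alignments, truth = simulate_lampcr_reads(
            sites, genome, rmap, barcodes=barcodes, error_rate=0.0, seed=3
        )
        recovered, counts = process_reads(reads, barcodes, alignments, DEFAULT_LTR_TAIL, "pre")
        truth_keys = {
            (r.chrom, r.position, r.strand)
            for r in truth.itertuples()
            if r.fragment_len >= 20
        }
        got = {(s.chrom, s.position, s.strand) for s in recovered}
        assert got == truth_keys
        assert counts["reads_in"] == counts["accepted_reads"] + counts["too_short"] + (
            counts["no_ltr"] + counts["unassigned"] + counts["unaligned"] + counts["multi_mapped"]
        )
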