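"""Spacing distributions, FDR thresholds, cluster calling and comparisons."""

import numpy as np
import pytest
from scipy import stats

from retromap.cluster_analysis import (
    call_clusters,
    compare_cluster_frequency,
    consecutive_distances,
    cluster_target_genes,
    estimate_cluster_threshold,
    gene_set_overrepresentation,
)
from retromap.genome_annotation import GeneModel
from retromap.random_controls import RandomSitePool
from retromap.read_processing import IntegrationSite


def sites_at(positions, chrom="chr1", strand="+"):
    return [IntegrationSite(chrom, p, strand, "s", "pre") for p in positions]


def uniform_pool(n, L, seed, chroms=("chr1",)):
    rng = np.random.default_rng(seed)
    ci = rng.integers(0, len(chroms), size=n)
    return RandomSitePool(
        chroms=np.array([chroms[i] for i in ci], dtype=object),
        positions=rng.integers(0, L, size=n),
        strands=np.array(["+"] * n, dtype=object),
        d_re=np.zeros(n, dtype=int),
        seed=seed,
    )


class TestConsecutiveDistances:
    def test_sorted_successive_differences(self):
        d = consecutive_distances(sites_at([100, 350, 1_000]))
        assert d.distances.tolist() == [250, 650]

    def test_singletons_on_each_chromosome_give_empty(self):
        d = consecutive_distances(
            sites_at([100]) + sites_at([500], chrom="chr2")
        )
        assert len(d.distances) == 0 and d.n_sites == 2

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(31)
        positions = sorted(set(rng.integers(0, 10_000, size=100).tolist()))
        sites = sites_at(positions)
        # oracle: for each site, distance to nearest following site
        oracle = sorted(
            min(q - p for q in positions if q > p)
            for p in positions
            if any(q > p for q in positions)
        )
        assert consecutive_distances(sites).distances.tolist() == oracle

    def test_strand_and_duplicates_ignored(self):
        sites = sites_at([100, 500]) + sites_at([500], strand="-")
        assert consecutive_distances(sites).distances.tolist() == [400]


class TestThresholdEstimate:
    def test_closed_form_for_uniform_spacings(self):
        """At density lambda, the 1% quantile of exponential spacings is
        -ln(1-0.01)/lambda; the resampled empirical threshold must agree."""
        L, n_sites = 10_000_000, 1_000
        pool = uniform_pool(20_000, L, seed=41)
        est = estimate_cluster_threshold(n_sites, pool, fdr=0.01, n_resamples=200, seed=1)
        lam = n_sites / L
        expected = -np.log(1 - 0.01) / lam
        assert abs(est.threshold_bp - expected) / expected < 0.10

    def test_fdr_monotonicity(self):
        pool = uniform_pool(5_000, 1_000_000, seed=43)
        t1 = estimate_cluster_threshold(500, pool, fdr=0.01, n_resamples=100, seed=2)
        t5 = estimate_cluster_threshold(500, pool, fdr=0.05, n_resamples=100, seed=2)
        assert t5.threshold_bp > t1.threshold_bp

    def test_seed_determinism(self):
        pool = uniform_pool(5_000, 1_000_000, seed=47)
        a = estimate_cluster_threshold(500, pool, n_resamples=50, seed=9)
        b = estimate_cluster_threshold(500, pool, n_resamples=50, seed=9)
        assert a.threshold_bp == b.threshold_bp

    def test_threshold_shrinks_with_dataset_size(self):
        """Doubling the number of sites densifies random spacings."""
        pool = uniform_pool(20_000, 10_000_000, seed=53)
        t_small = estimate_cluster_threshold(500, pool, n_resamples=100, seed=3)
        t_large = estimate_cluster_threshold(1_000, pool, n_resamples=100, seed=3)
        assert t_large.threshold_bp < t_small.threshold_bp

    def test_oversized_request_rejected(self):
        pool = uniform_pool(100, 1_000_000, seed=59)
        with pytest.raises(ValueError):
            estimate_cluster_threshold(101, pool)


def brute_force_clusters(positions, threshold):
    """Oracle: all maximal index ranges with every adjacent gap <= threshold."""
    pos = sorted(set(positions))
    out = []
    n = len(pos)
    for i in range(n):
        for j in range(i + 1, n):
            gaps_ok = all(pos[k + 1] - pos[k] <= threshold for k in range(i, j))
            left_max = i == 0 or pos[i] - pos[i - 1] > threshold
            right_max = j == n - 1 or pos[j + 1] - pos[j] > threshold
            if gaps_ok and left_max and right_max:
                out.append(tuple(pos[i : j + 1]))
    return out


class TestCallClusters:
    def test_worked_example(self):
        clusters = call_clusters(
            sites_at([100, 600, 5_000, 5_400, 5_900, 20_000]), 1_000
        )
        assert [(c.start, c.end) for c in clusters] == [(100, 600), (5_000, 5_900)]
        assert [c.size for c in clusters] == [2, 3]

    def test_no_close_pairs_no_clusters(self):
        assert call_clusters(sites_at([0, 10_000, 20_000]), 100) == []

    def test_all_close_single_cluster(self):
        clusters = call_clusters(sites_at([0, 50, 120, 190]), 100)
        assert len(clusters) == 1 and clusters[0].size == 4

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(61)
        for trial in range(5):
            positions = rng.integers(0, 50_000, size=200).tolist()
            threshold = int(rng.integers(50, 2_000))
            called = call_clusters(sites_at(positions), threshold)
            assert [c.positions for c in called] == brute_force_clusters(
                positions, threshold
            )

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            call_clusters([], 0)


class TestClusterTargetGenes:
    def make(self, tss_offset):
        from retromap.cluster_analysis import Cluster

        cluster = Cluster("chr1", 100_000, 101_000, (100_000, 101_000))
        gene = GeneModel(
            "t", "g", "g", "chr1", "+", 101_000 + tss_offset, 101_000 + tss_offset + 5_000
        )
        return [cluster], [gene]

    def test_boundary_inclusion(self):
        clusters, genes = self.make(49_999)
        per, union = cluster_target_genes(clusters, genes)
        assert union == {"g"}

    def test_boundary_exclusion(self):
        clusters, genes = self.make(50_001)
        _, union = cluster_target_genes(clusters, genes)
        assert union == set()

    def test_union_deduplicates(self):
        from retromap.cluster_analysis import Cluster

        clusters = [
            Cluster("chr1", 0, 1_000, (0, 1_000)),
            Cluster("chr1", 2_000, 3_000, (2_000, 3_000)),
        ]
        genes = [GeneModel("t", "g", "g", "chr1", "+", 1_500, 6_000)]
        per, union = cluster_target_genes(clusters, genes)
        assert per == [{"g"}, {"g"}] and union == {"g"}


class TestCompareClusterFrequency:
    def test_identical_datasets_ks_zero(self):
        sites = sites_at(list(range(0, 10_000, 100)))
        res = compare_cluster_frequency(sites, sites, n_subsamples=3, seed=1)
        assert res["median_statistic"] == 0.0
        assert res["median_pvalue"] == pytest.approx(1.0)

    def test_null_subsampling_rarely_significant(self):
        rng = np.random.default_rng(67)
        pre = sites_at(sorted(rng.choice(2_000_000, size=2_000, replace=False)))
        post = sites_at(sorted(rng.choice(2_000_000, size=400, replace=False)))
        res = compare_cluster_frequency(pre, post, n_subsamples=10, seed=2)
        assert sum(p > 0.05 for p in res["pvalues"]) >= 8

    def test_clustered_post_detected(self):
        rng = np.random.default_rng(71)
        pre = sites_at(sorted(rng.choice(2_000_000, size=2_000, replace=False)))
        # strongly clustered alternative: sites in tight clumps
        centers = rng.choice(2_000_000, size=40, replace=False)
        post_pos = sorted(
            {int(c + o) for c in centers for o in rng.integers(0, 200, size=10)}
        )
        res = compare_cluster_frequency(pre, sites_at(post_pos), n_subsamples=10, seed=3)
        assert res["median_pvalue"] < 0.01

    def test_pre_smaller_than_post_rejected(self):
        with pytest.raises(ValueError):
            compare_cluster_frequency(sites_at([1, 2]), sites_at([1, 2, 3]))


class TestOverrepresentation:
    def test_continuity_corrected_worked_example(self):
        """8/10 vs 2/10 in a 2x2 with Yates correction: chi2 = 5, p ~ 0.025."""
        res = gene_set_overrepresentation(
            [f"t{i}" for i in range(10)],
            {f"t{i}" for i in range(8)} | {f"b{i}" for i in range(2)},
            [f"b{i}" for i in range(10)],
        )
        assert res["chi2"] == pytest.approx(5.0)
        assert res["pvalue"] == pytest.approx(0.02535, abs=1e-4)

    def test_identical_proportions_not_significant(self):
        res = gene_set_overrepresentation(
            [f"t{i}" for i in range(20)],
            {f"t{i}" for i in range(5)} | {f"b{i}" for i in range(5)},
            [f"b{i}" for i in range(20)],
        )
        assert res["pvalue"] > 0.9

    def test_pvalue_decreases_with_effect(self):
        def p_at(k):
            return gene_set_overrepresentation(
                [f"t{i}" for i in range(40)],
                {f"t{i}" for i in range(k)},
                [f"b{i}" for i in range(40)] + [f"t{i}" for i in range(4)],
            )["pvalue"]

        assert p_at(30) < p_at(20) < p_at(12)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            gene_set_overrepresentation([], set(), ["b"])
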