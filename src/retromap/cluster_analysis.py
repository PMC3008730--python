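"""Integration-cluster detection with a data-size-dependent FDR threshold.

Integration sites cluster in preferred genomic regions.  A cluster is a
maximal run of >=2 sites in which every adjacent spacing is below a
threshold; the threshold is not fixed but estimated from the data size by
resampling equal-sized sets from a restriction-matched random pool and
taking the quantile of their inter-site spacing distribution at the
desired false discovery rate (1% by default).  Because the quantile
shrinks as the number of sites grows, datasets of different depth can be
compared on the same footing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from retromap.genome_annotation import GeneIndex, GeneModel, _as_index
from retromap.random_controls import RandomSitePool
from retromap.read_processing import IntegrationSite

__all__ = [
    "SpacingDistribution",
    "ThresholdEstimate",
    "Cluster",
    "consecutive_distances",
    "estimate_cluster_threshold",
    "call_clusters",
    "cluster_target_genes",
    "compare_cluster_frequency",
    "gene_set_overrepresentation",
]


@dataclass
class SpacingDistribution:
    """Sorted distances between each site and the next site on its chromosome."""

    distances: np.ndarray
    n_sites: int


@dataclass
class ThresholdEstimate:
    threshold_bp: int
    fdr: float
    n_resamples: int
    n_sites: int
    seed: int
    n_pooled_distances: int


@dataclass
class Cluster:
    chrom: str
    start: int
    end: int
    positions: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.positions)


def _positions_by_chrom(
    sites: "Iterable[IntegrationSite] | RandomSitePool",
) -> dict[str, np.ndarray]:
    """Sorted, deduplicated positions per chromosome (strand ignored)."""
    per: dict[str, set[int]] = {}
    if isinstance(sites, RandomSitePool):
        for chrom, pos in zip(sites.chroms, sites.positions):
            per.setdefault(chrom, set()).add(int(pos))
    else:
        for s in sites:
            per.setdefault(s.chrom, set()).add(s.position)
    return {c: np.array(sorted(p), dtype=int) for c, p in per.items()}


def consecutive_distances(
    sites: "Iterable[IntegrationSite] | RandomSitePool",
) -> SpacingDistribution:
    """Spacings between consecutive sites per chromosome, pooled and sorted.

    Strand is ignored and co-located sites are deduplicated, so every
    spacing is >= 1.  Chromosomes carrying fewer than two sites contribute
    no spacings.
    """
    per = _positions_by_chrom(sites)
    n_sites = sum(len(p) for p in per.values())
    diffs = [np.diff(p) for p in per.values() if len(p) >= 2]
    distances = (
        np.sort(np.concatenate(diffs)) if diffs else np.array([], dtype=int)
    )
    return SpacingDistribution(distances=distances, n_sites=n_sites)


def estimate_cluster_threshold(
    n_sites: int,
    pool: RandomSitePool,
    fdr: float = 0.01,
    n_resamples: int = 1_000,
    seed: int = 0,
) -> ThresholdEstimate:
    """FDR-quantile of random inter-site spacings at the dataset's size.

    Each resample draws ``n_sites`` pool entries without replacement and
    computes its consecutive-spacing distribution; all resampled distances
    are pooled and the threshold is the left-continuous empirical quantile:
    the largest observed distance d with fraction(distances < d) <= fdr.
    """
    if n_sites > len(pool):
        raise ValueError(f"n_sites={n_sites} exceeds pool size {len(pool)}")
    if n_sites < 2:
        raise ValueError("need at least 2 sites to form spacings")
    rng = np.random.default_rng(seed)
    # Sort the pool once; resampling then only needs index selection.
    chrom_codes, chrom_uniques = _encode_chroms(pool)
    order = np.lexsort((pool.positions, chrom_codes))
    sorted_pos = pool.positions[order]
    sorted_code = chrom_codes[order]
    all_dists: list[np.ndarray] = []
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(len(pool), size=n_sites, replace=False))
        pos = sorted_pos[idx]
        code = sorted_code[idx]
        same = code[1:] == code[:-1]
        d = (pos[1:] - pos[:-1])[same]
        d = d[d > 0]  # duplicate positions within a resample carry no spacing
        all_dists.append(d)
    pooled = np.sort(np.concatenate(all_dists))
    threshold = _left_quantile(pooled, fdr)
    return ThresholdEstimate(
        threshold_bp=int(threshold),
        fdr=fdr,
        n_resamples=n_resamples,
        n_sites=n_sites,
        seed=seed,
        n_pooled_distances=len(pooled),
    )


def _encode_chroms(pool: RandomSitePool) -> tuple[np.ndarray, np.ndarray]:
    uniques, codes = np.unique(pool.chroms.astype(str), return_inverse=True)
    return codes, uniques


def _left_quantile(sorted_values: np.ndarray, fdr: float) -> int:
    """Largest value v with fraction(values < v) <= fdr."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("no spacings available for threshold estimation")
    counts_less = np.searchsorted(sorted_values, sorted_values, side="left")
    ok = counts_less / n <= fdr
    return int(sorted_values[ok].max())


def call_clusters(
    sites: Iterable[IntegrationSite], threshold_bp: int
) -> list[Cluster]:
    """Single-linkage chaining: maximal runs with all adjacent gaps <= threshold.

    Positions are deduplicated per chromosome (strand and sample ignored);
    runs of at least two sites are emitted.
    """
    if threshold_bp < 1:
        raise ValueError("threshold_bp must be >= 1")
    clusters: list[Cluster] = []
    for chrom in sorted(per := _positions_by_chrom(sites)):
        pos = per[chrom]
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        breaks = np.flatnonzero(gaps > threshold_bp)
        start = 0
        for b in list(breaks) + [len(pos) - 1]:
            run = pos[start : b + 1]
            if len(run) >= 2:
                clusters.append(
                    Cluster(
                        chrom=chrom,
                        start=int(run[0]),
                        end=int(run[-1]),
                        positions=tuple(int(p) for p in run),
                    )
                )
            start = b + 1
    return clusters


def cluster_target_genes(
    clusters: Sequence[Cluster],
    genes: "GeneIndex | Iterable[GeneModel]",
    window: int = 50_000,
) -> tuple[list[set[str]], set[str]]:
    """Genes with a TSS within ±window of each cluster interval, plus the union."""
    index = _as_index(genes)
    per_cluster: list[set[str]] = []
    for cl in clusters:
        hit: set[str] = set()
        # any isoform TSS inside [start-window, end+window]
        for g in index.genes:
            if g.chrom == cl.chrom and cl.start - window <= g.tss <= cl.end + window:
                hit.add(g.gene_id)
        per_cluster.append(hit)
    union: set[str] = set().union(*per_cluster) if per_cluster else set()
    return per_cluster, union


def compare_cluster_frequency(
    pre_sites: Sequence[IntegrationSite],
    post_sites: Sequence[IntegrationSite],
    n_subsamples: int = 10,
    seed: int = 0,
) -> dict:
    """KS comparison of spacing distributions at equal numerical complexity.

    The larger (pre) dataset is subsampled without replacement to the size
    of the smaller (post) dataset ``n_subsamples`` times; each subsample's
    consecutive-spacing distribution is compared to the post distribution
    with a two-sample Kolmogorov-Smirnov test.  Returns per-subsample
    statistics and p-values plus their medians.
    """
    pre = list(pre_sites)
    post = list(post_sites)
    if len(pre) < len(post):
        raise ValueError("pre dataset must be at least as large as post")
    post_d = consecutive_distances(post).distances
    rng = np.random.default_rng(seed)
    stats_, pvals = [], []
    for _ in range(n_subsamples):
        idx = rng.choice(len(pre), size=len(post), replace=False)
        sub_d = consecutive_distances([pre[i] for i in idx]).distances
        res = stats.ks_2samp(sub_d, post_d, method="asymp")
        stats_.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    return {
        "statistics": stats_,
        "pvalues": pvals,
        "median_statistic": float(np.median(stats_)),
        "median_pvalue": float(np.median(pvals)),
        "n_subsamples": n_subsamples,
        "n_per_sample": len(post),
    }


def gene_set_overrepresentation(
    target_genes: Iterable[str],
    annotated_set: set[str],
    background_target_genes: Iterable[str],
) -> dict:
    """Two-proportion test (chi-square with continuity correction).

    Compares the fraction of ``target_genes`` falling in ``annotated_set``
    (e.g. a cancer-gene compilation) with the same fraction among genes
    targeted by random control sites.
    """
    t = set(target_genes)
    b = set(background_target_genes)
    if not t or not b:
        raise ValueError("empty gene list")
    t_in = len(t & annotated_set)
    b_in = len(b & annotated_set)
    table = np.array([[t_in, len(t) - t_in], [b_in, len(b) - b_in]])
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValueError("zero denominator in over-representation test")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return {
        "target_fraction": t_in / len(t),
        "background_fraction": b_in / len(b),
        "n_target": len(t),
        "n_background": len(b),
        "chi2": float(chi2),
        "pvalue": float(p),
    }
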