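"""Restriction-matched random controls for integration-site statistics.

LAM-PCR only recovers junctions whose flank reaches a restriction site
within a sequenceable distance, so an unconstrained uniform control set is
biased relative to the experimental sites.  Two control constructs correct
for this:

* a large in-silico pool of uniform random sites kept only when the
  nearest recognition site of the digestion enzymes lies within
  [min_d, max_d] bp (defaults 20-500 bp: below 20 bp the flank cannot be
  mapped, above ~500 bp the amplicon sequences poorly), used as background
  for cluster FDR estimation and genomic-distribution comparisons; and
* per-site matched controls drawn so that each control lies EXACTLY the
  same number of bases from a recognition site as its experimental site,
  used as strata in the epigenetic ROC statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from retromap.read_processing import IntegrationSite

__all__ = [
    "ENZYMES",
    "RestrictionMap",
    "RandomSitePool",
    "MatchedControlSet",
    "build_restriction_map",
    "distance_to_nearest_re",
    "generate_random_pool",
    "match_controls",
    "match_controls_batch",
]

# 4-cutters used for the LAM-PCR digestion; all three motifs are
# palindromic so a single forward scan covers both strands.
ENZYMES: dict[str, str] = {
    "Tsp509I": "AATT",
    "HpyCH4IV": "ACGT",
    "HinP1I": "GCGC",
}


@dataclass
class RestrictionMap:
    """Sorted recognition-site start coordinates per enzyme per chromosome."""

    sites: dict[str, dict[str, np.ndarray]]
    chrom_lengths: dict[str, int]
    _merged: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def merged(self, chrom: str) -> np.ndarray:
        """Union of all enzymes' site coordinates on one chromosome, sorted."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"chromosome {chrom!r} not in restriction map")
        if chrom not in self._merged:
            arrays = [
                per_chrom[chrom]
                for per_chrom in self.sites.values()
                if chrom in per_chrom
            ]
            self._merged[chrom] = (
                np.unique(np.concatenate(arrays)) if arrays else np.array([], dtype=int)
            )
        return self._merged[chrom]


@dataclass
class RandomSitePool:
    """Random genomic sites passing the restriction-distance filter."""

    chroms: np.ndarray  # object array of chromosome names
    positions: np.ndarray
    strands: np.ndarray
    d_re: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MatchedControlSet:
    """k random positions at exactly the experimental site's d_re."""

    site: IntegrationSite
    d_re: int
    controls: tuple[tuple[str, int, str], ...]  # (chrom, position, strand)


def build_restriction_map(
    genome: Mapping[str, str], enzymes: Mapping[str, str] = ENZYMES
) -> RestrictionMap:
    """Scan a genome for exact recognition-motif occurrences.

    Overlapping occurrences are counted; windows containing N never match.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    sites: dict[str, dict[str, np.ndarray]] = {}
    for enzyme, motif in enzymes.items():
        per_chrom: dict[str, np.ndarray] = {}
        for chrom, seq in genome.items():
            seq = seq.upper()
            hits = []
            start = seq.find(motif)
            while start != -1:
                hits.append(start)
                start = seq.find(motif, start + 1)
            per_chrom[chrom] = np.array(hits, dtype=int)
        sites[enzyme] = per_chrom
    lengths = {chrom: len(seq) for chrom, seq in genome.items()}
    return RestrictionMap(sites=sites, chrom_lengths=lengths)


def distance_to_nearest_re(
    position: int, chrom: str, rmap: RestrictionMap
) -> int:
    """Distance (bp) to the nearest recognition-site start, any enzyme, either side."""
    merged = rmap.merged(chrom)
    if len(merged) == 0:
        raise ValueError(f"no recognition sites on chromosome {chrom!r}")
    i = np.searchsorted(merged, position)
    best = np.inf
    if i < len(merged):
        best = merged[i] - position
    if i > 0:
        best = min(best, position - merged[i - 1])
    return int(best)


def _distances_vectorized(positions: np.ndarray, merged: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(merged, positions)
    right = np.where(idx < len(merged), merged[np.minimum(idx, len(merged) - 1)] - positions, np.iinfo(np.int64).max)
    left = np.where(idx > 0, positions - merged[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
    return np.minimum(right, left)


def generate_random_pool(
    genome: Mapping[str, str],
    rmap: RestrictionMap,
    n: int = 40_000,
    min_d: int = 20,
    max_d: int = 500,
    seed: int = 0,
) -> RandomSitePool:
    """Rejection-sample n uniform genomic sites with min_d <= d_re <= max_d.

    Chromosomes are weighted by length, strand is uniform.  Aborts if the
    empirical eligibility rate falls below 1e-4 (the genome then cannot
    plausibly supply the pool).
    """
    rng = np.random.default_rng(seed)
    chrom_names = sorted(rmap.chrom_lengths)
    lengths = np.array([rmap.chrom_lengths[c] for c in chrom_names], dtype=float)
    weights = lengths / lengths.sum()
    kept_chrom: list[str] = []
    kept_pos: list[int] = []
    kept_strand: list[str] = []
    kept_d: list[int] = []
    tried = 0
    while len(kept_pos) < n:
        batch = max(1024, 2 * (n - len(kept_pos)))
        ci = rng.choice(len(chrom_names), size=batch, p=weights)
        pos = (rng.random(batch) * lengths[ci]).astype(int)
        strands = np.where(rng.random(batch) < 0.5, "+", "-")
        tried += batch
        for c in np.unique(ci):
            chrom = chrom_names[c]
            mask = ci == c
            d = _distances_vectorized(pos[mask], rmap.merged(chrom))
            ok = (d >= min_d) & (d <= max_d)
            kept_chrom.extend([chrom] * int(ok.sum()))
            kept_pos.extend(pos[mask][ok].tolist())
            kept_strand.extend(strands[mask][ok].tolist())
            kept_d.extend(d[ok].tolist())
        if tried >= 100_000 and len(kept_pos) / tried < 1e-4:
            raise RuntimeError(
                f"random-pool eligibility rate {len(kept_pos) / tried:.2e} < 1e-4 "
                f"after {tried} draws; genome too restriction-poor for "
                f"d_re in [{min_d}, {max_d}]"
            )
    return RandomSitePool(
        chroms=np.array(kept_chrom[:n], dtype=object),
        positions=np.array(kept_pos[:n], dtype=int),
        strands=np.array(kept_strand[:n], dtype=object),
        d_re=np.array(kept_d[:n], dtype=int),
        seed=seed,
    )


def candidate_positions_at_distance(
    rmap: RestrictionMap, chrom: str, d: int
) -> np.ndarray:
    """All positions on ``chrom`` whose nearest recognition site is exactly d bp away."""
    merged = rmap.merged(chrom)
    length = rmap.chrom_lengths[chrom]
    cand = np.unique(np.concatenate([merged - d, merged + d]))
    cand = cand[(cand >= 0) & (cand < length)]
    dist = _distances_vectorized(cand, merged)
    return cand[dist == d]


def match_controls_batch(
    sites: Iterable[IntegrationSite],
    rmap: RestrictionMap,
    k: int = 3,
    seed: int = 0,
) -> list[MatchedControlSet]:
    """Matched controls for many sites, caching candidates per distance.

    Sites sharing a d_re reuse one genome-wide candidate enumeration, so
    matching a full dataset costs one scan per distinct distance.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(rmap.chrom_lengths)
    cache: dict[int, list[tuple[str, int]]] = {}
    out: list[MatchedControlSet] = []
    for site in sites:
        d = distance_to_nearest_re(site.position, site.chrom, rmap)
        if d not in cache:
            cache[d] = [
                (chrom, int(p))
                for chrom in chroms
                for p in candidate_positions_at_distance(rmap, chrom, d)
            ]
        cand = [
            c for c in cache[d] if c != (site.chrom, site.position)
        ]
        if len(cand) < k:
            raise ValueError(
                f"only {len(cand)} candidate positions at d_re={d} for site "
                f"{site.chrom}:{site.position} (need {k})"
            )
        idx = rng.choice(len(cand), size=k, replace=False)
        controls = tuple(
            (cand[i][0], cand[i][1], "+" if rng.random() < 0.5 else "-")
            for i in sorted(idx)
        )
        out.append(MatchedControlSet(site=site, d_re=d, controls=controls))
    return out


def match_controls(
    site: IntegrationSite,
    rmap: RestrictionMap,
    k: int = 3,
    seed: int = 0,
    genome_wide: bool = True,
) -> MatchedControlSet:
    """Draw k control positions at exactly the site's restriction distance.

    Candidates are enumerated genome-wide from the recognition-site
    coordinates (p = r ± d with nearest distance equal to d), the
    experimental position itself is excluded, and k are drawn uniformly
    without replacement.  Control strands are drawn uniformly.
    """
    d = distance_to_nearest_re(site.position, site.chrom, rmap)
    rng = np.random.default_rng(seed)
    chroms = sorted(rmap.chrom_lengths) if genome_wide else [site.chrom]
    cand: list[tuple[str, int]] = []
    for chrom in chroms:
        for p in candidate_positions_at_distance(rmap, chrom, d):
            if chrom == site.chrom and int(p) == site.position:
                continue
            cand.append((chrom, int(p)))
    if len(cand) < k:
        raise ValueError(
            f"only {len(cand)} candidate positions at d_re={d} for site "
            f"{site.chrom}:{site.position} (need {k})"
        )
    idx = rng.choice(len(cand), size=k, replace=False)
    controls = tuple(
        (cand[i][0], cand[i][1], "+" if rng.random() < 0.5 else "-")
        for i in sorted(idx)
    )
    return MatchedControlSet(site=site, d_re=d, controls=controls)
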