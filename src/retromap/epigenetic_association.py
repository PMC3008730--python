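"""Stratified ROC-area association between sites and epigenetic tracks.

Chromatin features (histone-modification or protein-binding ChIP-seq
intervals) are counted in a ±500 bp window around each integration site
and around its restriction-matched random controls.  Each site and its k
controls form one stratum; the stratum score is the mid-rank probability
that the experimental count exceeds a control count,

    s_i = [#(c_ij < e_i) + 0.5 * #(c_ij = e_i)] / k,

and the ROC area is the mean score over strata.  0.5 means no
association, values above 0.5 a positive and below 0.5 a negative
correlation of the feature with integration.  Significance comes from
permuting the experimental/control labels within strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from retromap.random_controls import MatchedControlSet
from retromap.read_processing import IntegrationSite

__all__ = [
    "EpigeneticTrack",
    "AssociationResult",
    "count_features_in_window",
    "roc_association",
    "association_matrix",
]


class EpigeneticTrack:
    """A named feature track reduced to sorted per-chromosome midpoints.

    Interval features are represented by their midpoint floor((start+end)/2);
    point features (single-coordinate tags) by the coordinate itself.
    """

    def __init__(self, name: str, midpoints: Mapping[str, Sequence[int]]):
        self.name = name
        self.midpoints: dict[str, np.ndarray] = {
            chrom: np.sort(np.asarray(mids, dtype=int))
            for chrom, mids in midpoints.items()
        }

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Iterable[tuple[str, int, int]]
    ) -> "EpigeneticTrack":
        per: dict[str, list[int]] = {}
        for chrom, start, end in intervals:
            if not start < end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            per.setdefault(chrom, []).append((start + end) // 2)
        return cls(name, per)

    def n_features(self) -> int:
        return sum(len(m) for m in self.midpoints.values())


@dataclass
class AssociationResult:
    track: str
    category: str  # all | TSS_proximal | intragenic | intergenic
    roc_area: float
    n_strata: int
    pvalue: float
    flag: str = ""  # "" or insufficient_data


def count_features_in_window(
    position: int, chrom: str, track: EpigeneticTrack, half_window: int = 500
) -> int:
    """Number of feature midpoints m with |m - position| <= half_window."""
    mids = track.midpoints.get(chrom)
    if mids is None or len(mids) == 0:
        return 0
    lo = np.searchsorted(mids, position - half_window, side="left")
    hi = np.searchsorted(mids, position + half_window, side="right")
    return int(hi - lo)


def _stratum_scores(exp: np.ndarray, ctl: np.ndarray) -> np.ndarray:
    """Mid-rank score per stratum; exp shape (n,), ctl shape (n, k)."""
    e = exp[:, None]
    return ((ctl < e).sum(axis=1) + 0.5 * (ctl == e).sum(axis=1)) / ctl.shape[1]


def roc_association(
    matched: Sequence[MatchedControlSet],
    track: EpigeneticTrack,
    half_window: int = 500,
    n_permutations: int = 1_000,
    seed: int = 0,
    category: str = "all",
) -> AssociationResult:
    """Stratified ROC area of a track over sites with matched controls.

    The empirical two-sided p-value compares |ROC - 0.5| against the same
    statistic after swapping, independently per stratum, the experimental
    count with one of the pooled counts of the stratum (label permutation
    within strata), with the +1 small-sample correction.
    """
    if not matched:
        return AssociationResult(track.name, category, float("nan"), 0, float("nan"), "insufficient_data")
    ks = {len(m.controls) for m in matched}
    if min(ks) < 1:
        missing = next(m for m in matched if len(m.controls) < 1)
        raise ValueError(
            f"site {missing.site.chrom}:{missing.site.position} has no matched controls"
        )
    k = max(ks)
    exp = np.array(
        [
            count_features_in_window(m.site.position, m.site.chrom, track, half_window)
            for m in matched
        ]
    )
    ctl = np.full((len(matched), k), -1, dtype=int)
    for i, m in enumerate(matched):
        for j, (chrom, pos, _strand) in enumerate(m.controls):
            ctl[i, j] = count_features_in_window(pos, chrom, track, half_window)
        # strata with fewer controls repeat their last control count
        for j in range(len(m.controls), k):
            ctl[i, j] = ctl[i, len(m.controls) - 1]
    roc = float(_stratum_scores(exp, ctl).mean())

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([exp[:, None], ctl], axis=1)  # (n, k+1)
    obs = abs(roc - 0.5)
    hits = 0
    n = len(matched)
    for _ in range(n_permutations):
        pick = rng.integers(0, k + 1, size=n)
        perm = pooled.copy()
        rows = np.arange(n)
        e_perm = perm[rows, pick]
        perm[rows, pick] = perm[rows, 0]
        perm_roc = _stratum_scores(e_perm, perm[:, 1:]).mean()
        if abs(perm_roc - 0.5) >= obs - 1e-12:
            hits += 1
    pvalue = (hits + 1) / (n_permutations + 1)
    return AssociationResult(track.name, category, roc, n, pvalue)


def association_matrix(
    matched_by_category: Mapping[str, Sequence[MatchedControlSet]],
    tracks: Sequence[EpigeneticTrack],
    half_window: int = 500,
    n_permutations: int = 1_000,
    seed: int = 0,
) -> tuple[list[AssociationResult], pd.DataFrame]:
    """One ROC result per (track, site category); matrix for heat-map plotting.

    Empty categories yield a result flagged ``insufficient_data`` rather
    than being dropped, so the matrix shape is stable.
    """
    results: list[AssociationResult] = []
    for t_i, track in enumerate(tracks):
        for c_i, (category, matched) in enumerate(matched_by_category.items()):
            res = roc_association(
                list(matched),
                track,
                half_window=half_window,
                n_permutations=n_permutations,
                seed=seed + 1000 * t_i + c_i,
                category=category,
            )
            results.append(res)
    matrix = pd.DataFrame(
        {
            cat: [
                r.roc_area
                for r in results
                if r.category == cat
            ]
            for cat in matched_by_category
        },
        index=[t.name for t in tracks],
    )
    return results, matrix


def plot_association_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Render the ROC matrix as a blue (<0.5) / red (>0.5) heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.2 + 0.8 * matrix.shape[1], 0.6 + 0.3 * matrix.shape[0])
    )
    im = ax.imshow(matrix.values, cmap="bwr", vmin=0.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns)
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    fig.colorbar(im, ax=ax, label="ROC area")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
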