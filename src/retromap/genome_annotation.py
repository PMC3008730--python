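"""Annotation of integration sites against gene models.

Sites are classified with respect to transcription start sites (TSS) and
transcript spans: TSS-proximal when within ±2.5 kb of at least one TSS,
intragenic when inside a transcript beyond that window, intergenic
otherwise.  "Target genes" are all genes with a TSS within ±50 kb of a
site; for multi-isoform genes the isoform with the nearest TSS represents
the gene.  Provirus orientation (forward/reverse relative to the enclosing
transcript) is the readout used to detect selection against
gene-disrupting insertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from retromap.read_processing import IntegrationSite

__all__ = [
    "GeneModel",
    "GeneIndex",
    "AnnotationRecord",
    "TargetGene",
    "classify_site",
    "annotate_target_genes",
    "annotate_orientation",
    "annotate_sites",
    "tss_distance_profile",
    "summarize_distribution",
    "round_pct",
]

TSS_WINDOW = 2_500
TARGET_WINDOW = 50_000


@dataclass(frozen=True)
class GeneModel:
    """One transcript of a gene. Coordinates 0-based half-open."""

    transcript_id: str
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"{self.transcript_id}: tx_start must be < tx_end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start: tx_start on +, last base (tx_end-1) on -."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def signed_tss_distance(self, position: int) -> int:
        """Distance from TSS in the gene's reading direction.

        Negative upstream of the TSS, positive downstream.
        """
        d = position - self.tss
        return d if self.strand == "+" else -d


@dataclass(frozen=True)
class TargetGene:
    """A gene targeted by a site: chosen isoform and signed TSS distance."""

    gene_id: str
    transcript_id: str
    distance: int


@dataclass(frozen=True)
class AnnotationRecord:
    site: IntegrationSite
    category: str  # TSS_proximal | intragenic | intergenic
    target_genes: tuple[TargetGene, ...]
    orientation: str  # forward | reverse | not_applicable


class GeneIndex:
    """Per-chromosome index of transcripts: sorted TSS arrays + span trees."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        self._tss_pos: dict[str, np.ndarray] = {}
        self._tss_idx: dict[str, np.ndarray] = {}
        self._spans: dict[str, IntervalTree] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, g in enumerate(self.genes):
            by_chrom.setdefault(g.chrom, []).append(i)
            self._spans.setdefault(g.chrom, IntervalTree()).addi(
                g.tx_start, g.tx_end, i
            )
        for chrom, idx in by_chrom.items():
            tss = np.array([self.genes[i].tss for i in idx])
            order = np.argsort(tss, kind="stable")
            self._tss_pos[chrom] = tss[order]
            self._tss_idx[chrom] = np.array(idx)[order]

    def tss_in_window(self, chrom: str, position: int, window: int) -> list[GeneModel]:
        """Transcripts with |TSS - position| <= window."""
        pos = self._tss_pos.get(chrom)
        if pos is None:
            return []
        lo = np.searchsorted(pos, position - window, side="left")
        hi = np.searchsorted(pos, position + window, side="right")
        return [self.genes[i] for i in self._tss_idx[chrom][lo:hi]]

    def enclosing(self, chrom: str, position: int) -> list[GeneModel]:
        """Transcripts whose span contains the position."""
        tree = self._spans.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in tree.at(position)]


def _as_index(genes: "GeneIndex | Iterable[GeneModel]") -> GeneIndex:
    return genes if isinstance(genes, GeneIndex) else GeneIndex(genes)


def classify_site(
    site: IntegrationSite,
    genes: "GeneIndex | Iterable[GeneModel]",
    tss_window: int = TSS_WINDOW,
) -> str:
    """TSS_proximal / intragenic / intergenic, with at-least-one-gene semantics.

    Proximity to any TSS wins over being inside some other gene.
    """
    index = _as_index(genes)
    if index.tss_in_window(site.chrom, site.position, tss_window):
        return "TSS_proximal"
    if index.enclosing(site.chrom, site.position):
        return "intragenic"
    return "intergenic"


def annotate_target_genes(
    site: IntegrationSite,
    genes: "GeneIndex | Iterable[GeneModel]",
    target_window: int = TARGET_WINDOW,
) -> tuple[TargetGene, ...]:
    """Genes with a TSS within ±target_window, one entry per gene_id.

    For multi-isoform genes the isoform with the smallest |TSS - position|
    is chosen; ties go to the lower tx_start (then transcript_id) for
    determinism.  Distances are signed in the gene's reading direction.
    """
    index = _as_index(genes)
    hits = index.tss_in_window(site.chrom, site.position, target_window)
    best: dict[str, GeneModel] = {}
    for g in hits:
        cur = best.get(g.gene_id)
        if cur is None or _isoform_key(g, site.position) < _isoform_key(cur, site.position):
            best[g.gene_id] = g
    return tuple(
        TargetGene(g.gene_id, g.transcript_id, g.signed_tss_distance(site.position))
        for g in sorted(best.values(), key=lambda g: (g.chrom, g.tx_start, g.transcript_id))
    )


def _isoform_key(g: GeneModel, position: int) -> tuple[int, int, str]:
    return (abs(g.tss - position), g.tx_start, g.transcript_id)


def annotate_orientation(
    site: IntegrationSite, enclosing: Sequence[GeneModel]
) -> str:
    """forward/reverse vs the enclosing transcript, not_applicable outside genes.

    With several enclosing transcripts the nearest-TSS one (same tie rule
    as target-gene choice) defines the direction of transcription.
    """
    if not enclosing:
        return "not_applicable"
    rep = min(enclosing, key=lambda g: _isoform_key(g, site.position))
    return "forward" if site.strand == rep.strand else "reverse"


def annotate_sites(
    sites: Iterable[IntegrationSite],
    genes: "GeneIndex | Iterable[GeneModel]",
    tss_window: int = TSS_WINDOW,
    target_window: int = TARGET_WINDOW,
) -> list[AnnotationRecord]:
    """Full annotation: category, target genes and orientation per site."""
    index = _as_index(genes)
    out = []
    for site in sites:
        out.append(
            AnnotationRecord(
                site=site,
                category=classify_site(site, index, tss_window),
                target_genes=annotate_target_genes(site, index, target_window),
                orientation=annotate_orientation(
                    site, index.enclosing(site.chrom, site.position)
                ),
            )
        )
    return out


def tss_distance_profile(
    sites: Iterable[IntegrationSite],
    genes: "GeneIndex | Iterable[GeneModel]",
    bin_bp: int = 200,
    span_bp: int = 50_000,
    near_tss_bp: int = 1_700,
) -> tuple[pd.DataFrame, float]:
    """Histogram of per-target-gene nearest-site TSS distances.

    For every target gene (TSS within ±span_bp of some site) the signed
    distance of its nearest site is binned at ``bin_bp`` resolution;
    percentages are relative to the number of distinct target genes.
    Also returns the fraction (%) of target genes with a site within
    ±near_tss_bp of the TSS.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if span_bp % bin_bp != 0:
        raise ValueError("span_bp must be a multiple of bin_bp")
    index = _as_index(genes)
    nearest: dict[str, int] = {}
    for site in sites:
        for tg in annotate_target_genes(site, index, span_bp):
            cur = nearest.get(tg.gene_id)
            if cur is None or abs(tg.distance) < abs(cur):
                nearest[tg.gene_id] = tg.distance
    n_genes = len(nearest)
    edges = np.arange(-span_bp, span_bp + bin_bp, bin_bp)
    counts, _ = np.histogram(list(nearest.values()), bins=edges)
    pct = 100.0 * counts / n_genes if n_genes else counts.astype(float)
    profile = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts, "pct": pct}
    )
    near = (
        100.0
        * sum(1 for d in nearest.values() if -near_tss_bp <= d <= near_tss_bp)
        / n_genes
        if n_genes
        else float("nan")
    )
    return profile, near


def round_pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage rounded half-up to ``ndigits`` decimals (as printed in tables)."""
    if denominator == 0:
        return float("nan")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    q = Decimal(1).scaleb(-ndigits)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def summarize_distribution(
    annotations: Iterable[AnnotationRecord],
    group_by: tuple[str, ...] = ("sample_id", "timepoint"),
) -> pd.DataFrame:
    """Table-style per-group summary of categories and orientation.

    One row per (sample, timepoint) group with counts and rounded
    percentages of intergenic / TSS-proximal / intragenic sites, and the
    forward/reverse split among sites lying inside a transcript (the
    orientation denominator includes TSS-proximal sites inside a gene,
    which is why forward+reverse can exceed the intragenic count).
    """
    rows: dict[tuple, Counter_] = {}
    annotations = list(annotations)
    for rec in annotations:
        key = tuple(getattr(rec.site, f) for f in group_by)
        c = rows.setdefault(key, Counter_())
        c.total += 1
        setattr(c, rec.category, getattr(c, rec.category) + 1)
        if rec.orientation in ("forward", "reverse"):
            setattr(c, rec.orientation, getattr(c, rec.orientation) + 1)
    out = []
    for key, c in sorted(rows.items()):
        n_orient = c.forward + c.reverse
        out.append(
            {
                **dict(zip(group_by, key)),
                "n_sites": c.total,
                "intergenic": c.intergenic,
                "intergenic_pct": round_pct(c.intergenic, c.total),
                "TSS_proximal": c.TSS_proximal,
                "TSS_proximal_pct": round_pct(c.TSS_proximal, c.total),
                "intragenic": c.intragenic,
                "intragenic_pct": round_pct(c.intragenic, c.total),
                "forward": c.forward,
                "forward_pct": round_pct(c.forward, n_orient),
                "reverse": c.reverse,
                "reverse_pct": round_pct(c.reverse, n_orient),
            }
        )
    return pd.DataFrame(out)


class Counter_:
    """Per-group tallies for summarize_distribution."""

    def __init__(self) -> None:
        self.total = 0
        self.intergenic = 0
        self.TSS_proximal = 0
        self.intragenic = 0
        self.forward = 0
        self.reverse = 0
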