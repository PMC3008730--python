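"""Synthetic genomes, gene models, tracks, expression tables and LAM-PCR reads.

Every pipeline stage is testable without external downloads: the generator
emits a random genome, non-overlapping gene models with expression values,
integration sites with controllable TSS bias / orientation bias /
clustering, TSS- or site-anchored epigenetic feature tracks, and LAM-PCR
style reads (barcode + LTR tail ending in CA + genomic flank up to the
nearest restriction site on the provirus strand) with companion ideal PSL
alignment records.  A truth table accompanies each simulated object so
recovery can be scored exactly.

The defaults mirror the structure of a gamma-retroviral insertion-site
study in primary T cells at desk scale: roughly a third of sites placed
around TSSs, near-random orientation inside genes, and a 4-cutter
digestion (Tsp509I / HpyCH4IV / HinP1I) defining recoverable fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from retromap.expression_association import ExpressionTable
from retromap.genome_annotation import GeneIndex, GeneModel, classify_site
from retromap.random_controls import (
    ENZYMES,
    RestrictionMap,
    build_restriction_map,
)
from retromap.read_processing import AlignmentRecord, IntegrationSite, RawRead

__all__ = [
    "SyntheticConfig",
    "simulate_genome",
    "simulate_genes",
    "simulate_sites",
    "simulate_track",
    "simulate_lampcr_reads",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_LTR_TAIL = "TTCA"  # vector LTR end, terminal CA = integration dinucleotide


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study.  ``seed`` is mandatory.

    The placement parameters are fractions in [0, 1]; ``tss_sd`` is the
    spread (bp) of TSS-anchored placement, ``cluster_boost`` the fraction
    of sites re-placed near an existing site within ``cluster_scale_bp``.
    """

    seed: int
    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    n_genes: int = 120
    gene_length_log_mean: float = np.log(6_000.0)
    gene_length_log_sd: float = 0.6
    isoform_prob: float = 0.25
    isoform_tss_offset_sd: float = 3_000.0
    expression_detection_rate: float = 0.8
    n_sites: int = 1_000
    tss_bias_fraction: float = 0.3
    tss_sd: float = 1_000.0
    orientation_reverse_prob: float = 0.5
    cluster_boost: float = 0.0
    cluster_scale_bp: int = 1_000
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tss_bias_fraction", "orientation_reverse_prob", "cluster_boost", "error_rate", "isoform_prob", "expression_detection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")


def simulate_genome(
    config: SyntheticConfig, enzymes: Mapping[str, str] = ENZYMES
) -> tuple[dict[str, str], RestrictionMap]:
    """I.i.d. uniform-nucleotide chromosomes plus their restriction map.

    Each 4-bp recognition motif then occurs at rate ~1/256 per position.
    """
    rng = np.random.default_rng(config.seed)
    per_len = config.genome_length // config.n_chromosomes
    genome: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        bases = rng.integers(0, 4, size=per_len)
        genome[f"chr{i + 1}"] = "".join("ACGT"[b] for b in bases)
    return genome, build_restriction_map(genome, enzymes)


def simulate_genes(
    genome: Mapping[str, str], config: SyntheticConfig
) -> tuple[list[GeneModel], ExpressionTable]:
    """Non-overlapping transcripts with random strands and expression values.

    Gene lengths are log-normal; a fraction of genes get a second isoform
    with an offset TSS (sharing the gene span end).  Expression values are
    log-normal with a Bernoulli detection call.
    """
    rng = np.random.default_rng(config.seed + 1)
    chroms = sorted(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    values: dict[str, float] = {}
    detected: dict[str, bool] = {}
    attempts = 0
    g = 0
    while g < config.n_genes:
        attempts += 1
        if attempts > 200 * config.n_genes:
            raise RuntimeError(
                f"could not place {config.n_genes} non-overlapping genes "
                f"in a {sum(lengths.values())} bp genome"
            )
        length = int(rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd))
        length = max(2_000, length)
        chrom = chroms[rng.integers(0, len(chroms))]
        if length >= lengths[chrom]:
            continue
        start = int(rng.integers(0, lengths[chrom] - length))
        end = start + length
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{g:04d}"
        genes.append(
            GeneModel(f"{gene_id}.1", gene_id, gene_id, chrom, strand, start, end)
        )
        if rng.random() < config.isoform_prob:
            # second isoform: TSS shifted into the gene body, same 3' end
            shift = int(abs(rng.normal(0.0, config.isoform_tss_offset_sd))) + 100
            shift = min(shift, length - 500)
            if strand == "+":
                genes.append(
                    GeneModel(f"{gene_id}.2", gene_id, gene_id, chrom, strand, start + shift, end)
                )
            else:
                genes.append(
                    GeneModel(f"{gene_id}.2", gene_id, gene_id, chrom, strand, start, end - shift)
                )
        values[gene_id] = float(rng.lognormal(5.0, 1.0))
        detected[gene_id] = bool(rng.random() < config.expression_detection_rate)
        g += 1
    return genes, ExpressionTable(values=values, detected=detected)


def simulate_sites(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    config: SyntheticConfig,
    sample_id: str = "S1",
    timepoint: str = "pre",
) -> tuple[list[IntegrationSite], pd.DataFrame]:
    """Integration sites with planted TSS bias, orientation bias and clustering.

    A ``tss_bias_fraction`` of sites is drawn Normal(TSS, tss_sd) around a
    random gene, the rest uniformly (chromosome weighted by length).  The
    strand of a site falling inside a transcript is the reverse of the
    gene strand with probability ``orientation_reverse_prob``; outside
    genes it is uniform.  A ``cluster_boost`` fraction is then re-placed
    within ±cluster_scale_bp of a randomly chosen earlier site.  Positions
    are unique per (chrom, position, strand); the truth table records
    placement mode, category and enclosing gene.
    """
    rng = np.random.default_rng(config.seed + 2)
    index = GeneIndex(genes)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    seen: set[tuple[str, int, str]] = set()
    rows: list[dict] = []

    def draw_strand(chrom: str, pos: int) -> str:
        enclosing = index.enclosing(chrom, pos)
        if enclosing:
            gene_strand = enclosing[0].strand
            flip = rng.random() < config.orientation_reverse_prob
            return ("-" if gene_strand == "+" else "+") if flip else gene_strand
        return "+" if rng.random() < 0.5 else "-"

    while len(rows) < config.n_sites:
        if rows and config.cluster_boost > 0 and rng.random() < config.cluster_boost:
            anchor = rows[rng.integers(0, len(rows))]
            chrom = anchor["chrom"]
            offset = int(rng.integers(-config.cluster_scale_bp, config.cluster_scale_bp + 1))
            pos = anchor["position"] + offset
            mode = "cluster"
        elif genes and rng.random() < config.tss_bias_fraction:
            gene = genes[rng.integers(0, len(genes))]
            chrom = gene.chrom
            pos = int(round(rng.normal(gene.tss, config.tss_sd)))
            mode = "tss"
        else:
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            pos = int(rng.integers(0, int(lengths[ci])))
            mode = "uniform"
        if not 0 <= pos < len(genome[chrom]):
            continue
        strand = draw_strand(chrom, pos)
        key = (chrom, pos, strand)
        if key in seen:
            continue
        seen.add(key)
        enclosing = index.enclosing(chrom, pos)
        rows.append(
            {
                "chrom": chrom,
                "position": pos,
                "strand": strand,
                "mode": mode,
                "enclosing_gene": enclosing[0].gene_id if enclosing else "",
                "gene_strand": enclosing[0].strand if enclosing else "",
            }
        )
    sites = [
        IntegrationSite(r["chrom"], r["position"], r["strand"], sample_id, timepoint)
        for r in rows
    ]
    truth = pd.DataFrame(rows)
    truth["category"] = [classify_site(s, index) for s in sites]
    truth["sample_id"] = sample_id
    truth["timepoint"] = timepoint
    return sites, truth


def simulate_track(
    genome: Mapping[str, str],
    anchors: Sequence[tuple[str, int]],
    name: str,
    n_features: int,
    enrichment_factor: float = 1.0,
    anchor_sd: float = 200.0,
    seed: int = 0,
) -> "object":
    """A feature track with a planted enrichment around anchor positions.

    A feature is anchor-associated with probability 1 - 1/enrichment_factor
    (0 for factor 1, i.e. fully uniform) and then placed Normal(anchor,
    anchor_sd); otherwise uniformly on the genome.  Returns an
    EpigeneticTrack of point features.
    """
    from retromap.epigenetic_association import EpigeneticTrack

    if enrichment_factor < 1.0:
        raise ValueError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    p_anchor = 1.0 - 1.0 / enrichment_factor
    mids: dict[str, list[int]] = {c: [] for c in chroms}
    for _ in range(n_features):
        if anchors and rng.random() < p_anchor:
            chrom, pos = anchors[rng.integers(0, len(anchors))]
            m = int(round(rng.normal(pos, anchor_sd)))
        else:
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            m = int(rng.integers(0, int(lengths[ci])))
        if 0 <= m < len(genome[chrom]):
            mids[chrom].append(m)
    return EpigeneticTrack(name, mids)


def _fragment(
    genome: Mapping[str, str], rmap: RestrictionMap, chrom: str, pos: int, strand: str
) -> tuple[str, int]:
    """LAM-PCR genomic flank: junction to nearest recognition-site start
    in the read direction (downstream on the provirus strand)."""
    merged = rmap.merged(chrom)
    seq = genome[chrom]
    if strand == "+":
        i = np.searchsorted(merged, pos, side="left")
        end = int(merged[i]) if i < len(merged) else len(seq)
        frag = seq[pos:end]
    else:
        i = np.searchsorted(merged, pos, side="right")
        start = int(merged[i - 1]) if i > 0 else -1
        frag = _revcomp(seq[start + 1 : pos + 1])
    return frag, len(frag)


def simulate_lampcr_reads(
    sites: Sequence[IntegrationSite],
    genome: Mapping[str, str],
    rmap: RestrictionMap,
    ltr_tail: str = DEFAULT_LTR_TAIL,
    barcodes: Mapping[str, str] | None = None,
    config: SyntheticConfig | None = None,
    error_rate: float | None = None,
    seed: int | None = None,
) -> tuple[list[RawRead], list[AlignmentRecord], pd.DataFrame]:
    """LAM-PCR reads plus ideal PSL-style alignment records per site.

    Each site yields one read ``barcode + ltr_tail + fragment`` where the
    fragment runs from the junction to the nearest recognition site in the
    read direction.  Substitution errors are planted in the fragment at
    ``error_rate`` and mirrored in the alignment record's mismatch count,
    so the alignment-filtering logic can be exercised without running an
    aligner.  Alignments are only emitted for non-empty fragments.
    """
    if not ltr_tail.endswith("CA"):
        raise ValueError("ltr_tail must end with CA")
    rate = error_rate if error_rate is not None else (config.error_rate if config else 0.0)
    s = seed if seed is not None else (config.seed + 3 if config else 0)
    rng = np.random.default_rng(s)
    barcodes = barcodes or {}
    reads: list[RawRead] = []
    alignments: list[AlignmentRecord] = []
    rows: list[dict] = []
    for i, site in enumerate(sorted(sites)):
        frag, flen = _fragment(genome, rmap, site.chrom, site.position, site.strand)
        n_err = 0
        if rate > 0 and flen > 0:
            frag_list = list(frag)
            for j in range(flen):
                if rng.random() < rate:
                    frag_list[j] = rng.choice(
                        [b for b in "ACGT" if b != frag_list[j]]
                    )
                    n_err += 1
            frag = "".join(frag_list)
        read_id = f"read{i:06d}"
        bc = barcodes.get(site.sample_id, "")
        seq = bc + ltr_tail + frag
        if seq:
            reads.append(RawRead(read_id, seq))
        if flen >= 1:
            if site.strand == "+":
                t_start, t_end = site.position, site.position + flen
            else:
                t_start, t_end = site.position - flen + 1, site.position + 1
            alignments.append(
                AlignmentRecord(
                    query_id=read_id,
                    query_size=flen,
                    matches=flen - n_err,
                    mismatches=n_err,
                    query_gap_bases=0,
                    tile_gap_bases=0,
                    query_start=0,
                    chrom=site.chrom,
                    target_start=t_start,
                    target_end=t_end,
                    strand=site.strand,
                )
            )
        rows.append(
            {
                "read_id": read_id,
                "sample_id": site.sample_id,
                "timepoint": site.timepoint,
                "chrom": site.chrom,
                "position": site.position,
                "strand": site.strand,
                "fragment_len": flen,
                "n_errors": n_err,
            }
        )
    return reads, alignments, pd.DataFrame(rows)
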