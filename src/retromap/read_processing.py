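"""LAM-PCR read validation, demultiplexing and alignment filtering.

LAM-PCR amplicons read off the vector 5' LTR into flanking host DNA, so a
valid read is ``barcode + LTR tail (ending in the invariant CA integration
dinucleotide) + genomic flank``.  The functions here take raw reads to
unique integration sites in four steps: demultiplex by exact barcode
prefix, validate/trim the LTR tail, collapse redundant fragments, and
filter BLAT alignments to a single confident hit per query.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RawRead",
    "TrimmedFragment",
    "AlignmentRecord",
    "IntegrationSite",
    "Rejection",
    "demultiplex_reads",
    "validate_and_trim",
    "collapse_redundant",
    "compute_blat_identity",
    "filter_alignments",
    "alignments_to_sites",
]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class RawRead:
    """A raw sequencing read (id + nucleotide sequence)."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class TrimmedFragment:
    """Genomic portion of a validated read, barcode and LTR tail removed."""

    read_id: str
    sample_id: str
    genomic_seq: str
    support: int = 1


@dataclass(frozen=True)
class Rejection:
    """A read or query discarded by a filter, tagged with the reason."""

    read_id: str
    reason: str  # no_ltr | too_short | unaligned | multi_mapped | low_quality


@dataclass(frozen=True)
class AlignmentRecord:
    """One BLAT hit of a query fragment on the genome (PSL semantics).

    Coordinates are 0-based half-open.  ``query_start`` is the offset of the
    first aligned query base; ``tile_gap_bases`` is the number of target
    (tile) gap bases.  ``target_end`` is needed to place the junction base
    for minus-strand alignments.
    """

    query_id: str
    query_size: int
    matches: int
    mismatches: int
    query_gap_bases: int
    tile_gap_bases: int
    query_start: int
    chrom: str
    target_start: int
    target_end: int
    strand: str

    @property
    def identity(self) -> float:
        return compute_blat_identity(self)


@dataclass(frozen=True, order=True)
class IntegrationSite:
    """A unique vector-genome junction.

    ``position`` is the 0-based coordinate of the first genomic base after
    the LTR junction; (chrom, position, strand) identifies the site within
    a sample/timepoint, ``support`` counts the reads that produced it.
    """

    chrom: str
    position: int
    strand: str
    sample_id: str = ""
    timepoint: str = ""
    support: int = 1

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative site position {self.position}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


def demultiplex_reads(
    reads: Iterable[RawRead], barcodes: Mapping[str, str]
) -> tuple[dict[str, list[RawRead]], list[RawRead]]:
    """Assign reads to samples by exact barcode prefix match.

    Barcodes must be mutually non-prefixing so assignment is unambiguous.
    Returns ``(per-sample reads with the barcode stripped, unassigned)``.
    """
    codes = list(barcodes.items())
    for i, (sa, ba) in enumerate(codes):
        for sb, bb in codes[i + 1 :]:
            if ba.startswith(bb) or bb.startswith(ba):
                raise ValueError(
                    f"barcode conflict: {sa}={ba!r} and {sb}={bb!r} "
                    "(one is a prefix of the other)"
                )
    assigned: dict[str, list[RawRead]] = {s: [] for s in barcodes}
    unassigned: list[RawRead] = []
    for read in reads:
        for sample_id, bc in codes:
            if read.sequence.startswith(bc):
                assigned[sample_id].append(
                    RawRead(read.read_id, read.sequence[len(bc) :])
                )
                break
        else:
            unassigned.append(read)
    return assigned, unassigned


def validate_and_trim(
    read: RawRead,
    ltr_tail: str,
    min_genomic_len: int = 20,
    sample_id: str = "",
) -> TrimmedFragment | Rejection:
    """Validate the LTR tail and return the genomic flank.

    A valid read starts with ``ltr_tail`` — the vector LTR end up to and
    including the terminal CA integration dinucleotide — followed by at
    least ``min_genomic_len`` genomic bases.  Matching is exact; reads that
    lack the tail are tagged ``no_ltr``, short flanks ``too_short``.
    """
    if not ltr_tail.endswith("CA"):
        raise ValueError("ltr_tail must end with the CA integration dinucleotide")
    if not read.sequence.startswith(ltr_tail):
        return Rejection(read.read_id, "no_ltr")
    genomic = read.sequence[len(ltr_tail) :]
    if len(genomic) < min_genomic_len:
        return Rejection(read.read_id, "too_short")
    return TrimmedFragment(read.read_id, sample_id, genomic)


def collapse_redundant(
    fragments: Iterable[TrimmedFragment],
) -> list[TrimmedFragment]:
    """Collapse exact duplicate genomic sequences, summing support.

    The representative keeps the lexicographically smallest read_id among
    the duplicates; output is sorted by sequence so the result is
    deterministic regardless of input order.
    """
    by_seq: dict[str, list[TrimmedFragment]] = {}
    for frag in fragments:
        by_seq.setdefault(frag.genomic_seq, []).append(frag)
    out = []
    for seq in sorted(by_seq):
        group = sorted(by_seq[seq], key=lambda f: f.read_id)
        out.append(
            TrimmedFragment(
                read_id=group[0].read_id,
                sample_id=group[0].sample_id,
                genomic_seq=seq,
                support=sum(f.support for f in group),
            )
        )
    return out


def compute_blat_identity(a: AlignmentRecord) -> float:
    """Fraction of the query confidently aligned.

    identity = [matches - (mismatches + query gap bases + tile gap bases)]
    / query size, floored at 0.  Gaps are penalised on top of not matching,
    so the score drops below the naive matches/size for gapped alignments.
    """
    if a.query_size <= 0:
        raise ValueError(f"query {a.query_id!r}: non-positive query_size")
    raw = (
        a.matches - (a.mismatches + a.query_gap_bases + a.tile_gap_bases)
    ) / a.query_size
    return max(0.0, raw)


def filter_alignments(
    hits: Sequence[AlignmentRecord],
    min_identity: float = 0.90,
    max_query_start: int = 3,
    ambiguity_margin: float = 0.02,
) -> AlignmentRecord | Rejection:
    """Select the single confident genomic hit for one query.

    Hits must start within the first ``max_query_start`` query bases
    (0-based offsets 0..max_query_start-1) and reach ``min_identity``.
    If the two best surviving hits differ in identity by less than
    ``ambiguity_margin`` the query maps ambiguously and is rejected as
    ``multi_mapped``; at a difference >= the margin the best hit wins.
    """
    if not hits:
        return Rejection("", "unaligned")
    qid = hits[0].query_id
    if any(h.query_id != qid for h in hits):
        raise ValueError("filter_alignments expects hits for a single query")
    surviving = [
        h
        for h in hits
        if h.query_start < max_query_start and h.identity >= min_identity
    ]
    if not surviving:
        return Rejection(qid, "unaligned")
    surviving.sort(key=lambda h: (-h.identity, h.chrom, h.target_start))
    if len(surviving) >= 2:
        # small epsilon so a difference exactly at the margin keeps the best
        # hit regardless of binary rounding of the identity fractions
        if surviving[0].identity - surviving[1].identity < ambiguity_margin - 1e-9:
            return Rejection(qid, "multi_mapped")
    return surviving[0]


def alignments_to_sites(
    accepted: Iterable[AlignmentRecord],
    sample_id: str,
    timepoint: str,
    support: Mapping[str, int] | None = None,
) -> list[IntegrationSite]:
    """Convert accepted alignments to unique integration sites.

    The junction base is the first aligned genomic base on the provirus
    strand: target_start for plus-strand hits, target_end - 1 for
    minus-strand hits.  Sites sharing (chrom, position, strand) merge with
    summed support; ``support`` optionally carries per-query read counts
    from redundancy collapsing (default 1 per query).
    """
    counts: Counter[tuple[str, int, str]] = Counter()
    for a in accepted:
        pos = a.target_start if a.strand == "+" else a.target_end - 1
        n = 1 if support is None else support.get(a.query_id, 1)
        counts[(a.chrom, pos, a.strand)] += n
    return sorted(
        IntegrationSite(chrom, pos, strand, sample_id, timepoint, n)
        for (chrom, pos, strand), n in counts.items()
    )
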