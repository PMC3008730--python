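"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython; gene models are refFlat-like TSV; sites
and clusters are TSV/BED6; alignments are BLAT PSL (tab format, written
and parsed here because no installed library handles PSL).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from retromap.cluster_analysis import Cluster
from retromap.epigenetic_association import EpigeneticTrack
from retromap.genome_annotation import GeneModel
from retromap.random_controls import RandomSitePool
from retromap.read_processing import AlignmentRecord, IntegrationSite, RawRead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_reads",
    "write_reads",
    "read_barcodes",
    "read_psl",
    "write_psl",
    "read_refflat",
    "write_refflat",
    "read_sites_tsv",
    "write_sites_tsv",
    "write_sites_bed",
    "read_track_bed",
    "write_pool",
    "write_clusters_bed",
    "read_expression_tsv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path: str | Path, fmt: str | None = None) -> list[RawRead]:
    """Reads from FASTA or FASTQ (format inferred from the extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [RawRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_reads(reads: Iterable[RawRead], path: str | Path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads]
    SeqIO.write(records, str(path), "fasta")


def read_barcodes(path: str | Path) -> dict[str, str]:
    """Barcode TSV: sample_id <tab> barcode."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "barcode"} <= set(df.columns):
        raise ValueError("barcode table needs columns sample_id, barcode")
    return dict(zip(df["sample_id"], df["barcode"]))


# PSL columns (BLAT tab output, no header):
# matches misMatches repMatches nCount qNumInsert qBaseInsert tNumInsert
# tBaseInsert strand qName qSize qStart qEnd tName tSize tStart tEnd
# blockCount blockSizes qStarts tStarts
def read_psl(path: str | Path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue  # optional header block
            f = line.split("\t")
            records.append(
                AlignmentRecord(
                    query_id=f[9],
                    query_size=int(f[10]),
                    matches=int(f[0]),
                    mismatches=int(f[1]),
                    query_gap_bases=int(f[5]),
                    tile_gap_bases=int(f[7]),
                    query_start=int(f[11]),
                    chrom=f[13],
                    target_start=int(f[15]),
                    target_end=int(f[16]),
                    strand=f[8],
                )
            )
    return records


def write_psl(alignments: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            span = a.target_end - a.target_start
            fields = [
                a.matches, a.mismatches, 0, 0, 0, a.query_gap_bases, 0,
                a.tile_gap_bases, a.strand, a.query_id, a.query_size,
                a.query_start, a.query_start + a.matches + a.mismatches,
                a.chrom, 0, a.target_start, a.target_end,
                1, f"{span},", f"{a.query_start},", f"{a.target_start},",
            ]
            fh.write("\t".join(str(x) for x in fields) + "\n")


def read_refflat(path: str | Path) -> list[GeneModel]:
    """refFlat-like TSV: gene_id transcript_id symbol chrom strand txStart txEnd."""
    df = pd.read_csv(path, sep="\t", dtype={"txStart": int, "txEnd": int})
    return [
        GeneModel(
            transcript_id=r.transcript_id,
            gene_id=r.gene_id,
            symbol=getattr(r, "symbol", r.gene_id),
            chrom=r.chrom,
            strand=r.strand,
            tx_start=int(r.txStart),
            tx_end=int(r.txEnd),
        )
        for r in df.itertuples()
    ]


def write_refflat(genes: Iterable[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "transcript_id": g.transcript_id,
                "symbol": g.symbol,
                "chrom": g.chrom,
                "strand": g.strand,
                "txStart": g.tx_start,
                "txEnd": g.tx_end,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def sites_frame(sites: Iterable[IntegrationSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "position": s.position,
                "strand": s.strand,
                "sample_id": s.sample_id,
                "timepoint": s.timepoint,
                "support": s.support,
            }
            for s in sites
        ]
    )


def write_sites_tsv(sites: Iterable[IntegrationSite], path: str | Path) -> None:
    sites_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[IntegrationSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str, "timepoint": str})
    return [
        IntegrationSite(
            r.chrom, int(r.position), r.strand, str(r.sample_id), str(r.timepoint), int(r.support)
        )
        for r in df.itertuples()
    ]


def write_sites_bed(sites: Iterable[IntegrationSite], path: str | Path) -> None:
    """BED6: single-base intervals, name=sample, score=support."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t"
                f"{s.sample_id or 'site'}\t{s.support}\t{s.strand}\n"
            )


def read_track_bed(path: str | Path, name: str | None = None) -> EpigeneticTrack:
    """BED3+ feature track; the name defaults to the file stem."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            intervals.append((f[0], int(f[1]), int(f[2])))
    return EpigeneticTrack.from_intervals(name or Path(path).stem, intervals)


def write_track_bed(track: EpigeneticTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.midpoints):
            for m in track.midpoints[chrom]:
                fh.write(f"{chrom}\t{m}\t{m + 1}\t{track.name}\n")


def write_pool(pool: RandomSitePool, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": pool.chroms,
            "position": pool.positions,
            "strand": pool.strands,
            "d_re": pool.d_re,
        }
    ).to_csv(path, sep="\t", index=False)


def read_pool(path: str | Path, seed: int = 0) -> RandomSitePool:
    import numpy as np

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return RandomSitePool(
        chroms=df["chrom"].to_numpy(dtype=object),
        positions=df["position"].to_numpy(dtype=int),
        strands=df["strand"].to_numpy(dtype=object),
        d_re=df["d_re"].to_numpy(dtype=int),
        seed=seed,
    )


def write_clusters_bed(clusters: Sequence[Cluster], path: str | Path) -> None:
    """BED: chrom start end name=cluster id score=size."""
    with open(path, "w") as fh:
        for i, cl in enumerate(clusters):
            fh.write(
                f"{cl.chrom}\t{cl.start}\t{cl.end + 1}\tcluster{i:04d}\t{cl.size}\t.\n"
            )


def read_expression_tsv(path: str | Path):
    from retromap.expression_association import ExpressionTable

    df = pd.read_csv(path, sep="\t")
    return ExpressionTable.from_frame(df)


def write_expression_tsv(table, path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": list(table.values),
            "value": [table.values[g] for g in table.values],
            "detected": [table.detected[g] for g in table.values],
        }
    ).to_csv(path, sep="\t", index=False)
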