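"""Readers and writers for the standard formats at the pipeline boundary.

FASTA is read through :mod:`pyfaidx`, GFF3 through :mod:`gffutils`,
SAM through :mod:`pysam` and FASTQ through Biopython; writing uses the
plain-text conventions of each format (GFF3 1-based closed, SAM 1-based
via pysam, internal coordinates 0-based half-open).
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from pyfaidx import Fasta

from .model import GeneModel, RawRead, SplicedAlignment

_SOURCE = "splicewatch"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    fa = Fasta(str(path), rebuild=True)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(annotation: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Emit one gene/mRNA/exon hierarchy per gene model (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotation:
            attrs = f"ID={gene.gene_id}"
            if gene.cds_frame_anchor is not None:
                attrs += f";translation_start={gene.cds_frame_anchor + 1}"
            fh.write(
                f"{gene.chrom}\t{_SOURCE}\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            tid = f"{gene.gene_id}.t1"
            fh.write(
                f"{gene.chrom}\t{_SOURCE}\tmRNA\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={tid};Parent={gene.gene_id}\n"
            )
            for i, (s, e) in enumerate(gene.exons):
                fh.write(
                    f"{gene.chrom}\t{_SOURCE}\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = sorted(
            (child.start - 1, child.end)
            for child in db.children(gene, featuretype="exon")
        )
        anchor = gene.attributes.get("translation_start")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cds_frame_anchor=int(anchor[0]) - 1 if anchor else None,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _cigar(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    ops: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(blocks):
        if i:
            ops.append((3, s - blocks[i - 1][1]))  # N = skipped intron
        ops.append((0, e - s))  # M
    return ops


def write_sam(
    alignments: Iterable[SplicedAlignment],
    chrom_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.flag = 16 if aln.strand == "-" else 0
            seg.reference_name = aln.chrom
            seg.reference_start = aln.start
            seg.mapping_quality = 60
            seg.cigartuples = _cigar(aln.blocks)
            if aln.sequence is not None:
                seg.query_sequence = aln.sequence
                seg.query_qualities = pysam.qualitystring_to_array("I" * len(aln.sequence))
            if aln.gene_id is not None:
                seg.set_tag("ZG", aln.gene_id, "Z")
            out.write(seg)


def read_sam(path: str | os.PathLike) -> list[SplicedAlignment]:
    alignments: list[SplicedAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            blocks = tuple(rec.get_blocks())
            alignments.append(
                SplicedAlignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    blocks=blocks,
                    strand="-" if rec.is_reverse else "+",
                    gene_id=rec.get_tag("ZG") if rec.has_tag("ZG") else None,
                    sequence=rec.query_sequence,
                )
            )
    return alignments


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[RawRead], path: str | os.PathLike) -> None:
    # Constant qualities: base-quality modelling is out of scope.
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def read_fastq(path: str | os.PathLike) -> list[RawRead]:
    return [
        RawRead(read_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
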