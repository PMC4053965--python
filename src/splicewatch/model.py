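"""Core genomic primitives shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; the
1-based conventions of GFF3 and SAM are applied only at the file
boundary (see :mod:`splicewatch.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Smallest intron the package accepts.  Keeping introns at or above this
#: size makes the 50%-coverage intron-retention rule meaningful even on
#: toy chromosomes.
MIN_INTRON_LEN = 20


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SizingError(ValueError):
    """Requested geometry does not fit (chromosome, pool, or library too small)."""


class PlacementError(ValueError):
    """A planted event's coordinates fall outside legal gene geometry."""


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene: ordered exons on one strand of one chromosome.

    ``exons`` are half-open intervals in genome order (ascending start),
    regardless of strand.  The gaps between consecutive exons are the
    annotated introns.  ``cds_frame_anchor`` is the genome coordinate of
    the first translated base (used by frame-impact analysis); ``None``
    marks a non-coding model.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds_frame_anchor: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon interval ({s}, {e})")
            if prev_end is not None:
                if s < prev_end:
                    raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
                if s - prev_end < MIN_INTRON_LEN:
                    raise ValueError(
                        f"{self.gene_id}: intron shorter than {MIN_INTRON_LEN} nt"
                    )
            prev_end = e

    # -- geometry ---------------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Introns in genome order (gaps between consecutive exons)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genome_intron_index(self, transcribed_index: int) -> int:
        """Map a transcribed-order intron index to genome order."""
        n = len(self.exons) - 1
        if not 0 <= transcribed_index < n:
            raise IndexError(transcribed_index)
        return transcribed_index if self.strand == "+" else n - 1 - transcribed_index

    def genome_exon_index(self, transcribed_index: int) -> int:
        n = len(self.exons)
        if not 0 <= transcribed_index < n:
            raise IndexError(transcribed_index)
        return transcribed_index if self.strand == "+" else n - 1 - transcribed_index

    def transcript_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced transcript in transcribed (5'->3') orientation."""
        return transcript_sequence(genome, self.chrom, self.exons, self.strand)


def transcript_sequence(
    genome: Mapping[str, str],
    chrom: str,
    exons: Sequence[Interval],
    strand: str,
) -> str:
    seq = "".join(genome[chrom][s:e] for s, e in exons)
    return seq if strand == "+" else revcomp(seq)


def window_to_blocks(
    exons: Sequence[Interval], strand: str, t0: int, t1: int
) -> tuple[Interval, ...]:
    """Map a transcript window [t0, t1) onto genome-coordinate blocks.

    ``t0``/``t1`` are positions along the transcribed (5'->3') sequence.
    Returned blocks are half-open genome intervals in ascending order; a
    window crossing a spliced-out intron yields one block per exon
    touched.
    """
    total = sum(e - s for s, e in exons)
    if not 0 <= t0 < t1 <= total:
        raise ValueError(f"window [{t0}, {t1}) outside transcript of length {total}")
    if strand == "-":
        t0, t1 = total - t1, total - t0
    blocks: list[Interval] = []
    off = 0
    for s, e in exons:
        length = e - s
        lo = max(t0 - off, 0)
        hi = min(t1 - off, length)
        if lo < hi:
            blocks.append((s + lo, s + hi))
        off += length
    return tuple(blocks)


@dataclass
class SplicedAlignment:
    """One read's gapped placement on a chromosome.

    ``blocks`` are the aligned segments in ascending genome order; the
    gaps between consecutive blocks are candidate introns (SAM ``N``
    operations).  ``sequence``, when present, is the read sequence in
    genome-forward orientation.
    """

    read_id: str
    chrom: str
    blocks: tuple[Interval, ...]
    strand: str = "+"
    gene_id: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.blocks:
            if e <= s:
                raise ValueError(f"{self.read_id}: zero-width or inverted block ({s}, {e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.read_id}: blocks overlap or are unsorted")
            prev_end = e
        if not self.blocks:
            raise ValueError(f"{self.read_id}: alignment has no blocks")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def gaps(self) -> tuple[Interval, ...]:
        """Skipped intervals between consecutive blocks."""
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )


@dataclass(frozen=True)
class RawRead:
    """An unaligned read as it would appear in FASTQ."""

    read_id: str
    sequence: str
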