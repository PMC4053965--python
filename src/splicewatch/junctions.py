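"""Junction discovery, decoy-null construction and false-positive filtering.

The pipeline treats every distinct alignment gap as a candidate intron
("junction").  False positives -- typically mis-placed reads with short
exon overhangs and singleton support -- are calibrated against a decoy
null: junction references built by splicing exon flanks from *different
chromosomes* together in silico.  Reads are matched to junction
references by exact substring placement (no mismatches) with a minimum
anchor on both sides of the splice point, and the catalog is filtered by
an overhang/coverage rule (junctions kept when the maximum overhang
exceeds 20 nt and at least two reads span the junction, by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    GeneModel,
    Interval,
    RawRead,
    SizingError,
    SplicedAlignment,
)

logger = logging.getLogger(__name__)

#: Minimum anchor (nt) a read must keep on each side of the splice point
#: when matched against a junction reference.
DEFAULT_MIN_ANCHOR = 11


def default_flank(read_length: int) -> int:
    """Flank length of a junction reference for a given read length.

    The reference carries ``read_length - 11`` nt of exon sequence on
    either side of the splice point, so that any exact full-length read
    placement keeps an overhang of at least 11 nt (180 nt references for
    101-nt reads, 148 nt for 85-nt reads).
    """
    if read_length <= DEFAULT_MIN_ANCHOR:
        raise ValueError("read length must exceed the minimum anchor")
    return read_length - DEFAULT_MIN_ANCHOR


@dataclass
class Junction:
    """A candidate intron with read support.

    ``max_overhang`` is the per-junction aggregate of each supporting
    read's shorter flanking block (the largest such value over all
    supporting reads).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    read_count: int = 0
    max_overhang: int = 0
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"junction interval empty: ({self.start}, {self.end})")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class FilterConfig:
    """Keep a junction iff overhang > ``min_overhang_exclusive`` (strict)
    and support >= ``min_reads``.  ``exempt_annotated`` passes annotated
    junctions through unconditionally."""

    min_overhang_exclusive: int = 20
    min_reads: int = 2
    exempt_annotated: bool = False

    def __post_init__(self) -> None:
        if self.min_overhang_exclusive < 1 or self.min_reads < 1:
            raise ValueError("filter thresholds must be >= 1")


@dataclass(frozen=True)
class JunctionRef:
    """A junction reference sequence: donor flank || acceptor flank.

    ``donor_locus``/``acceptor_locus`` are ``(chrom, genome coordinate)``
    of the exon boundary contributing each flank.  For annotated
    references both loci sit on the same chromosome and delimit the
    intron; for random (decoy) references they come from different
    chromosomes.
    """

    ref_id: str
    sequence: str
    flank: int
    origin: str  # "annotated" | "random"
    donor_locus: tuple[str, int]
    acceptor_locus: tuple[str, int]
    strand: str = "."
    intron: tuple[str, int, int] | None = None  # (chrom, start, end) when annotated

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.flank:
            raise ValueError("reference sequence must be exactly 2 x flank long")


@dataclass(frozen=True)
class MatchRecord:
    """One read supporting one junction reference at one placement."""

    ref_id: str
    read_id: str
    offset: int
    overhang: int


@dataclass
class RefSupport:
    """Per-reference aggregate of matched reads (decoy-null bookkeeping)."""

    ref_id: str
    origin: str
    read_count: int
    max_overhang: int


@dataclass
class NullReport:
    """Overhang/coverage distributions per origin plus threshold survival."""

    per_junction: pd.DataFrame
    survival: pd.DataFrame
    note: str = ""


# ---------------------------------------------------------------------------
# Junction extraction from spliced alignments
# ---------------------------------------------------------------------------

def extract_junctions(
    alignments: Iterable[SplicedAlignment],
    annotation: Sequence[GeneModel] | None = None,
    genome: Mapping[str, str] | None = None,
) -> list[Junction]:
    """Collapse alignment gaps into a junction catalog.

    One junction per distinct ``(chrom, gap_start, gap_end)``;
    ``read_count`` counts supporting reads and ``max_overhang`` is the
    largest of each read's shorter gap-adjacent block.  Strand is taken
    from the overlapping gene when an annotation is given, otherwise
    inferred from GT/AG orientation when the genome is given, otherwise
    left unknown (``.``).
    """
    agg: dict[tuple[str, int, int], list[int]] = {}
    for aln in alignments:
        blocks = aln.blocks
        for i in range(len(blocks) - 1):
            gap = (blocks[i][1], blocks[i + 1][0])
            overhang = min(
                blocks[i][1] - blocks[i][0], blocks[i + 1][1] - blocks[i + 1][0]
            )
            key = (aln.chrom, gap[0], gap[1])
            entry = agg.setdefault(key, [0, 0])
            entry[0] += 1
            entry[1] = max(entry[1], overhang)

    annotated_introns: dict[tuple[str, int, int], str] = {}
    gene_index: dict[str, list[GeneModel]] = {}
    if annotation is not None:
        for gene in annotation:
            gene_index.setdefault(gene.chrom, []).append(gene)
            for s, e in gene.introns:
                annotated_introns[(gene.chrom, s, e)] = gene.strand
        for genes in gene_index.values():
            genes.sort(key=lambda g: g.start)

    catalog: list[Junction] = []
    for (chrom, s, e), (count, overhang) in sorted(agg.items()):
        key = (chrom, s, e)
        strand = annotated_introns.get(key, ".")
        annotated = key in annotated_introns
        if strand == "." and annotation is not None:
            gene = _containing_gene(gene_index.get(chrom, ()), s, e)
            if gene is not None:
                strand = gene.strand
        if strand == "." and genome is not None:
            strand = _gtag_strand(genome, chrom, s, e)
        catalog.append(
            Junction(
                chrom=chrom, start=s, end=e, strand=strand,
                read_count=count, max_overhang=overhang, annotated=annotated,
            )
        )
    return catalog


def _containing_gene(
    genes: Sequence[GeneModel], start: int, end: int
) -> GeneModel | None:
    for gene in genes:  # gene lists are short and non-overlapping on toy genomes
        if gene.start <= start and end <= gene.end:
            return gene
    return None


def _gtag_strand(genome: Mapping[str, str], chrom: str, s: int, e: int) -> str:
    seq = genome.get(chrom)
    if seq is None or e > len(seq):
        return "."
    head, tail = seq[s : s + 2].upper(), seq[e - 2 : e].upper()
    if head == "GT" and tail == "AG":
        return "+"
    if head == "CT" and tail == "AC":
        return "-"
    return "."


# ---------------------------------------------------------------------------
# Junction reference construction
# ---------------------------------------------------------------------------

def _transcript_flanks(
    gene: GeneModel, genome: Mapping[str, str]
) -> tuple[str, list[int]]:
    """Transcript sequence plus cumulative exon end offsets (transcribed order)."""
    seq = gene.transcript_sequence(genome)
    lengths = [e - s for s, e in gene.exons]
    if gene.strand == "-":
        lengths = lengths[::-1]
    cum: list[int] = []
    total = 0
    for length in lengths:
        total += length
        cum.append(total)
    return seq, cum


def _pad_left(seq: str, flank: int) -> str:
    return ("N" * (flank - len(seq))) + seq if len(seq) < flank else seq[-flank:]


def _pad_right(seq: str, flank: int) -> str:
    return seq + ("N" * (flank - len(seq))) if len(seq) < flank else seq[:flank]


def build_junction_refs(
    genome: Mapping[str, str],
    annotation: Sequence[GeneModel],
    flank: int,
    mode: str = "annotated",
    n_random: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[JunctionRef]:
    """Build annotated or random (decoy) junction references.

    Flank sequence is taken from the spliced transcript context, so exons
    shorter than the flank borrow sequence from their upstream/downstream
    neighbours and every reference has constant length ``2 * flank``
    (N-padded at transcript ends).  Random references join the donor-side
    flank of one exon with the acceptor-side flank of an exon on a
    *different* chromosome.
    """
    if mode not in ("annotated", "random"):
        raise ValueError(f"unknown mode {mode!r}")

    flanks: dict[str, tuple[str, list[int]]] = {
        gene.gene_id: _transcript_flanks(gene, genome) for gene in annotation
    }

    if mode == "annotated":
        refs: list[JunctionRef] = []
        for gene in annotation:
            seq, cum = flanks[gene.gene_id]
            n_introns = gene.n_exons - 1
            for k in range(n_introns):
                dpos = cum[k]
                donor = _pad_left(seq[:dpos], flank)
                acceptor = _pad_right(seq[dpos:], flank)
                g = gene.genome_intron_index(k)
                istart, iend = gene.introns[g]
                donor_coord = istart if gene.strand == "+" else iend
                acceptor_coord = iend if gene.strand == "+" else istart
                refs.append(
                    JunctionRef(
                        ref_id=f"{gene.gene_id}.J{k}",
                        sequence=donor + acceptor,
                        flank=flank,
                        origin="annotated",
                        donor_locus=(gene.chrom, donor_coord),
                        acceptor_locus=(gene.chrom, acceptor_coord),
                        strand=gene.strand,
                        intron=(gene.chrom, istart, iend),
                    )
                )
        return refs

    # random mode -----------------------------------------------------------
    if rng is None:
        rng = np.random.default_rng(seed)
    sites: list[tuple[GeneModel, int]] = [
        (gene, k) for gene in annotation for k in range(gene.n_exons)
    ]
    by_chrom: dict[str, int] = {}
    for gene, _ in sites:
        by_chrom[gene.chrom] = by_chrom.get(gene.chrom, 0) + 1
    if len(by_chrom) < 2:
        raise SizingError("random junction references need >= 2 chromosomes")
    total = len(sites)
    cross_pairs = total * total - sum(n * n for n in by_chrom.values())
    if n_random > cross_pairs:
        raise SizingError(
            f"requested {n_random} random references but only {cross_pairs} "
            "cross-chromosome exon pairs exist"
        )

    refs = []
    seen: set[tuple[int, int]] = set()
    while len(refs) < n_random:
        i = int(rng.integers(total))
        j = int(rng.integers(total))
        gene_a, ka = sites[i]
        gene_b, kb = sites[j]
        if gene_a.chrom == gene_b.chrom or (i, j) in seen:
            continue
        seen.add((i, j))
        seq_a, cum_a = flanks[gene_a.gene_id]
        seq_b, cum_b = flanks[gene_b.gene_id]
        dpos = cum_a[ka]
        apos = cum_b[kb] - (gene_b.exons[gene_b.genome_exon_index(kb)][1]
                            - gene_b.exons[gene_b.genome_exon_index(kb)][0])
        donor = _pad_left(seq_a[:dpos], flank)
        acceptor = _pad_right(seq_b[apos:], flank)
        ga = gene_a.genome_exon_index(ka)
        gb = gene_b.genome_exon_index(kb)
        donor_coord = gene_a.exons[ga][1] if gene_a.strand == "+" else gene_a.exons[ga][0]
        acceptor_coord = gene_b.exons[gb][0] if gene_b.strand == "+" else gene_b.exons[gb][1]
        refs.append(
            JunctionRef(
                ref_id=f"R{len(refs):05d}",
                sequence=donor + acceptor,
                flank=flank,
                origin="random",
                donor_locus=(gene_a.chrom, donor_coord),
                acceptor_locus=(gene_b.chrom, acceptor_coord),
            )
        )
    return refs


# ---------------------------------------------------------------------------
# Exact-substring matching of reads to junction references
# ---------------------------------------------------------------------------

def match_reads_to_refs(
    reads: Iterable[RawRead],
    refs: Sequence[JunctionRef],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[MatchRecord]:
    """Match reads to junction references with no mismatches.

    A read supports a reference iff it is an exact substring of the
    reference sequence *and* its placement crosses the splice point with
    at least ``min_anchor`` nt on both sides.  The recorded overhang is
    the shorter side of the placement.  A read matching several
    references (or several placements) is counted for each; multiplicity
    is logged.
    """
    reads = list(reads)
    lengths = {len(r.sequence) for r in reads}
    for ref in refs:
        for L in lengths:
            if L > len(ref.sequence):
                raise ValueError(
                    f"read length {L} exceeds reference length {len(ref.sequence)}"
                )

    # Index every anchored placement of every reference, keyed by the
    # substring a matching read must equal.  Lookup is then O(1) per read.
    index: dict[int, dict[str, list[tuple[str, int, int]]]] = {}
    for L in lengths:
        sub_index: dict[str, list[tuple[str, int, int]]] = {}
        for ref in refs:
            mid = len(ref.sequence) // 2
            for off in range(len(ref.sequence) - L + 1):
                left = mid - off
                right = off + L - mid
                if left >= min_anchor and right >= min_anchor:
                    sub_index.setdefault(ref.sequence[off : off + L], []).append(
                        (ref.ref_id, off, min(left, right))
                    )
        index[L] = sub_index

    records: list[MatchRecord] = []
    multi = 0
    for read in reads:
        hits = index[len(read.sequence)].get(read.sequence)
        if not hits:
            continue
        if len(hits) > 1:
            multi += 1
        for ref_id, off, overhang in hits:
            records.append(
                MatchRecord(ref_id=ref_id, read_id=read.read_id, offset=off, overhang=overhang)
            )
    if multi:
        logger.info("%d reads matched more than one junction reference", multi)
    return records


def summarize_support(
    refs: Sequence[JunctionRef], records: Iterable[MatchRecord]
) -> list[RefSupport]:
    """Aggregate match records per reference (references with >= 1 read)."""
    origin = {ref.ref_id: ref.origin for ref in refs}
    agg: dict[str, RefSupport] = {}
    for rec in records:
        sup = agg.get(rec.ref_id)
        if sup is None:
            agg[rec.ref_id] = RefSupport(
                ref_id=rec.ref_id, origin=origin[rec.ref_id],
                read_count=1, max_overhang=rec.overhang,
            )
        else:
            sup.read_count += 1
            sup.max_overhang = max(sup.max_overhang, rec.overhang)
    return [agg[k] for k in sorted(agg)]


# ---------------------------------------------------------------------------
# Null characterisation and filtering
# ---------------------------------------------------------------------------

_DEFAULT_OVERHANG_GRID = (0, 5, 10, 15, 20, 25)
_DEFAULT_READS_GRID = (1, 2, 3)


def characterize_null(
    random_records: Iterable[MatchRecord],
    annotated_records: Iterable[MatchRecord],
    random_refs: Sequence[JunctionRef],
    annotated_refs: Sequence[JunctionRef],
    overhang_grid: Sequence[int] = _DEFAULT_OVERHANG_GRID,
    reads_grid: Sequence[int] = _DEFAULT_READS_GRID,
) -> NullReport:
    """Tabulate overhang/coverage distributions per origin and the
    survival fraction of each origin under candidate threshold pairs."""
    support = summarize_support(random_refs, random_records) + summarize_support(
        annotated_refs, annotated_records
    )
    note = ""
    if not any(s.origin == "random" for s in support):
        note = "null not exercised: no read matched a random junction reference"
        logger.warning(note)
    per_junction = pd.DataFrame(
        [
            {
                "origin": s.origin,
                "ref_id": s.ref_id,
                "read_count": s.read_count,
                "max_overhang": s.max_overhang,
            }
            for s in support
        ],
        columns=["origin", "ref_id", "read_count", "max_overhang"],
    )
    rows = []
    for origin in ("random", "annotated"):
        sub = [s for s in support if s.origin == origin]
        for min_ov in overhang_grid:
            for min_reads in reads_grid:
                kept = sum(
                    1 for s in sub
                    if s.max_overhang > min_ov and s.read_count >= min_reads
                )
                rows.append(
                    {
                        "origin": origin,
                        "min_overhang_exclusive": min_ov,
                        "min_reads": min_reads,
                        "n_junctions": len(sub),
                        "n_survived": kept,
                        "survival": kept / len(sub) if sub else float("nan"),
                    }
                )
    return NullReport(per_junction=per_junction, survival=pd.DataFrame(rows), note=note)


def apply_filter(catalog: Iterable, cfg: FilterConfig = FilterConfig()) -> list:
    """Filter any catalog of objects carrying ``max_overhang``/``read_count``.

    The rule is strict on overhang ("more than" the threshold) and
    inclusive on read support.  Items are returned untouched, so the
    filter is idempotent and conservative.
    """
    kept = []
    for item in catalog:
        if cfg.exempt_annotated and getattr(item, "annotated", False):
            kept.append(item)
            continue
        if item.max_overhang > cfg.min_overhang_exclusive and item.read_count >= cfg.min_reads:
            kept.append(item)
    return kept


def junctions_to_frame(catalog: Sequence[Junction], kept: Sequence[Junction] | None = None) -> pd.DataFrame:
    kept_keys = {j.key for j in kept} if kept is not None else None
    rows = []
    for j in catalog:
        row = {
            "chrom": j.chrom, "start": j.start, "end": j.end, "strand": j.strand,
            "reads": j.read_count, "max_overhang": j.max_overhang,
            "annotated": j.annotated,
        }
        if kept_keys is not None:
            row["kept"] = j.key in kept_keys
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "reads", "max_overhang", "annotated"]
        + (["kept"] if kept_keys is not None else []),
    )
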