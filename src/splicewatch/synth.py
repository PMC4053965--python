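"""Synthetic spliced RNA-seq study generator with a ground-truth ledger.

The generator emulates the study design the pipeline was built for: a
compact plant-style transcriptome sequenced as fixed-length single-end
libraries (101 nt by default, 85 nt supported).  A wild-type condition
splices exactly as annotated; perturbed conditions carry planted

* intron retention at a tunable per-intron transcript fraction
  (0.15 by default, i.e. ~15% of a targeted gene's transcripts retain
  the intron),
* alternative 5'/3' splice sites offset by 2-10 nt from the dominant
  (annotated) sites, and
* exon skipping of targeted internal exons,

plus decoy junction-spanning reads drawn from cross-chromosome random
junction references to exercise the false-positive filter.  Every
planted deviation is written to a :class:`PlantedEventLedger`, so
downstream detectors can be scored against ground truth.

The simulator emits truth alignments directly (no aligner is run);
per-base substitution errors are applied to the raw FASTQ sequences only
and never move alignment coordinates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .junctions import build_junction_refs, JunctionRef
from .model import (
    GeneModel,
    Interval,
    MIN_INTRON_LEN,
    PlacementError,
    RawRead,
    SizingError,
    SplicedAlignment,
    revcomp,
    transcript_sequence,
    window_to_blocks,
)

logger = logging.getLogger(__name__)

IR = "IR"
ALT5SS = "ALT5SS"
ALT3SS = "ALT3SS"
CASSETTE = "CASSETTE"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Geometry and sequencing parameters of one synthetic study.

    Ranges are inclusive ``(lo, hi)`` pairs in nt.  Terminal exons are
    drawn longer than internal ones (mimicking UTR-bearing first/last
    exons) so that interior features sit in the flat part of the
    coverage profile.
    """

    n_chromosomes: int = 2
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_len: tuple[int, int] = (80, 140)
    terminal_exon_len: tuple[int, int] = (200, 280)
    intron_len: tuple[int, int] = (60, 120)
    intergenic_len: tuple[int, int] = (150, 400)
    read_length: int = 101
    library_depth: int = 50_000
    error_rate: float = 0.001
    ir_fraction: float = 0.15
    alt_ss_offset_range: tuple[int, int] = (2, 10)
    alt_ss_usage: float = 0.3
    skip_usage: float = 0.3
    decoy_read_count: int = 100
    decoy_overhang_max: int = 15
    decoy_singleton: bool = True
    max_chromosome_len: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30 nt")
        for name in ("error_rate", "ir_fraction", "alt_ss_usage", "skip_usage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "exons_per_gene", "exon_len", "terminal_exon_len",
            "intron_len", "intergenic_len", "alt_ss_offset_range",
        ):
            lo, hi = getattr(self, name)
            if hi < lo or lo < 1:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty or non-positive")
        if self.intron_len[0] < MIN_INTRON_LEN:
            raise ValueError(f"introns must be >= {MIN_INTRON_LEN} nt")
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise ValueError("need at least one chromosome and one gene")
        if self.exons_per_gene[0] < 2:
            raise ValueError("genes need >= 2 exons so every gene has an intron")


@dataclass(frozen=True)
class PlantedEvent:
    """One deviation from annotated splicing planted in a condition.

    ``index`` is a transcribed-order intron index (IR / alternative
    splice sites) or exon index (skipping).  ``offset`` is the signed
    splice-site shift in transcribed orientation (downstream positive);
    ``usage`` is the transcript fraction carrying the deviant isoform.
    """

    event_type: str
    gene_id: str
    index: int
    offset: int = 0
    usage: float = 0.15

    def __post_init__(self) -> None:
        if self.event_type not in (IR, ALT5SS, ALT3SS, CASSETTE):
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not 0.0 < self.usage <= 1.0:
            raise ValueError("usage fraction must lie in (0, 1]")
        if self.event_type in (ALT5SS, ALT3SS) and self.offset == 0:
            raise ValueError("alternative splice sites need a non-zero offset")


@dataclass(frozen=True)
class ConditionProfile:
    """Which genes carry which planted events in one condition."""

    name: str
    events: tuple[PlantedEvent, ...] = ()


@dataclass(frozen=True)
class LedgerEntry:
    condition: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # novel junction / retained intron interval, genome coords
    end: int
    offset: int
    usage: float


@dataclass
class PlantedEventLedger:
    """Ground truth emitted by the simulator (one row per planted event)."""

    entries: list[LedgerEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [e.__dict__ for e in self.entries],
            columns=[
                "condition", "event_type", "gene_id", "chrom", "strand",
                "start", "end", "offset", "usage",
            ],
        )

    def of_type(self, event_type: str, condition: str | None = None) -> list[LedgerEntry]:
        return [
            e for e in self.entries
            if e.event_type == event_type
            and (condition is None or e.condition == condition)
        ]


@dataclass
class Isoform:
    """One transcript structure in a condition's isoform pool."""

    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    weight: float
    event: PlantedEvent | None = None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def make_genome_and_annotation(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate a toy genome plus single-transcript gene models.

    Genes alternate +/- strand and are distributed round-robin over the
    chromosomes.  Every annotated intron is forced to carry canonical
    dinucleotides on the transcribed strand (GT...AG), so splice-site
    sequence analyses are exercised end to end.  Deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: 0 for c in chrom_names}
    placements: list[tuple[str, str, tuple[Interval, ...]]] = []

    for i in range(config.n_genes):
        chrom = chrom_names[i % config.n_chromosomes]
        strand = "+" if i % 2 == 0 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        gap = int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))
        pos = cursors[chrom] + gap
        exons: list[Interval] = []
        for k in range(n_ex):
            lo, hi = (
                config.terminal_exon_len if k in (0, n_ex - 1) else config.exon_len
            )
            length = int(rng.integers(lo, hi + 1))
            exons.append((pos, pos + length))
            pos += length
            if k < n_ex - 1:
                pos += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
        cursors[chrom] = exons[-1][1]
        placements.append((f"g{i:04d}", chrom, tuple(exons)))

    tail = config.intergenic_len[1]
    lengths = {c: cursors[c] + tail for c in chrom_names}
    if config.max_chromosome_len is not None:
        for c, length in lengths.items():
            if length > config.max_chromosome_len:
                raise SizingError(
                    f"{c} needs {length} nt but max_chromosome_len="
                    f"{config.max_chromosome_len}"
                )

    genome: dict[str, np.ndarray] = {
        c: _BASES[rng.integers(0, 4, size=lengths[c])].copy() for c in chrom_names
    }

    annotation: list[GeneModel] = []
    for idx, (gene_id, chrom, exons) in enumerate(placements):
        strand = "+" if idx % 2 == 0 else "-"
        arr = genome[chrom]
        for i in range(len(exons) - 1):
            istart, iend = exons[i][1], exons[i + 1][0]
            if strand == "+":
                arr[istart : istart + 2] = np.frombuffer(b"GT", dtype="S1")
                arr[iend - 2 : iend] = np.frombuffer(b"AG", dtype="S1")
            else:
                # transcribed GT...AG reads CT...AC on the forward strand
                arr[istart : istart + 2] = np.frombuffer(b"CT", dtype="S1")
                arr[iend - 2 : iend] = np.frombuffer(b"AC", dtype="S1")
        if strand == "+":
            anchor = exons[0][0] + 10
        else:
            anchor = exons[-1][1] - 11
        annotation.append(
            GeneModel(
                gene_id=gene_id, chrom=chrom, strand=strand,
                exons=exons, cds_frame_anchor=anchor,
            )
        )

    genome_str = {c: genome[c].tobytes().decode("ascii") for c in chrom_names}
    return genome_str, annotation


# ---------------------------------------------------------------------------
# Isoform pools with planted events
# ---------------------------------------------------------------------------

def _event_exons(gene: GeneModel, event: PlantedEvent) -> tuple[Interval, ...]:
    exons = list(gene.exons)
    if event.event_type == IR:
        g = gene.genome_intron_index(event.index)
        merged = (exons[g][0], exons[g + 1][1])
        return tuple(exons[:g] + [merged] + exons[g + 2 :])

    if event.event_type == CASSETTE:
        g = gene.genome_exon_index(event.index)
        if g in (0, len(exons) - 1):
            raise PlacementError(
                f"{gene.gene_id}: cannot skip a terminal exon (index {event.index})"
            )
        return tuple(exons[:g] + exons[g + 1 :])

    g = gene.genome_intron_index(event.index)
    istart, iend = gene.introns[g]
    d = event.offset
    if event.event_type == ALT5SS:
        # shift the donor boundary; transcribed-downstream is +d
        if gene.strand == "+":
            new_end = istart + d
            if not exons[g][0] < new_end <= iend - MIN_INTRON_LEN:
                raise PlacementError(f"{gene.gene_id}: ALT5SS offset {d} out of bounds")
            exons[g] = (exons[g][0], new_end)
        else:
            new_start = iend - d
            if not istart + MIN_INTRON_LEN <= new_start < exons[g + 1][1]:
                raise PlacementError(f"{gene.gene_id}: ALT5SS offset {d} out of bounds")
            exons[g + 1] = (new_start, exons[g + 1][1])
    else:  # ALT3SS: shift the acceptor boundary
        if gene.strand == "+":
            new_start = iend + d
            if not istart + MIN_INTRON_LEN <= new_start < exons[g + 1][1]:
                raise PlacementError(f"{gene.gene_id}: ALT3SS offset {d} out of bounds")
            exons[g + 1] = (new_start, exons[g + 1][1])
        else:
            new_end = istart - d
            if not exons[g][0] < new_end <= iend - MIN_INTRON_LEN:
                raise PlacementError(f"{gene.gene_id}: ALT3SS offset {d} out of bounds")
            exons[g] = (exons[g][0], new_end)
    return tuple(exons)


def _event_coords(gene: GeneModel, event: PlantedEvent) -> Interval:
    """Genome interval of the novel junction (or retained intron)."""
    if event.event_type == IR:
        return gene.introns[gene.genome_intron_index(event.index)]
    if event.event_type == CASSETTE:
        g = gene.genome_exon_index(event.index)
        return (gene.introns[g - 1][0], gene.introns[g][1])
    g = gene.genome_intron_index(event.index)
    istart, iend = gene.introns[g]
    d = event.offset
    if event.event_type == ALT5SS:
        return (istart + d, iend) if gene.strand == "+" else (istart, iend - d)
    return (istart, iend + d) if gene.strand == "+" else (istart - d, iend)


def simulate_isoforms(
    annotation: Sequence[GeneModel],
    config: SimConfig,
    profile: ConditionProfile,
) -> tuple[list[Isoform], PlantedEventLedger]:
    """Build a condition's isoform pool and its ground-truth ledger.

    Each gene contributes an annotated isoform plus one isoform per
    planted event; mixture weights equal the planted usage fractions,
    with the annotated isoform absorbing the remainder.
    """
    by_gene: dict[str, list[PlantedEvent]] = {}
    gene_map = {g.gene_id: g for g in annotation}
    for ev in profile.events:
        if ev.gene_id not in gene_map:
            raise PlacementError(f"planted event references unknown gene {ev.gene_id}")
        by_gene.setdefault(ev.gene_id, []).append(ev)

    pool: list[Isoform] = []
    ledger = PlantedEventLedger()
    for gene in annotation:
        events = by_gene.get(gene.gene_id, [])
        total_usage = sum(ev.usage for ev in events)
        if total_usage > 1.0 + 1e-9:
            raise PlacementError(
                f"{gene.gene_id}: planted usage fractions sum to {total_usage:.3f} > 1"
            )
        for j, ev in enumerate(events):
            exons = _event_exons(gene, ev)
            pool.append(
                Isoform(
                    isoform_id=f"{gene.gene_id}.{ev.event_type.lower()}{j}",
                    gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
                    exons=exons, weight=ev.usage, event=ev,
                )
            )
            start, end = _event_coords(gene, ev)
            ledger.entries.append(
                LedgerEntry(
                    condition=profile.name, event_type=ev.event_type,
                    gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
                    start=start, end=end, offset=ev.offset, usage=ev.usage,
                )
            )
        if total_usage < 1.0 - 1e-9 or not events:
            pool.append(
                Isoform(
                    isoform_id=f"{gene.gene_id}.ref",
                    gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
                    exons=gene.exons, weight=max(1.0 - total_usage, 0.0),
                )
            )
    return pool, ledger


def sample_isoforms(
    pool: Sequence[Isoform], n: int, rng: np.random.Generator
) -> list[Isoform]:
    """Draw ``n`` transcript molecules from the pool by mixture weight."""
    weights = np.array([iso.weight for iso in pool], dtype=float)
    weights /= weights.sum()
    idx = rng.choice(len(pool), size=n, p=weights)
    return [pool[i] for i in idx]


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: Mapping[str, str],
    pool: Sequence[Isoform],
    config: SimConfig,
    rng: np.random.Generator,
    library: str,
) -> tuple[list[SplicedAlignment], list[RawRead]]:
    """Sample fixed-length reads from the isoform pool.

    Each read is a uniform window on one isoform (isoforms chosen with
    probability proportional to mixture weight times the number of legal
    start positions, emulating uniform fragmentation).  The read is
    emitted twice: as a raw transcript-sense sequence with substitution
    errors at ``config.error_rate``, and as its truth-derived gapped
    alignment in genome coordinates (error-free; coordinates never move).
    Isoforms shorter than the read length are skipped with a warning.
    """
    L = config.read_length
    usable: list[Isoform] = []
    seqs: list[str] = []
    for iso in pool:
        if iso.length < L:
            logger.warning(
                "isoform %s (%d nt) shorter than read length %d; skipped",
                iso.isoform_id, iso.length, L,
            )
            continue
        if iso.weight <= 0:
            continue
        usable.append(iso)
        seqs.append(transcript_sequence(genome, iso.chrom, iso.exons, iso.strand))
    if not usable:
        raise SizingError("no isoform is long enough to sample reads from")

    probs = np.array(
        [iso.weight * (iso.length - L + 1) for iso in usable], dtype=float
    )
    probs /= probs.sum()
    iso_idx = rng.choice(len(usable), size=config.library_depth, p=probs)
    u = rng.random(config.library_depth)

    alignments: list[SplicedAlignment] = []
    reads: list[RawRead] = []
    for i in range(config.library_depth):
        iso = usable[iso_idx[i]]
        t0 = int(u[i] * (iso.length - L + 1))
        raw = seqs[iso_idx[i]][t0 : t0 + L]
        blocks = window_to_blocks(iso.exons, iso.strand, t0, t0 + L)
        forward = raw if iso.strand == "+" else revcomp(raw)
        read_id = f"{library}:{i:06d}"
        if config.error_rate > 0:
            raw = _mutate(raw, config.error_rate, rng)
        reads.append(RawRead(read_id=read_id, sequence=raw))
        alignments.append(
            SplicedAlignment(
                read_id=read_id, chrom=iso.chrom, blocks=blocks,
                strand=iso.strand, gene_id=iso.gene_id, sequence=forward,
            )
        )
    return alignments, reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    out = list(seq)
    for pos in np.nonzero(mask)[0]:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(3))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Decoy junction reads
# ---------------------------------------------------------------------------

def make_decoy_reads(
    genome: Mapping[str, str],
    annotation: Sequence[GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    refs: Sequence[JunctionRef] | None = None,
) -> tuple[list[RawRead], list[JunctionRef]]:
    """Generate reads spanning artificial cross-chromosome junctions.

    Decoy reads are exact substrings of random junction references
    (donor/acceptor flanks from exons on different chromosomes), placed
    so their overhang never exceeds ``config.decoy_overhang_max``.  In
    singleton mode each decoy junction is supported by exactly one read.
    The random reference pool is returned alongside the reads so the
    caller can rebuild the same null.
    """
    if config.n_chromosomes < 2:
        raise SizingError("decoy junctions need >= 2 chromosomes")
    if rng is None:
        rng = np.random.default_rng(config.seed + 7)
    L = config.read_length
    flank = L - 11
    if refs is None:
        refs = build_junction_refs(
            genome, annotation, flank=flank, mode="random",
            n_random=config.decoy_read_count, rng=rng,
        )
    cap = min(config.decoy_overhang_max, L // 2)
    if cap < 11:
        raise SizingError("decoy overhang cap below the 11 nt matcher anchor")

    reads: list[RawRead] = []
    for i in range(config.decoy_read_count):
        ref = refs[i % len(refs)] if config.decoy_singleton else refs[int(rng.integers(len(refs)))]
        overhang = int(rng.integers(11, cap + 1))
        left = overhang if rng.random() < 0.5 else L - overhang
        start = ref.flank - left
        seq = ref.sequence[start : start + L]
        reads.append(RawRead(read_id=f"decoy:{i:04d}", sequence=seq))
    return reads, list(refs)


# ---------------------------------------------------------------------------
# Default study profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileSpec:
    """How many genes of each planted class a condition carries."""

    n_ir: int = 0
    n_alt5: int = 0
    n_alt3: int = 0
    n_skip: int = 0
    n_coordinated: int = 0  # skip genes that also carry an alt SS on the skipped exon


def build_condition_profile(
    annotation: Sequence[GeneModel],
    config: SimConfig,
    name: str,
    spec: ProfileSpec,
    rng: np.random.Generator,
) -> ConditionProfile:
    """Assign planted events to disjoint gene sets.

    Intron-retention and alternative-splice-site targets are interior
    introns (both flanking exons internal), so recovery statistics are
    measured in the flat part of the coverage profile; skipped exons are
    internal by construction.
    """
    needed = spec.n_ir + spec.n_alt5 + spec.n_alt3 + spec.n_skip
    eligible = [g for g in annotation if g.n_exons >= 4]
    if needed > len(eligible):
        raise SizingError(
            f"profile needs {needed} genes with >= 4 exons but only "
            f"{len(eligible)} exist"
        )
    order = rng.permutation(len(eligible))
    genes = [eligible[i] for i in order]

    def interior_intron(gene: GeneModel) -> int:
        # transcribed intron indices 1 .. n-2 are flanked by internal exons
        n = gene.n_exons - 1
        return 1 + int(rng.integers(max(n - 2, 1)))

    def signed_offset() -> int:
        lo, hi = config.alt_ss_offset_range
        mag = int(rng.integers(lo, hi + 1))
        return mag if rng.random() < 0.5 else -mag

    events: list[PlantedEvent] = []
    cursor = 0
    for _ in range(spec.n_ir):
        gene = genes[cursor]; cursor += 1
        events.append(
            PlantedEvent(IR, gene.gene_id, interior_intron(gene), usage=config.ir_fraction)
        )
    for _ in range(spec.n_alt5):
        gene = genes[cursor]; cursor += 1
        events.append(
            PlantedEvent(
                ALT5SS, gene.gene_id, interior_intron(gene),
                offset=signed_offset(), usage=config.alt_ss_usage,
            )
        )
    for _ in range(spec.n_alt3):
        gene = genes[cursor]; cursor += 1
        events.append(
            PlantedEvent(
                ALT3SS, gene.gene_id, interior_intron(gene),
                offset=signed_offset(), usage=config.alt_ss_usage,
            )
        )
    for k in range(spec.n_skip):
        gene = genes[cursor]; cursor += 1
        exon_idx = 1 + int(rng.integers(gene.n_exons - 2))
        events.append(
            PlantedEvent(CASSETTE, gene.gene_id, exon_idx, usage=config.skip_usage)
        )
        if k < spec.n_coordinated:
            # the skipped exon also bears an alternative donor in other
            # transcripts, giving the planted skip/alt-SS co-occurrence
            events.append(
                PlantedEvent(
                    ALT5SS, gene.gene_id, exon_idx,
                    offset=signed_offset(), usage=min(config.alt_ss_usage, 0.2),
                )
            )
    return ConditionProfile(name=name, events=tuple(events))
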