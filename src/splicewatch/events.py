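"""Alternative-splicing event classification and intron-retention calling.

Junction-based events are classified by the geometric relation of a
novel junction to the annotated introns of its gene, after reorienting
minus-strand genes so that "donor" always means the transcribed 5' side:

* ``ALT5SS``  -- the junction shares its acceptor with an annotated
  intron but uses a different donor;
* ``ALT3SS``  -- shares the donor, different acceptor;
* ``CASSETTE`` / ``COORD_CASSETTE`` -- the junction joins the donor of
  one annotated intron to the acceptor of a downstream annotated
  intron, skipping one / several exons;
* ``MUTEX``   -- two cassette events over adjacent exons whose shared
  intron carries no read support (the exons are never co-included);
* ``ALT_FIRST`` / ``ALT_LAST`` -- the novel boundary lies beyond the
  annotated terminal exon.

Intron retention is called from unspliced coverage: an intron is
retained when at least five reads cover at least 50% of its bases
(defaults of :class:`IRConfig`).
"""
from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .junctions import Junction
from .model import GeneModel, Interval, SplicedAlignment

logger = logging.getLogger(__name__)

EVENT_TYPES = (
    "ALT5SS", "ALT3SS", "CASSETTE", "MUTEX", "COORD_CASSETTE",
    "ALT_FIRST", "ALT_LAST",
)


@dataclass
class ASEvent:
    """A classified junction-based alternative-splicing event."""

    event_type: str
    gene_id: str
    chrom: str
    strand: str
    junction: Interval                     # novel junction, genome coords
    dominant: Interval | None = None       # annotated counterpart intron
    partner_junction: Interval | None = None  # second junction of a MUTEX pair
    offset: int | None = None              # transcribed-orientation site shift
    alt_site: int | None = None            # genome coord of the shifted site
    dominant_site: int | None = None
    skipped_exons: tuple[int, ...] = ()    # transcribed exon indices
    read_count: int = 0

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.junction[0], self.junction[1], self.event_type)


@dataclass
class EventCatalog:
    events: list[ASEvent] = field(default_factory=list)
    unclassified: list[Junction] = field(default_factory=list)
    intergenic: list[Junction] = field(default_factory=list)

    def of_type(self, event_type: str) -> list[ASEvent]:
        return [e for e in self.events if e.event_type == event_type]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "event_type": e.event_type, "gene_id": e.gene_id,
                "chrom": e.chrom, "strand": e.strand,
                "junction_start": e.junction[0], "junction_end": e.junction[1],
                "dominant_start": e.dominant[0] if e.dominant else -1,
                "dominant_end": e.dominant[1] if e.dominant else -1,
                "offset": e.offset if e.offset is not None else 0,
                "skipped_exons": ",".join(map(str, e.skipped_exons)),
                "reads": e.read_count,
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "event_type", "gene_id", "chrom", "strand",
                "junction_start", "junction_end", "dominant_start",
                "dominant_end", "offset", "skipped_exons", "reads",
            ],
        )


@dataclass(frozen=True)
class IRConfig:
    """Thresholds of the intron-retention call."""

    min_reads: int = 5
    min_covered_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_reads < 1 or not 0 < self.min_covered_fraction <= 1:
            raise ValueError("IR thresholds must be positive")


@dataclass
class IntronRetentionCall:
    gene_id: str
    chrom: str
    strand: str
    intron: Interval
    n_unspliced_reads: int
    covered_fraction: float
    called: bool

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron[0], self.intron[1])


# ---------------------------------------------------------------------------
# Junction-based classification
# ---------------------------------------------------------------------------

def _dominant_intron(
    candidates: Sequence[Interval],
    junction_counts: Mapping[tuple[str, int, int], int],
    chrom: str,
) -> Interval:
    """The annotated intron sharing the conserved boundary: highest read
    count wins, ties broken by the smallest interval."""
    return max(
        candidates,
        key=lambda iv: (junction_counts.get((chrom, iv[0], iv[1]), 0), -(iv[1] - iv[0])),
    )


def classify_events(
    junctions: Sequence[Junction],
    annotation: Sequence[GeneModel],
) -> EventCatalog:
    """Classify novel junctions of a (filtered) catalog into AS events.

    Annotated junctions produce no event.  Junctions overlapping no gene
    are reported as intergenic; novel junctions matching no geometric
    rule are reported unclassified.  One junction yields at most one
    junction-based event.
    """
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for gene in annotation:
        genes_by_chrom.setdefault(gene.chrom, []).append(gene)
    for lst in genes_by_chrom.values():
        lst.sort(key=lambda g: g.start)
    starts_by_chrom = {c: [g.start for g in lst] for c, lst in genes_by_chrom.items()}

    counts = {j.key: j.read_count for j in junctions}
    catalog = EventCatalog()
    cassettes: dict[str, list[ASEvent]] = {}

    for j in junctions:
        if j.annotated:
            continue
        gene = _locate_gene(genes_by_chrom, starts_by_chrom, j)
        if gene is None:
            catalog.intergenic.append(j)
            continue
        event = _classify_one(j, gene, counts)
        if event is None:
            catalog.unclassified.append(j)
            continue
        catalog.events.append(event)
        if event.event_type == "CASSETTE":
            cassettes.setdefault(gene.gene_id, []).append(event)

    _mark_mutex(catalog, cassettes, counts, {g.gene_id: g for g in annotation})
    catalog.events.sort(key=lambda e: (e.chrom, e.junction, e.event_type))
    return catalog


def _locate_gene(
    genes_by_chrom: Mapping[str, list[GeneModel]],
    starts_by_chrom: Mapping[str, list[int]],
    j: Junction,
) -> GeneModel | None:
    genes = genes_by_chrom.get(j.chrom)
    if not genes:
        return None
    i = bisect_right(starts_by_chrom[j.chrom], j.start) - 1
    if i >= 0 and genes[i].start <= j.start and j.end <= genes[i].end:
        return genes[i]
    # allow a novel boundary to stick out of the gene span (alt first/last)
    for cand in genes[max(i, 0) : i + 2]:
        if cand.start < j.end and j.start < cand.end:
            return cand
    return None


def _classify_one(
    j: Junction,
    gene: GeneModel,
    counts: Mapping[tuple[str, int, int], int],
) -> ASEvent | None:
    introns = gene.introns
    strand = gene.strand
    start_index = {iv[0]: i for i, iv in enumerate(introns)}
    end_index = {iv[1]: i for i, iv in enumerate(introns)}

    # exact donor+acceptor matches to two different annotated introns:
    # exon skipping
    if j.start in start_index and j.end in end_index:
        gi, gj = start_index[j.start], end_index[j.end]
        if gj > gi:
            skipped_genome = tuple(range(gi + 1, gj + 1))
            n = gene.n_exons
            skipped = tuple(
                sorted(
                    k if strand == "+" else n - 1 - k for k in skipped_genome
                )
            )
            return ASEvent(
                event_type="CASSETTE" if len(skipped) == 1 else "COORD_CASSETTE",
                gene_id=gene.gene_id, chrom=j.chrom, strand=strand,
                junction=(j.start, j.end), skipped_exons=skipped,
                read_count=j.read_count,
            )

    shares_donor = j.start in start_index if strand == "+" else j.end in end_index
    shares_acceptor = j.end in end_index if strand == "+" else j.start in start_index

    if shares_acceptor and not shares_donor:
        # novel donor: alternative 5' splice site (or alternative first exon)
        if strand == "+":
            cands = [iv for iv in introns if iv[1] == j.end]
            dom = _dominant_intron(cands, counts, j.chrom)
            offset = j.start - dom[0]
            alt_site, dom_site = j.start, dom[0]
            beyond = j.start < gene.start
        else:
            cands = [iv for iv in introns if iv[0] == j.start]
            dom = _dominant_intron(cands, counts, j.chrom)
            offset = dom[1] - j.end
            alt_site, dom_site = j.end - 1, dom[1] - 1
            beyond = j.end > gene.end
        return ASEvent(
            event_type="ALT_FIRST" if beyond else "ALT5SS",
            gene_id=gene.gene_id, chrom=j.chrom, strand=strand,
            junction=(j.start, j.end), dominant=dom, offset=offset,
            alt_site=alt_site, dominant_site=dom_site, read_count=j.read_count,
        )

    if shares_donor and not shares_acceptor:
        # novel acceptor: alternative 3' splice site (or alternative last exon)
        if strand == "+":
            cands = [iv for iv in introns if iv[0] == j.start]
            dom = _dominant_intron(cands, counts, j.chrom)
            offset = j.end - dom[1]
            alt_site, dom_site = j.end - 1, dom[1] - 1
            beyond = j.end > gene.end
        else:
            cands = [iv for iv in introns if iv[1] == j.end]
            dom = _dominant_intron(cands, counts, j.chrom)
            offset = dom[0] - j.start
            alt_site, dom_site = j.start, dom[0]
            beyond = j.start < gene.start
        return ASEvent(
            event_type="ALT_LAST" if beyond else "ALT3SS",
            gene_id=gene.gene_id, chrom=j.chrom, strand=strand,
            junction=(j.start, j.end), dominant=dom, offset=offset,
            alt_site=alt_site, dominant_site=dom_site, read_count=j.read_count,
        )

    return None


def _mark_mutex(
    catalog: EventCatalog,
    cassettes: Mapping[str, list[ASEvent]],
    counts: Mapping[tuple[str, int, int], int],
    gene_map: Mapping[str, GeneModel],
) -> None:
    """Merge adjacent never-co-included cassette pairs into MUTEX events.

    Two single-exon cassettes over adjacent exons are mutually exclusive
    when the annotated intron *between* the two exons has no junction
    support (junction reads cannot phase distant exons, so this is the
    strongest junction-level evidence available).
    """
    for gene_id, evs in cassettes.items():
        gene = gene_map[gene_id]
        by_exon = {e.skipped_exons[0]: e for e in evs if len(e.skipped_exons) == 1}
        for k in sorted(by_exon):
            a, b = by_exon.get(k), by_exon.get(k + 1)
            if a is None or b is None or a.event_type != "CASSETTE" or b.event_type != "CASSETTE":
                continue
            shared = gene.introns[gene.genome_intron_index(k)]
            if counts.get((gene.chrom, shared[0], shared[1]), 0) > 0:
                continue
            a.event_type = "MUTEX"
            a.partner_junction = b.junction
            catalog.events.remove(b)


# ---------------------------------------------------------------------------
# Intron retention
# ---------------------------------------------------------------------------

def call_intron_retention(
    alignments: Iterable[SplicedAlignment],
    annotation: Sequence[GeneModel],
    cfg: IRConfig = IRConfig(),
) -> list[IntronRetentionCall]:
    """Call retained introns from unspliced coverage.

    For every annotated intron, ``n_unspliced_reads`` counts reads with
    at least one aligned base inside the intron and no alignment gap
    equal to the intron; ``covered_fraction`` is the fraction of intron
    bases covered by such reads at >= 1x.  The intron is called retained
    iff both thresholds are met.
    """
    introns: list[tuple[str, Interval, GeneModel]] = []
    for gene in annotation:
        for iv in gene.introns:
            if iv[1] <= iv[0]:
                raise ValueError(f"{gene.gene_id}: zero-length intron {iv}")
            introns.append((gene.chrom, iv, gene))
    introns.sort(key=lambda t: (t[0], t[1][0]))
    starts_by_chrom: dict[str, list[int]] = {}
    slots_by_chrom: dict[str, list[int]] = {}
    for idx, (chrom, iv, _) in enumerate(introns):
        starts_by_chrom.setdefault(chrom, []).append(iv[0])
        slots_by_chrom.setdefault(chrom, []).append(idx)

    coverage = [np.zeros(iv[1] - iv[0], dtype=bool) for _, iv, _ in introns]
    read_counts = [0] * len(introns)
    last_read = [-1] * len(introns)

    for rid, aln in enumerate(alignments):
        starts = starts_by_chrom.get(aln.chrom)
        if starts is None:
            continue
        slots = slots_by_chrom[aln.chrom]
        gaps = set(aln.gaps)
        for bs, be in aln.blocks:
            # candidate introns overlapping this block (introns are disjoint)
            i = bisect_left(starts, bs)
            if i > 0 and introns[slots[i - 1]][1][1] > bs:
                i -= 1
            while i < len(starts) and starts[i] < be:
                slot = slots[i]
                _, iv, _ = introns[slot]
                if (iv[0], iv[1]) in gaps:
                    i += 1
                    continue
                lo, hi = max(bs, iv[0]), min(be, iv[1])
                if lo < hi:
                    coverage[slot][lo - iv[0] : hi - iv[0]] = True
                    if last_read[slot] != rid:
                        last_read[slot] = rid
                        read_counts[slot] += 1
                i += 1

    calls = []
    for slot, (chrom, iv, gene) in enumerate(introns):
        frac = float(coverage[slot].mean())
        n = read_counts[slot]
        calls.append(
            IntronRetentionCall(
                gene_id=gene.gene_id, chrom=chrom, strand=gene.strand,
                intron=iv, n_unspliced_reads=n, covered_fraction=frac,
                called=n >= cfg.min_reads and frac >= cfg.min_covered_fraction,
            )
        )
    return calls


def ir_calls_to_frame(calls: Sequence[IntronRetentionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id, "chrom": c.chrom, "strand": c.strand,
                "intron_start": c.intron[0], "intron_end": c.intron[1],
                "unspliced_reads": c.n_unspliced_reads,
                "covered_fraction": round(c.covered_fraction, 6),
                "called": c.called,
            }
            for c in calls
        ],
        columns=[
            "gene_id", "chrom", "strand", "intron_start", "intron_end",
            "unspliced_reads", "covered_fraction", "called",
        ],
    )


# ---------------------------------------------------------------------------
# Coding-frame impact
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class FrameImpact:
    kind: str  # in_frame_indel | frameshift_PTC | PTC_in_retained_intron | non_coding
    codons: int | None = None


def frame_impact(
    delta_nt: int,
    retained_sequence: str | None = None,
    within_cds: bool = True,
    frame_offset: int = 0,
) -> FrameImpact:
    """Coding consequence of a splice change.

    ``delta_nt`` is the net coding length inserted (positive) or removed
    (negative) by the event; the caller supplies it explicitly because
    reported site shifts are convention-dependent.  For intron retention
    pass the retained sequence (transcribed sense) and the codon phase
    at which it is inserted (``frame_offset`` = nt until the next codon
    boundary): the sequence is scanned for in-frame stop codons.
    """
    if not within_cds:
        return FrameImpact("non_coding")
    if retained_sequence is not None:
        seq = retained_sequence.upper()
        if len(seq) % 3 != 0:
            return FrameImpact("frameshift_PTC")
        for p in range(frame_offset % 3, len(seq) - 2, 3):
            if seq[p : p + 3] in _STOPS:
                return FrameImpact("PTC_in_retained_intron")
        return FrameImpact("in_frame_indel", codons=len(seq) // 3)
    if delta_nt % 3 != 0:
        return FrameImpact("frameshift_PTC")
    return FrameImpact("in_frame_indel", codons=abs(delta_nt) // 3)
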