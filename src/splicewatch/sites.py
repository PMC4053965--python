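"""Splice-site sequence matrices, positional offsets and coordination.

Sites are handled in transcribed orientation throughout: minus-strand
sequence is reverse-complemented before tallying, donor matrices are
anchored so intron positions +1/+2 hold the GT (GU in RNA), acceptor
matrices so -2/-1 hold the AG, and site offsets are signed with
transcribed-downstream positive.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import fisher_2x2
from .events import ASEvent
from .model import GeneModel, Interval

logger = logging.getLogger(__name__)

_ALPHABET = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class SpliceSite:
    """One splice site, anchored on the intron base adjacent to the boundary.

    ``pos`` is the genome coordinate of the first intron base (donor) or
    the last intron base (acceptor), in transcribed orientation.
    """

    chrom: str
    pos: int
    strand: str
    kind: str  # "donor" | "acceptor"


def donor_site(chrom: str, intron: Interval, strand: str) -> SpliceSite:
    pos = intron[0] if strand == "+" else intron[1] - 1
    return SpliceSite(chrom=chrom, pos=pos, strand=strand, kind="donor")


def acceptor_site(chrom: str, intron: Interval, strand: str) -> SpliceSite:
    pos = intron[1] - 1 if strand == "+" else intron[0]
    return SpliceSite(chrom=chrom, pos=pos, strand=strand, kind="acceptor")


@dataclass
class PositionFrequencyMatrix:
    """Per-position base tallies around a splice site.

    Positions are signed (no zero): negative upstream of the exon/intron
    boundary, positive downstream, in transcribed orientation.
    """

    positions: tuple[int, ...]
    counts: np.ndarray  # shape (4, len(positions)), rows A/C/G/T
    n_sequences: int

    def column(self, position: int) -> dict[str, int]:
        j = self.positions.index(position)
        return {base: int(self.counts[i, j]) for i, base in enumerate(_ALPHABET)}

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.counts.T, columns=list(_ALPHABET),
        )
        frame.insert(0, "position", self.positions)
        return frame


def site_window(
    genome: Mapping[str, str], site: SpliceSite, upstream: int, downstream: int
) -> str | None:
    """Transcribed-orientation sequence covering positions
    -upstream..-1, +1..+downstream around the site boundary, or None when
    the window leaves the chromosome."""
    seq = genome[site.chrom]
    direction = 1 if site.strand == "+" else -1
    out = []
    if site.kind == "donor":
        rng = list(range(-upstream, 0)) + list(range(1, downstream + 1))
        coords = [site.pos + direction * (i - 1) if i > 0 else site.pos + direction * i
                  for i in rng]
    else:
        rng = list(range(-upstream, 0)) + list(range(1, downstream + 1))
        coords = [site.pos + direction * i if i > 0 else site.pos + direction * (i + 1)
                  for i in rng]
    for c in coords:
        if not 0 <= c < len(seq):
            return None
        base = seq[c].upper()
        out.append(base if site.strand == "+" else _COMP.get(base, "N"))
    return "".join(out)


def extract_site_matrix(
    genome: Mapping[str, str],
    sites: Iterable[SpliceSite],
    window: int,
    site_kind: str,
) -> PositionFrequencyMatrix:
    """Tally bases in a +/-``window`` nt frame around each site.

    Sites whose window exceeds chromosome bounds are skipped with a log
    entry.  Raises if no site yields a sequence.
    """
    if site_kind not in ("donor", "acceptor"):
        raise ValueError(f"unknown site kind {site_kind!r}")
    positions = tuple(list(range(-window, 0)) + list(range(1, window + 1)))
    counts = np.zeros((4, len(positions)), dtype=int)
    n = 0
    for site in sites:
        if site.kind != site_kind:
            raise ValueError(f"site kind mismatch: expected {site_kind}, got {site.kind}")
        seq = site_window(genome, site, window, window)
        if seq is None:
            logger.info("site %s:%d window exceeds chromosome bounds; skipped",
                        site.chrom, site.pos)
            continue
        for j, base in enumerate(seq):
            i = _ALPHABET.find(base)
            if i >= 0:
                counts[i, j] += 1
        n += 1
    if n == 0:
        raise ValueError("no site produced a sequence window (empty matrix)")
    return PositionFrequencyMatrix(positions=positions, counts=counts, n_sequences=n)


# ---------------------------------------------------------------------------
# Alternative-site offsets
# ---------------------------------------------------------------------------

@dataclass
class OffsetHistogram:
    """Signed distances of alternative splice sites from their dominant
    sites (transcribed-downstream positive), binned per nt."""

    window: int
    counts: dict[int, int]
    n_total: int
    n_skipped: int = 0

    @property
    def offsets(self) -> list[int]:
        out = []
        for k in sorted(self.counts):
            out.extend([k] * self.counts[k])
        return out

    def mass_within(self, radius: int = 10) -> float:
        if self.n_total == 0:
            return float("nan")
        inside = sum(v for k, v in self.counts.items() if abs(k) <= radius)
        return inside / self.n_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"offset": k, "count": self.counts[k]} for k in sorted(self.counts)],
            columns=["offset", "count"],
        )


def offset_distribution(
    events: Iterable[ASEvent], window: int = 50
) -> OffsetHistogram:
    """Histogram of alternative-site offsets from their dominant sites.

    Takes the alternative 5'/3'SS events of one condition (events
    pairing each alternative site with its dominant counterpart);
    unpaired events are skipped with a log entry.  Offsets are signed in
    transcribed orientation and clipped to +/-``window``.
    """
    counts: Counter[int] = Counter()
    n = skipped = 0
    for ev in events:
        if ev.alt_site is None or ev.dominant_site is None:
            skipped += 1
            continue
        direction = 1 if ev.strand == "+" else -1
        offset = (ev.alt_site - ev.dominant_site) * direction
        if offset == 0:
            skipped += 1
            continue
        if abs(offset) <= window:
            counts[offset] += 1
        n += 1
    if skipped:
        logger.info("offset_distribution: %d sites without a dominant pairing skipped",
                    skipped)
    return OffsetHistogram(window=window, counts=dict(counts), n_total=n,
                           n_skipped=skipped)


# ---------------------------------------------------------------------------
# Skipping / alternative-SS coordination
# ---------------------------------------------------------------------------

@dataclass
class CoordinationResult:
    observed_fraction: float
    background_fraction: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def coordination_test(
    skipped_exons: Iterable[tuple[str, int]],
    alt_ss_exons: Iterable[tuple[str, int]],
    annotation: Sequence[GeneModel],
) -> CoordinationResult | None:
    """Do skipped exons carry alternative 5'/3' splice sites more often
    than annotated exons at large?

    Exons are identified as ``(gene_id, transcribed exon index)``.  The
    2x2 table (skipped vs not) x (has alt SS vs not) over all annotated
    exons is tested with Fisher's exact test.  Returns None (test
    skipped) when there are no skipped exons.
    """
    skipped = set(skipped_exons)
    alt = set(alt_ss_exons)
    if not skipped:
        logger.warning("coordination_test skipped: no skipped exons")
        return None
    universe = {
        (gene.gene_id, k) for gene in annotation for k in range(gene.n_exons)
    }
    skipped &= universe
    alt &= universe
    a = len(skipped & alt)
    b = len(skipped - alt)
    c = len(alt - skipped)
    d = len(universe) - a - b - c
    table = ((a, b), (c, d))
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        p = fisher_2x2(table)
    n_not_skipped = len(universe) - len(skipped)
    return CoordinationResult(
        observed_fraction=a / len(skipped),
        background_fraction=c / n_not_skipped if n_not_skipped else float("nan"),
        p_value=p,
        table=table,
    )


# ---------------------------------------------------------------------------
# Helpers tying events to sites/exons
# ---------------------------------------------------------------------------

def event_alt_ss_exon(event: ASEvent, gene: GeneModel) -> tuple[str, int]:
    """The exon whose boundary an alternative splice site shifts
    (donor-side exon for ALT5SS, acceptor-side exon for ALT3SS)."""
    if event.dominant is None:
        raise ValueError("event carries no dominant intron")
    g = gene.introns.index(event.dominant)
    n = gene.n_exons
    if event.event_type in ("ALT5SS", "ALT_FIRST"):
        exon_genome = g if gene.strand == "+" else g + 1
    elif event.event_type in ("ALT3SS", "ALT_LAST"):
        exon_genome = g + 1 if gene.strand == "+" else g
    else:
        raise ValueError(f"not an alternative-SS event: {event.event_type}")
    return (gene.gene_id, exon_genome if gene.strand == "+" else n - 1 - exon_genome)


def annotated_donor_sites(annotation: Sequence[GeneModel]) -> list[SpliceSite]:
    return [
        donor_site(g.chrom, iv, g.strand) for g in annotation for iv in g.introns
    ]


def annotated_acceptor_sites(annotation: Sequence[GeneModel]) -> list[SpliceSite]:
    return [
        acceptor_site(g.chrom, iv, g.strand) for g in annotation for iv in g.introns
    ]
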