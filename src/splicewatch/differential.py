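"""Equal-depth resampling and Fisher's-exact differential splicing tests.

Libraries are first equalised by uniform resampling of uniquely mapped
alignment records without replacement.  Each matched event (or intron)
is then tested with a two-sided Fisher's exact test on the 2x2 table

    (focal reads, corresponding flanking-exon reads) x (condition A, B)

at p < 0.01 for junction-based events and p < 0.001 for intron
retention.  An event detected in only one condition is deemed
significant when it has at least five supporting reads; its p-value is
reported as assigned zero, flagged, and never silently merged with
computed p-values.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .model import SizingError, SplicedAlignment

#: Tables with totals up to this size are evaluated in exact integer
#: arithmetic; larger tables fall back to log-space hypergeometric
#: summation with a relative tie tolerance.
_EXACT_TOTAL_LIMIT = 2000
_LOG_TIE_TOL = 1e-7


@dataclass(frozen=True)
class ResampleConfig:
    """Equal-depth resampling of alignment records (without replacement)."""

    n_reads: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")


@dataclass(frozen=True)
class EventCounts:
    """Matched per-condition counts for one tested event or intron."""

    event_id: str
    alt_a: int
    exon_a: int
    alt_b: int
    exon_b: int


@dataclass
class DifferentialResult:
    event_id: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    assigned_zero: bool
    direction: str  # "A_over" | "B_over" | "none"
    significant: bool


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(
    alignments: Sequence[SplicedAlignment], cfg: ResampleConfig
) -> list[SplicedAlignment]:
    """Draw exactly ``cfg.n_reads`` distinct records uniformly without
    replacement, preserving library order; deterministic under the seed."""
    if cfg.n_reads > len(alignments):
        raise SizingError(
            f"cannot draw {cfg.n_reads} reads from a library of {len(alignments)}"
        )
    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(len(alignments), size=cfg.n_reads, replace=False)
    idx.sort()
    return [alignments[i] for i in idx]


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    The p-value is the hypergeometric-tail sum of the probabilities of
    all tables (with the observed margins) no more probable than the
    observed one.  Small tables use exact integer arithmetic so that tie
    inclusion is unambiguous; large tables use log-space summation.  A
    zero margin makes every table equally (un)informative: p := 1 with a
    warning.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"table entries must be non-negative integers: {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("fisher_2x2: zero margin, p set to 1", stacklevel=2)
        return 1.0
    kmin, kmax = max(0, c1 - r2), min(c1, r1)

    if n <= _EXACT_TOTAL_LIMIT:
        weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)]
        observed = math.comb(r1, a) * math.comb(r2, c1 - a)
        total = math.comb(n, c1)
        return min(1.0, sum(w for w in weights if w <= observed) / total)

    k = np.arange(kmin, kmax + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(c2 + 1))
    )
    obs = logpmf[a - kmin]
    p = float(np.exp(logpmf[logpmf <= obs + _LOG_TIE_TOL]).sum())
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Per-event / per-intron tests
# ---------------------------------------------------------------------------

def _direction(counts: EventCounts) -> str:
    ra = counts.alt_a / counts.exon_a if counts.exon_a else float(counts.alt_a > 0)
    rb = counts.alt_b / counts.exon_b if counts.exon_b else float(counts.alt_b > 0)
    if ra > rb:
        return "A_over"
    if rb > ra:
        return "B_over"
    return "none"


def _test(
    counts: Iterable[EventCounts], alpha: float, min_unique_reads: int
) -> list[DifferentialResult]:
    results = []
    for ec in counts:
        table = ((ec.alt_a, ec.exon_a), (ec.alt_b, ec.exon_b))
        assigned = (ec.alt_a == 0 and ec.alt_b >= min_unique_reads) or (
            ec.alt_b == 0 and ec.alt_a >= min_unique_reads
        )
        if assigned:
            p = 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = fisher_2x2(table)
        results.append(
            DifferentialResult(
                event_id=ec.event_id,
                table=table,
                p_value=p,
                assigned_zero=assigned,
                direction=_direction(ec),
                significant=assigned or p < alpha,
            )
        )
    return results


def test_events(
    counts: Iterable[EventCounts],
    alpha_as: float = 0.01,
    min_unique_reads: int = 5,
) -> list[DifferentialResult]:
    """Differential junction-based AS events (p < 0.01, unique-event rule
    at >= 5 junction reads)."""
    return _test(counts, alpha_as, min_unique_reads)


def test_introns(
    counts: Iterable[EventCounts],
    alpha_ir: float = 0.001,
    min_unique_coverage: int = 5,
) -> list[DifferentialResult]:
    """Differential intron retention (p < 0.001, unique rule at >= 5x
    intron read coverage)."""
    return _test(counts, alpha_ir, min_unique_coverage)


def results_to_frame(
    results: Sequence[DifferentialResult], with_bh: bool = True
) -> pd.DataFrame:
    rows = [
        {
            "event_id": r.event_id,
            "alt_a": r.table[0][0], "exon_a": r.table[0][1],
            "alt_b": r.table[1][0], "exon_b": r.table[1][1],
            "p_value": r.p_value, "assigned_zero": r.assigned_zero,
            "direction": r.direction, "significant": r.significant,
        }
        for r in results
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "event_id", "alt_a", "exon_a", "alt_b", "exon_b",
            "p_value", "assigned_zero", "direction", "significant",
        ],
    )
    if with_bh and len(frame):
        # advisory column only: the headline calls mirror the uncorrected rule
        frame["q_value_bh"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    return frame


# ---------------------------------------------------------------------------
# Global comparison and rescue profiling
# ---------------------------------------------------------------------------

def global_comparison(
    events_a: Mapping[str, int] | Sequence,
    events_b: Mapping[str, int] | Sequence,
    total_a: int,
    total_b: int,
    event_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-event-type comparison of junction-read totals between two
    equal-depth catalogs.

    Accepts either ``{event_type: junction_reads}`` mappings or event
    lists carrying ``event_type``/``read_count``; tests each type's
    junction reads against the uniquely mapped totals with Fisher's
    exact test.
    """
    def tally(events) -> tuple[dict[str, int], dict[str, int]]:
        reads: dict[str, int] = {}
        counts: dict[str, int] = {}
        if isinstance(events, Mapping):
            return dict(events), {k: -1 for k in events}
        for e in events:
            reads[e.event_type] = reads.get(e.event_type, 0) + e.read_count
            counts[e.event_type] = counts.get(e.event_type, 0) + 1
        return reads, counts

    reads_a, n_a = tally(events_a)
    reads_b, n_b = tally(events_b)
    if event_types is None:
        from .events import EVENT_TYPES
        event_types = EVENT_TYPES
    rows = []
    for et in event_types:
        ja, jb = reads_a.get(et, 0), reads_b.get(et, 0)
        if ja == 0 and jb == 0:
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = fisher_2x2(((ja, total_a - ja), (jb, total_b - jb)))
        rows.append(
            {
                "event_type": et,
                "n_events_a": n_a.get(et, 0), "n_events_b": n_b.get(et, 0),
                "junction_reads_a": ja, "junction_reads_b": jb,
                "p_value": p,
                "direction": (
                    "A_over" if ja / total_a > jb / total_b
                    else "B_over" if jb / total_b > ja / total_a else "none"
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_type", "n_events_a", "n_events_b",
            "junction_reads_a", "junction_reads_b", "p_value", "direction",
        ],
    )


def profile_rescue(
    coverage: Mapping[str, Mapping[str, int]],
    totals: Mapping[str, int],
) -> pd.DataFrame:
    """Normalise per-event coverage by total uniquely mapped reads.

    ``coverage`` maps event id -> {group: read count}; the result holds
    reads-per-million-mapped per group, one row per event, supporting
    the rescue readout (events elevated in one group returning to
    baseline in another).
    """
    if not coverage:
        raise ValueError("profile_rescue needs a non-empty event set")
    groups = list(totals)
    rows = []
    for event_id in sorted(coverage):
        row: dict[str, object] = {"event_id": event_id}
        for g in groups:
            row[g] = coverage[event_id].get(g, 0) / totals[g] * 1e6
        rows.append(row)
    return pd.DataFrame(rows, columns=["event_id"] + groups)
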