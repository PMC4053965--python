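"""Feature-level expression (RPKM), intron-retention proportions and QC.

Exon expression counts every aligned base fractionally (a read
overlapping an exon/intron boundary is split by overlap length, so no
base is counted twice); intron expression counts only unspliced reads
overlapping intron bases -- junction reads gapped over the intron are
exon evidence.  RPKM = reads per kilobase of feature per million mapped
reads.
"""
from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GeneModel, Interval, SplicedAlignment


@dataclass(frozen=True)
class ExpressionRecord:
    feature_id: str
    feature_kind: str  # exon | intron | transcript | gene
    read_count: float
    length: int
    rpkm: float


@dataclass(frozen=True)
class IRProportion:
    """Retained-intron RPKM over combined flanking-exon RPKM."""

    intron_id: str
    intron_rpkm: float
    flanking_exon_rpkm: float
    proportion: float
    defined: bool


def rpkm(read_count: float, length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if length_nt <= 0 or total_mapped <= 0:
        raise ValueError("feature length and mapped total must be positive")
    return read_count / (length_nt / 1000.0) / (total_mapped / 1e6)


# ---------------------------------------------------------------------------
# Fractional feature counting
# ---------------------------------------------------------------------------

class FeatureIndex:
    """Distinct/fractional read counting over non-overlapping features.

    Features are ``(feature_id, chrom, start, end)``; features on one
    chromosome must not overlap (exons and introns of a gene partition
    its span, and toy genes never overlap).
    """

    def __init__(self, features: Iterable[tuple[str, str, int, int]]):
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for fid, chrom, s, e in features:
            if e <= s:
                raise ValueError(f"feature {fid} is empty")
            per_chrom.setdefault(chrom, []).append((s, e, fid))
        self._features: dict[str, list[tuple[int, int, str]]] = {}
        self._starts: dict[str, list[int]] = {}
        for chrom, lst in per_chrom.items():
            lst.sort()
            for (s1, e1, f1), (s2, _, f2) in zip(lst, lst[1:]):
                if s2 < e1:
                    raise ValueError(f"features {f1} and {f2} overlap")
            self._features[chrom] = lst
            self._starts[chrom] = [s for s, _, _ in lst]

    def overlaps(self, chrom: str, start: int, end: int) -> list[tuple[str, int]]:
        """(feature_id, overlap_nt) for every feature overlapping [start, end)."""
        feats = self._features.get(chrom)
        if not feats:
            return []
        starts = self._starts[chrom]
        i = bisect_left(starts, start)
        if i > 0 and feats[i - 1][1] > start:
            i -= 1
        out = []
        while i < len(feats) and feats[i][0] < end:
            s, e, fid = feats[i]
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out.append((fid, hi - lo))
            i += 1
        return out


def feature_read_counts(
    alignments: Iterable[SplicedAlignment],
    index: FeatureIndex,
    fractional: bool = True,
) -> dict[str, float]:
    """Per-feature read counts.

    Fractional mode assigns each read to features in proportion to the
    aligned bases overlapping them; distinct mode counts each read once
    per touched feature.
    """
    counts: dict[str, float] = {}
    for aln in alignments:
        touched: dict[str, int] = {}
        for bs, be in aln.blocks:
            for fid, ov in index.overlaps(aln.chrom, bs, be):
                touched[fid] = touched.get(fid, 0) + ov
        if not touched:
            continue
        if fractional:
            total = aln.aligned_length
            for fid, ov in touched.items():
                counts[fid] = counts.get(fid, 0.0) + ov / total
        else:
            for fid in touched:
                counts[fid] = counts.get(fid, 0.0) + 1.0
    return counts


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def _exon_features(annotation: Sequence[GeneModel]):
    for gene in annotation:
        for i, (s, e) in enumerate(gene.exons):
            yield (f"{gene.gene_id}.exon{i}", gene.chrom, s, e)


def _intron_features(annotation: Sequence[GeneModel]):
    for gene in annotation:
        for i, (s, e) in enumerate(gene.introns):
            yield (f"{gene.gene_id}.intron{i}", gene.chrom, s, e)


def expression_table(
    alignments: Sequence[SplicedAlignment],
    annotation: Sequence[GeneModel],
    total_mapped: int | None = None,
) -> pd.DataFrame:
    """Exon and intron expression records for one library.

    Intron counts include only unspliced reads (reads whose aligned
    bases fall inside the intron); spliced reads gapped over an intron
    never touch its bases and therefore count toward exons only.
    """
    if total_mapped is None:
        total_mapped = len(alignments)
    lengths: dict[str, int] = {}
    kinds: dict[str, str] = {}
    feats = []
    for fid, chrom, s, e in _exon_features(annotation):
        feats.append((fid, chrom, s, e))
        lengths[fid], kinds[fid] = e - s, "exon"
    for fid, chrom, s, e in _intron_features(annotation):
        feats.append((fid, chrom, s, e))
        lengths[fid], kinds[fid] = e - s, "intron"
    index = FeatureIndex(feats)
    counts = feature_read_counts(alignments, index, fractional=True)
    rows = [
        {
            "feature_id": fid,
            "feature_kind": kinds[fid],
            "gene_id": fid.split(".")[0],
            "read_count": round(counts.get(fid, 0.0), 6),
            "length": lengths[fid],
            "rpkm": round(rpkm(counts.get(fid, 0.0), lengths[fid], total_mapped), 6),
        }
        for fid, _, _, _ in feats
    ]
    return pd.DataFrame(
        rows,
        columns=["feature_id", "feature_kind", "gene_id", "read_count", "length", "rpkm"],
    )


def intron_exon_scatter(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Pair per-feature RPKM between two conditions.

    Returns the paired table plus the per-kind median B/A ratio
    (computed on features expressed in both conditions), the summary
    behind the intron-versus-exon up-regulation readout.
    """
    merged = expr_a.merge(
        expr_b[["feature_id", "read_count", "rpkm"]],
        on="feature_id", suffixes=("_a", "_b"),
    )
    expressed = merged[(merged["rpkm_a"] > 0) & (merged["rpkm_b"] > 0)]
    medians = (
        expressed.groupby("feature_kind")
        .apply(lambda g: float(np.median(g["rpkm_b"] / g["rpkm_a"])), include_groups=False)
        if len(expressed)
        else pd.Series(dtype=float)
    )
    return merged, medians


def ir_proportion(
    intron_rpkm_value: float, flanking_exon_rpkm_value: float, intron_id: str = ""
) -> IRProportion:
    """Retained-intron expression as a fraction of its flanking exons'.

    Undefined (flagged) when the flanking exons are silent.
    """
    if flanking_exon_rpkm_value <= 0:
        return IRProportion(intron_id, intron_rpkm_value, flanking_exon_rpkm_value,
                            float("nan"), defined=False)
    return IRProportion(
        intron_id, intron_rpkm_value, flanking_exon_rpkm_value,
        intron_rpkm_value / flanking_exon_rpkm_value, defined=True,
    )


def flanking_exon_rpkm(
    expr: pd.DataFrame, gene_id: str, intron_index: int, total_mapped: int
) -> float:
    """Combined RPKM of the two exons flanking intron ``intron_index``
    (combined read count over combined length)."""
    ids = [f"{gene_id}.exon{intron_index}", f"{gene_id}.exon{intron_index + 1}"]
    sub = expr[expr["feature_id"].isin(ids)]
    if len(sub) != 2:
        raise KeyError(f"flanking exons of {gene_id} intron {intron_index} not found")
    return rpkm(float(sub["read_count"].sum()), int(sub["length"].sum()), total_mapped)


def functional_expression(total: float, retained_intron: float) -> tuple[float, bool]:
    """Functional-transcript signal: total minus the retained-intron
    contribution, floored at zero (the flag marks flooring)."""
    if retained_intron < 0 or total < 0:
        raise ValueError("expression levels must be non-negative")
    functional = total - retained_intron
    if functional < 0:
        return 0.0, True
    return functional, False


# ---------------------------------------------------------------------------
# QC: saturation and coverage uniformity
# ---------------------------------------------------------------------------

def saturation_curve(
    alignments: Sequence[SplicedAlignment],
    annotation: Sequence[GeneModel],
    steps: Sequence[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Genes detected (>= 1 overlapping read) as reads accumulate.

    A single random permutation of the library is prefix-sampled at each
    step, so the curve is monotone non-decreasing by construction and
    deterministic under the seed.
    """
    index = FeatureIndex(
        (g.gene_id, g.chrom, g.start, g.end) for g in annotation
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(alignments))
    seen: set[str] = set()
    rows = []
    prev = 0
    for step in sorted(steps):
        step = min(step, len(alignments))
        for i in order[prev:step]:
            aln = alignments[i]
            for fid, _ in index.overlaps(aln.chrom, aln.start, aln.end):
                seen.add(fid)
        prev = step
        rows.append({"reads_sampled": step, "genes_detected": len(seen)})
    return pd.DataFrame(rows, columns=["reads_sampled", "genes_detected"])


def transcript_coverage_profile(
    alignments: Sequence[SplicedAlignment],
    annotation: Sequence[GeneModel],
    n_bins: int = 100,
) -> pd.DataFrame:
    """Median exonic depth per relative transcript position bin.

    Depth along each gene's spliced transcript (5'->3') is averaged
    within ``n_bins`` equal-width bins; the profile reports the median
    over transcripts per bin.  Uniform libraries yield a flat profile.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    depth: dict[str, np.ndarray] = {
        g.gene_id: np.zeros(g.transcript_length, dtype=np.int32) for g in annotation
    }
    offsets: dict[str, list[tuple[int, int, int]]] = {}
    for g in annotation:
        off = 0
        lst = []
        for s, e in g.exons:
            lst.append((s, e, off))
            off += e - s
        offsets[g.gene_id] = lst
    genes = {g.gene_id: g for g in annotation}
    index = FeatureIndex((g.gene_id, g.chrom, g.start, g.end) for g in annotation)

    for aln in alignments:
        hits = index.overlaps(aln.chrom, aln.start, aln.end)
        for gid, _ in hits:
            arr = depth[gid]
            for bs, be in aln.blocks:
                for s, e, off in offsets[gid]:
                    lo, hi = max(bs, s), min(be, e)
                    if lo < hi:
                        arr[off + lo - s : off + hi - s] += 1

    binned = []
    for g in annotation:
        arr = depth[g.gene_id]
        if g.strand == "-":
            arr = arr[::-1]
        edges = np.linspace(0, len(arr), n_bins + 1).astype(int)
        means = [arr[edges[i]: edges[i + 1]].mean() if edges[i + 1] > edges[i] else 0.0
                 for i in range(n_bins)]
        binned.append(means)
    matrix = np.array(binned)
    rows = [
        {"bin": i, "relative_position": (i + 0.5) / n_bins,
         "median_depth": float(np.median(matrix[:, i]))}
        for i in range(n_bins)
    ]
    return pd.DataFrame(rows, columns=["bin", "relative_position", "median_depth"])
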