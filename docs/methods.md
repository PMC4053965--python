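# Methods

## Overview

`splicewatch` analyses pre-mRNA splicing genome-wide from spliced
short-read alignments.  It follows a five-stage design: (1) junction
discovery from gapped alignments, (2) false-positive junction filtering
calibrated against a random-decoy junction null, (3) classification of
alternative-splicing (AS) events and intron-retention (IR) calling,
(4) equal-depth differential testing between conditions with Fisher's
exact test, and (5) splice-site sequence and positional analyses, plus
feature-level expression metrics.  A synthetic-data generator with a
ground-truth ledger stands in for real RNA-seq libraries, so every
detector can be scored by parameter recovery.

The pipeline's inputs begin at spliced alignments: no read aligner is
run.  The generator emits truth alignments directly, which isolates the
statistical behaviour of the downstream stages from aligner artefacts.

## Coordinates and orientation

Coordinates are 0-based half-open internally; GFF3 is written 1-based
closed and SAM 1-based, at the file boundary only.  All splice-site
semantics are transcribed-oriented: the donor (5'SS) is the transcribed
start of an intron, the acceptor (3'SS) its transcribed end, and signed
offsets count transcribed-downstream as positive.  Minus-strand genes
are reverse-complemented before any sequence tally, so a canonical
intron always reads GT...AG in transcript space.

## Junction discovery and the decoy null

Every distinct alignment gap `(chrom, start, end)` is a candidate
intron.  Per junction we record the supporting read count and the
**maximum overhang**: over all supporting reads, the largest value of
each read's shorter gap-adjacent block.  The maximum (rather than the
mean or per-read list) is the aggregate because the filter uses the
overhang as a keep/remove criterion — a junction is trustworthy if at
least one read anchors it deeply on both sides.

False-positive calibration uses two junction reference libraries built
from the annotation: *annotated* references join the donor-side and
acceptor-side transcript flanks of each annotated intron; *random*
(decoy) references join exon flanks from **different chromosomes**,
junctions that should essentially never be real.  For read length L the
flank is `L - 11` nt (90 nt for 101-nt reads, 74 nt for 85-nt reads,
giving 180/148-nt references), which forces any full-length exact
placement to keep at least an 11-nt anchor on both sides of the splice
point.  Reads are matched to references by exact substring placement
with no mismatches; each anchored placement records its overhang (the
shorter side).  Flank sequence is taken from the spliced transcript
context, so exons shorter than the flank borrow from their neighbours
and all references have constant length; transcript ends are N-padded
(N never matches a read base, so padding is conservative).

Matches to random references are false positives by construction.  The
null characterisation tabulates per-origin overhang and coverage
distributions and the survival of each origin under a grid of candidate
thresholds.  The default filter keeps a junction iff its maximum
overhang is **strictly greater than 20 nt** and it has **at least two**
supporting reads.  "More than 20" is read as a strict inequality
(21 kept, 20 removed).  The same rule applies to annotated junctions by
default; a flag (`exempt_annotated`) passes them through unfiltered for
users who want novel-only stringency.

A read matching several references (or placements) is counted for each,
with the multiplicity logged; with no mismatch tolerance this is rare
and affects only the null tabulation.

## Event classification

Novel (unannotated) junctions are classified against the annotated
introns of the gene that contains them:

* **ALT5SS** — shares its acceptor with an annotated intron, donor
  shifted; **ALT3SS** — shares the donor, acceptor shifted.  The
  *dominant* counterpart is the annotated intron sharing the conserved
  boundary; when several share it, the one with the highest junction
  read count wins (tie: smallest interval).
* **CASSETTE** — the junction joins the donor of one annotated intron
  to the acceptor of a downstream annotated intron, skipping exactly
  one exon; **COORD_CASSETTE** skips two or more consecutive exons.
* **MUTEX** — two single-exon cassettes over adjacent exons whose
  shared intron has no junction support.  Junction reads cannot phase
  distant exons, so absence of support for the only junction that would
  co-include both exons is the strongest junction-level evidence of
  mutual exclusivity available; when the shared intron does have reads
  the pair stays two cassettes.
* **ALT_FIRST / ALT_LAST** — the novel boundary lies beyond the
  annotated terminal exon.

One junction yields at most one junction-based event.  Junctions
overlapping no gene are reported intergenic; in-gene junctions matching
no rule are reported unclassified — both excluded from event tables but
never silently dropped.

**Intron retention** is called from unspliced coverage: an annotated
intron is retained when at least **5 reads** (each with ≥1 aligned base
inside the intron and no gap equal to the intron) cover at least
**50%** of the intron's bases at ≥1×.  Coverage is the union of
covered bases, not per-base depth; the per-base-depth reading of the
rule was rejected as overly strict for ~100-nt toy introns.  Reads
spanning an exon/intron boundary count as retention evidence.  The call
is monotone: adding unspliced reads can never un-call an intron.

**Frame impact** takes the net coding-length change explicitly (site
shifts reported by other tools are convention-dependent): a multiple of
3 without an internal stop is an in-frame indel of `|Δ|/3` codons, any
other shift is a frameshift generating a premature termination codon
(PTC), and retained introns are scanned for in-frame stops at the
supplied codon phase.  Stops straddling the intron boundary are not
scanned — a known limitation.

## Differential testing

Libraries are equalised by uniform resampling of alignment records
without replacement (deterministic under a seed; drawing the full
library returns it unchanged).  Each matched event is tested with a
**two-sided Fisher's exact test** on the 2×2 table of focal reads
versus *flanking-exon* reads across the two conditions.  The
denominator is the distinct reads over the two exons delimiting the
tested splicing choice (the dominant intron's flanks for alternative
sites, the joined exons for skipping, the retained intron's flanks for
IR) — gene-level counts would dilute the local splicing signal, but the
choice is exposed as a switch.  Thresholds: p < 0.01 for junction-based
events, p < 0.001 for intron retention.

The **unique-event rule**: an event observed in only one condition is
significant when it has at least five supporting reads (five unspliced
reads for IR); its p-value is reported as 0 with an `assigned_zero`
flag, never merged silently with computed p-values.

`fisher_2x2` computes the two-sided p as the hypergeometric tail sum of
all tables no more probable than the observed one.  Tables with total
≤ 2000 use exact integer arithmetic (`math.comb`), making tie inclusion
unambiguous; larger tables use log-space summation with a 1e-7 relative
tie tolerance (the convention of standard implementations).  A zero
margin yields p = 1 with a warning.  No multiple-testing correction is
applied to the headline calls; a Benjamini–Hochberg column is emitted
for users.

The global comparison tallies junction reads per event type and tests
them against the uniquely mapped totals of each library; the rescue
profile normalises per-event junction coverage by each library's mapped
total (reads per million), supporting the readout where events elevated
in a perturbed condition return to baseline in a rescue condition.

## Splice-site analyses

Position frequency matrices are tallied in a signed ±window frame with
no position zero: donor matrices anchor the first two intron bases at
+1/+2 (GT), acceptor matrices the last two at −2/−1 (AG).  Offsets of
alternative sites from their dominant sites are signed transcribed-
downstream-positive, histogrammed over ±50 nt with the ±10 nt mass
reported separately (±50 is a plotting window choice; the biology of
interest sits within ~10 nt).  The skipping/alternative-site
coordination test builds the 2×2 table of (skipped vs not) × (has
alternative SS vs not) over all annotated exons, counted per exon, and
applies the same Fisher test.

## Expression metrics

RPKM = reads / (feature length / 1000) / (mapped total / 1e6).  Exon
counts assign each read fractionally by overlap length so no aligned
base is counted twice; intron counts include only unspliced reads
(junction reads gapped over an intron are exon evidence, consistent
with the IR caller).  The IR proportion is intron RPKM over the
combined RPKM of the two flanking exons (combined counts over combined
length); at a planted per-transcript retention fraction π the estimator
converges to π because intron and exon coverage share the same
transcription rate.  Functional-transcript expression is the flanking-
exon total minus the retained-intron contribution, floored at zero with
a flag.  QC: a seeded saturation curve (prefix-sampling one permutation,
hence monotone by construction) and a median per-bin transcript
coverage profile.

## The synthetic generator

The generator emulates the kind of study the pipeline was designed for:
a compact two-chromosome plant-style genome (default 200 genes, 4–6
exons each, alternating strands, round-robin chromosome assignment),
single-end fixed-length libraries (101 nt; 85 nt supported, any ≥30
accepted), one wild-type condition splicing exactly as annotated, and
perturbed conditions with planted events:

* intron retention at a per-intron transcript fraction of **0.15**
  (the scale of retention the pipeline is expected to quantify);
* alternative 5'/3' splice sites offset uniformly by ±2..10 nt from the
  dominant sites, at 0.3 usage;
* skipping of targeted internal exons at 0.3 usage, with a configurable
  subset of skip genes also carrying an alternative site on the skipped
  exon (planted skip/alt-SS coordination);
* 100 decoy reads drawn as exact substrings of cross-chromosome random
  junction references, placed with overhangs of 11–15 nt and singleton
  support — the false-positive population the filter must remove.

Terminal exons are drawn longer (200–280 nt) than internal ones
(80–140 nt), mimicking UTR-bearing first/last exons; planted IR and
alternative sites target interior introns so recovery statistics are
measured in the flat part of the coverage profile rather than in the
end ramps that any finite-transcript uniform-fragmentation model
produces.  Introns are 60–120 nt and never below 20 nt, keeping the
50%-coverage IR rule meaningful.  Reads are uniform windows on isoforms
chosen proportionally to mixture weight × legal start positions
(uniform fragmentation); substitution errors (default 0.001/base) are
applied to the raw FASTQ sequences only and never move alignment
coordinates.  Mixture weights equal planted usage fractions, the
annotated isoform absorbing the remainder, and every planted deviation
is written to a ledger keyed by genome coordinates.

Reference problem sizes: 200 genes / 50 000 reads per library (~30×
exon coverage) for the end-to-end study, and a dedicated 100-gene /
55 000-read study (~65×) for retention parameter recovery, where the
per-intron evidence comfortably clears the 5-read rule.

### What the generator does not model

Sequencing quality variation (qualities are constant), paired ends, PCR
duplicates, indels, aligner errors and multi-mapping, overlapping
genes, multi-isoform annotation, expression heterogeneity between
genes, and background (unplanted) intron retention or noisy splicing.
Consequently, passing tests demonstrate the correctness and calibration
of the statistical machinery on clean truth alignments — they do not
certify performance on real libraries, where alignment artefacts and
biological background will add false-positive pressure that the decoy
filter only partially emulates.  The null-versus-null comparisons are
correspondingly clean: wild-type libraries carry no unspliced intron
reads at all, so IR null calibration is exercised by comparing two
resamples of the same retention-carrying library.

## Numerical and design choices

* Junction identity is `(chrom, start, end)`; strand is an attribute
  (reads are unstranded), inferred from the overlapping gene, then from
  GT/AG orientation, else unknown.
* The simulator emits SAM sequences in genome-forward orientation and
  FASTQ in transcript sense.
* Resampling indices are sorted, so a full-size resample is the
  identity permutation and subsets preserve library order.
* The single global seed fans out to stage seeds via
  `numpy.random.SeedSequence`, all below 2^31; reruns are byte-identical
  (the manifest's config echo omits the output path so manifests are
  location-independent).
* Direction of a differential result compares focal/denominator ratios;
  with a zero denominator the focal presence decides.
* Alternative sites planted by the generator do not carry their own
  GT/AG dinucleotides; splice-site purity statements concern the
  annotated (dominant) junctions.

## Known limitations

MUTEX and ALT_FIRST/ALT_LAST calls rest on weaker geometric heuristics
than the other classes and are not planted by the default generator
profiles; frame-impact scanning ignores codons straddling the retained
intron's boundaries; the coordination background is counted per exon
(per-site counting would roughly double the universe); and the flanking-
exon denominator, while localized, shares reads with the focal junction
count, making the Fisher test slightly conservative.
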