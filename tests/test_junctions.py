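"""Junction extraction, reference building, matching and filtering."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

from splicewatch import junctions as jx
from splicewatch.model import GeneModel, RawRead, SizingError, SplicedAlignment


class TestExtractJunctions:
    def test_single_gapped_read_records_min_side_overhang(self):
        aln = SplicedAlignment("r1", "chr1", ((100, 140), (200, 261)))
        (j,) = jx.extract_junctions([aln])
        assert (j.start, j.end) == (140, 200)
        assert j.read_count == 1
        assert j.max_overhang == min(40, 61) == 40

    def test_overhang_aggregates_as_the_maximum_over_reads(self):
        alns = [
            SplicedAlignment("r1", "chr1", ((125, 140), (200, 286))),  # min side 15
            SplicedAlignment("r2", "chr1", ((110, 140), (200, 271))),  # min side 30
        ]
        (j,) = jx.extract_junctions(alns)
        assert j.read_count == 2
        assert j.max_overhang == 30

    def test_gap_equal_to_an_annotated_intron_is_flagged(self):
        gene = GeneModel("g", "chr1", "+", ((100, 140), (200, 300)))
        aln = SplicedAlignment("r1", "chr1", ((120, 140), (200, 220)))
        (j,) = jx.extract_junctions([aln], [gene])
        assert j.annotated and j.strand == "+"

    def test_strand_falls_back_to_gtag_orientation(self):
        genome = {"chr1": "A" * 140 + "GT" + "A" * 56 + "AG" + "A" * 100}
        aln = SplicedAlignment("r1", "chr1", ((100, 140), (200, 240)))
        (j,) = jx.extract_junctions([aln], genome=genome)
        assert j.strand == "+"


class TestJunctionRefs:
    def test_annotated_refs_are_twice_the_flank_long(self, toy):
        refs = jx.build_junction_refs(toy.genome, toy.annotation, flank=90)
        assert refs
        assert all(len(r.sequence) == 180 for r in refs)

    def test_default_flank_is_read_length_minus_eleven(self):
        assert jx.default_flank(101) == 90
        assert jx.default_flank(85) == 74

    def test_three_exon_gene_yields_two_refs(self, toy):
        gene = next(g for g in toy.annotation if g.n_exons == 4)
        refs = jx.build_junction_refs(toy.genome, [gene], flank=90)
        assert len(refs) == gene.n_exons - 1

    def test_annotated_ref_matches_the_spliced_transcript(self, toy):
        gene = toy.annotation[0]
        (ref, *_) = jx.build_junction_refs(toy.genome, [gene], flank=90)
        transcript = gene.transcript_sequence(toy.genome)
        assert ref.sequence in transcript

    def test_random_refs_join_different_chromosomes(self, toy):
        refs = jx.build_junction_refs(
            toy.genome, toy.annotation, flank=90, mode="random", n_random=50, seed=4
        )
        assert len(refs) == 50
        assert all(r.donor_locus[0] != r.acceptor_locus[0] for r in refs)

    def test_oversized_random_request_raises(self):
        genome = {"chr1": "ACGT" * 300, "chr2": "ACGT" * 300}
        annotation = [
            GeneModel("a", "chr1", "+", ((0, 100), (150, 250))),
            GeneModel("b", "chr2", "+", ((0, 100), (150, 250))),
        ]
        with pytest.raises(SizingError):
            jx.build_junction_refs(
                genome, annotation, flank=50, mode="random", n_random=10_000, seed=0
            )


def brute_force_matches(reads, refs, min_anchor=11):
    """Independent oracle: scan every read against every ref at every offset."""
    out = []
    for read in reads:
        L = len(read.sequence)
        for ref in refs:
            mid = len(ref.sequence) // 2
            for off in range(len(ref.sequence) - L + 1):
                if ref.sequence[off : off + L] != read.sequence:
                    continue
                left, right = mid - off, off + L - mid
                if left >= min_anchor and right >= min_anchor:
                    out.append((read.read_id, ref.ref_id, off, min(left, right)))
    return sorted(out)


@pytest.fixture(scope="module")
def refs(toy):
    return jx.build_junction_refs(toy.genome, toy.annotation, flank=90)[:20]


class TestMatcher:
    def test_placement_arithmetic_of_a_centered_match(self, refs):
        ref = refs[0]
        read = RawRead("q", ref.sequence[25 : 25 + 101])  # 65 left, 36 right of midpoint
        (rec,) = [r for r in jx.match_reads_to_refs([read], [ref]) if r.ref_id == ref.ref_id]
        assert rec.offset == 25
        assert rec.overhang == 36

    def test_one_substitution_kills_the_match(self, refs):
        ref = refs[0]
        seq = list(ref.sequence[25 : 25 + 101])
        seq[50] = "A" if seq[50] != "A" else "C"
        assert not jx.match_reads_to_refs([RawRead("q", "".join(seq))], [ref])

    def test_ten_nt_anchor_is_rejected(self, refs):
        ref = refs[0]
        read = RawRead("q", ref.sequence[:101])  # 90 left / 11 right -> accepted
        ok = jx.match_reads_to_refs([read], [ref], min_anchor=11)
        assert any(r.overhang == 11 for r in ok)
        # a 100-nt read starting at offset 0 leaves only 10 nt on the right
        short = RawRead("q2", ref.sequence[0:100])
        assert not jx.match_reads_to_refs([short], [ref], min_anchor=11)

    def test_matcher_equals_brute_force_scan(self, toy, refs):
        rng = np.random.default_rng(2)
        reads = []
        for i, ref in enumerate(refs):
            off = int(rng.integers(0, 80))
            reads.append(RawRead(f"true{i}", ref.sequence[off : off + 101]))
        for i in range(20):  # random sequence: should never match
            reads.append(
                RawRead(f"rand{i}", "".join(rng.choice(list("ACGT"), size=101)))
            )
        for i in range(10):  # mutated copies
            seq = list(refs[i].sequence[10:111])
            seq[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[40]]
            reads.append(RawRead(f"mut{i}", "".join(seq)))
        got = sorted(
            (r.read_id, r.ref_id, r.offset, r.overhang)
            for r in jx.match_reads_to_refs(reads, refs)
        )
        assert got == brute_force_matches(reads, refs)


class TestFilter:
    @pytest.mark.parametrize(
        "overhang,reads,kept",
        [
            (15, 10, False),  # short overhang removed regardless of depth
            (30, 1, False),   # singleton removed regardless of overhang
            (21, 2, True),    # boundary of both rules is kept
            (20, 2, False),   # "more than 20" is strict
        ],
    )
    def test_threshold_boundaries(self, overhang, reads, kept):
        j = jx.Junction("chr1", 0, 100, read_count=reads, max_overhang=overhang)
        assert bool(jx.apply_filter([j])) is kept

    @settings(derandomize=True, max_examples=100)
    @given(
        hs.lists(
            hs.tuples(hs.integers(1, 90), hs.integers(1, 50)), max_size=30
        )
    )
    def test_filter_is_idempotent_and_conservative(self, raw):
        catalog = [
            jx.Junction("chr1", 10 * i, 10 * i + 5, read_count=r, max_overhang=o)
            for i, (o, r) in enumerate(raw)
        ]
        once = jx.apply_filter(catalog)
        assert jx.apply_filter(once) == once
        assert all(j in catalog for j in once)

    def test_annotated_exemption_flag(self):
        j = jx.Junction("chr1", 0, 100, read_count=1, max_overhang=5, annotated=True)
        assert not jx.apply_filter([j])
        assert jx.apply_filter([j], jx.FilterConfig(exempt_annotated=True)) == [j]


@pytest.fixture(scope="module")
def report(toy):
    from splicewatch.synth import make_decoy_reads

    refs_a = jx.build_junction_refs(toy.genome, toy.annotation, flank=90)
    decoy_reads, refs_r = make_decoy_reads(
        toy.genome, toy.annotation, toy.config, np.random.default_rng(13)
    )
    reads = list(toy.wt_reads) + list(decoy_reads)
    return jx.characterize_null(
        jx.match_reads_to_refs(reads, refs_r),
        jx.match_reads_to_refs(reads, refs_a),
        refs_r, refs_a,
    )


class TestNullCharacterisation:
    def test_planted_decoys_do_not_survive_the_study_thresholds(self, report):
        row = report.survival.query(
            "origin == 'random' and min_overhang_exclusive == 20 and min_reads == 2"
        )
        assert row["survival"].item() == 0.0

    def test_annotated_junctions_survive_the_same_thresholds(self, report):
        row = report.survival.query(
            "origin == 'annotated' and min_overhang_exclusive == 20 and min_reads == 2"
        )
        assert row["survival"].item() >= 0.95

    def test_no_op_thresholds_keep_everything(self, report):
        rows = report.survival.query("min_overhang_exclusive == 0 and min_reads == 1")
        assert (rows["survival"] == 1.0).all()

    def test_empty_null_is_reported_not_fatal(self, toy):
        refs_a = jx.build_junction_refs(toy.genome, toy.annotation, flank=90)[:5]
        refs_r = jx.build_junction_refs(
            toy.genome, toy.annotation, flank=90, mode="random", n_random=5, seed=1
        )
        records_a = jx.match_reads_to_refs(toy.wt_reads[:500], refs_a)
        report = jx.characterize_null([], records_a, refs_r, refs_a)
        assert "null not exercised" in report.note
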