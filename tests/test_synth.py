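"""The generator's contracts: determinism, planted truths, ledger fidelity."""
import numpy as np
import pytest

from splicewatch import io as swio
from splicewatch import synth
from splicewatch.model import PlacementError, revcomp
from splicewatch.synth import (
    ALT3SS,
    ALT5SS,
    CASSETTE,
    IR,
    ConditionProfile,
    PlantedEvent,
    SimConfig,
)


def _small_cfg(**kw):
    base = dict(n_genes=12, library_depth=2000, seed=11)
    base.update(kw)
    return SimConfig(**base)


class TestGenomeAndAnnotation:
    def test_same_seed_gives_byte_identical_fasta_and_gff(self, tmp_path):
        cfg = _small_cfg()
        for run in ("a", "b"):
            genome, annotation = synth.make_genome_and_annotation(cfg)
            swio.write_fasta(genome, tmp_path / f"{run}.fa")
            swio.write_gff3(annotation, tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_gene_count_and_exon_range_follow_the_config(self):
        cfg = _small_cfg(n_genes=10, exons_per_gene=(3, 5))
        _, annotation = synth.make_genome_and_annotation(cfg)
        assert len(annotation) == 10
        assert all(3 <= g.n_exons <= 5 for g in annotation)

    def test_every_intron_is_canonical_on_the_transcribed_strand(self):
        genome, annotation = synth.make_genome_and_annotation(_small_cfg())
        assert {g.strand for g in annotation} == {"+", "-"}
        for gene in annotation:
            for s, e in gene.introns:
                seq = genome[gene.chrom][s:e]
                if gene.strand == "-":
                    seq = revcomp(seq)
                assert seq[:2] == "GT" and seq[-2:] == "AG"

    def test_exons_lie_within_their_chromosome(self):
        genome, annotation = synth.make_genome_and_annotation(_small_cfg())
        for gene in annotation:
            assert 0 <= gene.start and gene.end <= len(genome[gene.chrom])

    def test_infeasible_geometry_raises_sizing_error(self):
        with pytest.raises(Exception, match="max_chromosome_len"):
            synth.make_genome_and_annotation(_small_cfg(max_chromosome_len=500))


@pytest.fixture(scope="module")
def setup():
    cfg = _small_cfg()
    genome, annotation = synth.make_genome_and_annotation(cfg)
    return cfg, genome, annotation


class TestIsoformPools:
    def test_planted_retention_fraction_recovers_binomially(self, setup):
        cfg, _, annotation = setup
        gene = next(g for g in annotation if g.n_exons >= 4)
        profile = ConditionProfile(
            "mut", (PlantedEvent(IR, gene.gene_id, 1, usage=0.15),)
        )
        pool, _ = synth.simulate_isoforms(annotation, cfg, profile)
        draws = synth.sample_isoforms(
            [iso for iso in pool if iso.gene_id == gene.gene_id],
            10_000, np.random.default_rng(0),
        )
        retained = sum(1 for iso in draws if iso.event is not None)
        sd = (10_000 * 0.15 * 0.85) ** 0.5
        assert abs(retained - 1500) <= 3 * sd

    def test_alt3_offset_moves_the_acceptor_downstream(self, setup):
        cfg, _, annotation = setup
        gene = next(g for g in annotation if g.strand == "+" and g.n_exons >= 4)
        istart, iend = gene.introns[1]
        profile = ConditionProfile(
            "mut", (PlantedEvent(ALT3SS, gene.gene_id, 1, offset=8, usage=0.3),)
        )
        pool, ledger = synth.simulate_isoforms(annotation, cfg, profile)
        iso = next(i for i in pool if i.event is not None)
        # acceptor-side exon starts 8 nt downstream of the annotated acceptor
        assert iso.exons[2][0] == iend + 8
        assert (ledger.entries[0].start, ledger.entries[0].end) == (istart, iend + 8)

    def test_empty_profile_yields_only_annotated_isoforms(self, setup):
        cfg, _, annotation = setup
        pool, ledger = synth.simulate_isoforms(annotation, cfg, ConditionProfile("wt"))
        assert len(pool) == len(annotation)
        assert all(iso.event is None for iso in pool)
        assert all(iso.exons == g.exons for iso, g in zip(pool, annotation))
        assert not ledger.entries

    def test_out_of_bounds_offset_is_a_placement_error(self, setup):
        cfg, _, annotation = setup
        gene = annotation[0]
        profile = ConditionProfile(
            "mut", (PlantedEvent(ALT5SS, gene.gene_id, 0, offset=10_000, usage=0.1),)
        )
        with pytest.raises(PlacementError):
            synth.simulate_isoforms(annotation, cfg, profile)

    def test_skipping_a_terminal_exon_is_rejected(self, setup):
        cfg, _, annotation = setup
        profile = ConditionProfile(
            "mut", (PlantedEvent(CASSETTE, annotation[0].gene_id, 0, usage=0.1),)
        )
        with pytest.raises(PlacementError):
            synth.simulate_isoforms(annotation, cfg, profile)


class TestReads:
    def test_sam_output_is_deterministic_under_the_seed(self, tmp_path):
        cfg = _small_cfg()
        genome, annotation = synth.make_genome_and_annotation(cfg)
        pool, _ = synth.simulate_isoforms(annotation, cfg, ConditionProfile("wt"))
        for run in ("a", "b"):
            aln, reads = synth.simulate_reads(
                genome, pool, cfg, np.random.default_rng(42), "lib"
            )
            chrom_lengths = {c: len(s) for c, s in genome.items()}
            swio.write_sam(aln, chrom_lengths, tmp_path / f"{run}.sam")
            swio.write_fastq(reads, tmp_path / f"{run}.fastq")
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_reads_are_exact_transcript_windows_with_truth_blocks(self, toy):
        # error-free check on a zero-error config
        cfg = _small_cfg(error_rate=0.0)
        genome, annotation = synth.make_genome_and_annotation(cfg)
        pool, _ = synth.simulate_isoforms(annotation, cfg, ConditionProfile("wt"))
        aln, reads = synth.simulate_reads(
            genome, pool, cfg, np.random.default_rng(1), "lib"
        )
        for a, r in zip(aln[:200], reads[:200]):
            assert sum(e - s for s, e in a.blocks) == cfg.read_length
            genome_seq = "".join(genome[a.chrom][s:e] for s, e in a.blocks)
            expected = genome_seq if a.strand == "+" else revcomp(genome_seq)
            assert r.sequence == expected

    def test_ledger_accounts_for_every_novel_junction_in_truth_alignments(self, toy):
        annotated = {
            (g.chrom, s, e) for g in toy.annotation for s, e in g.introns
        }
        planted = {
            (e.chrom, e.start, e.end)
            for e in toy.ledger.entries
            if e.event_type != IR
        }
        observed = {
            (a.chrom, gs, ge) for a in toy.mut_alignments for gs, ge in a.gaps
        }
        novel = observed - annotated
        assert novel  # the perturbed library does produce novel junctions
        assert novel <= planted


@pytest.fixture(scope="module")
def decoys():
    cfg = _small_cfg(decoy_read_count=100)
    genome, annotation = synth.make_genome_and_annotation(cfg)
    reads, refs = synth.make_decoy_reads(
        genome, annotation, cfg, np.random.default_rng(9)
    )
    return cfg, reads, refs


class TestDecoys:
    def test_requested_count_and_cross_chromosome_junctions(self, decoys):
        _, reads, refs = decoys
        assert len(reads) == 100
        assert all(r.donor_locus[0] != r.acceptor_locus[0] for r in refs)

    def test_singleton_mode_supports_each_junction_once(self, decoys):
        cfg, reads, refs = decoys
        from splicewatch.junctions import match_reads_to_refs, summarize_support

        support = summarize_support(refs, match_reads_to_refs(reads, refs))
        assert all(s.read_count == 1 for s in support)

    def test_overhang_cap_is_respected(self, decoys):
        cfg, reads, refs = decoys
        from splicewatch.junctions import match_reads_to_refs

        records = match_reads_to_refs(reads, refs)
        assert records
        assert max(r.overhang for r in records) <= cfg.decoy_overhang_max
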