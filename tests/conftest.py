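"""Shared fixtures: a small simulated study and the full reference run."""
from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from splicewatch import pipeline, synth
from splicewatch import junctions as jx


@pytest.fixture(scope="session")
def toy():
    """A 30-gene study with planted events: enough signal for module-level
    checks while staying fast."""
    cfg = synth.SimConfig(n_genes=30, library_depth=8000, seed=3)
    genome, annotation = synth.make_genome_and_annotation(cfg)
    profile = synth.build_condition_profile(
        annotation, cfg, "mut",
        synth.ProfileSpec(n_ir=5, n_alt5=5, n_alt3=5, n_skip=3, n_coordinated=1),
        np.random.default_rng(5),
    )
    pool, ledger = synth.simulate_isoforms(annotation, cfg, profile)
    mut_aln, mut_reads = synth.simulate_reads(
        genome, pool, cfg, np.random.default_rng(6), "mut"
    )
    wt_pool, _ = synth.simulate_isoforms(
        annotation, cfg, synth.ConditionProfile("wt")
    )
    wt_aln, wt_reads = synth.simulate_reads(
        genome, wt_pool, cfg, np.random.default_rng(8), "wt"
    )
    return SimpleNamespace(
        config=cfg,
        genome=genome,
        annotation=annotation,
        profile=profile,
        pool=pool,
        ledger=ledger,
        mut_alignments=mut_aln,
        mut_reads=mut_reads,
        wt_alignments=wt_aln,
        wt_reads=wt_reads,
    )


@pytest.fixture(scope="session")
def toy_catalog(toy):
    """Filtered junction catalog of the perturbed toy library."""
    catalog = jx.extract_junctions(toy.mut_alignments, toy.annotation, toy.genome)
    return catalog, jx.apply_filter(catalog)


@pytest.fixture(scope="session")
def reference_run(tmp_path_factory):
    """One full end-to-end run of the reference synthetic study."""
    outdir = tmp_path_factory.mktemp("reference_run")
    config = pipeline.default_run_config(outdir, seed=7)
    manifest = pipeline.run_all(config)
    return SimpleNamespace(config=config, manifest=manifest, outdir=outdir)
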