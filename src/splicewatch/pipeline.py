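"""End-to-end orchestration: simulate -> junctions -> events -> diff -> sites -> expr.

A run is driven by one :class:`RunConfig` (YAML-loadable) and a single
global seed that fans out to per-stage seeds by a fixed derivation, so
every stage is independently rerunnable and two runs with the same
config produce byte-identical outputs.  Every stage writes TSV artifacts
into the output directory and the run ends with a JSON manifest listing
row counts and checksums.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from . import events as ev
from . import expression as expr
from . import io as swio
from . import junctions as jx
from . import sites as st
from . import synth
from .model import GeneModel, SplicedAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    outdir: str
    seed: int = 1
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    conditions: dict[str, synth.ProfileSpec] = field(default_factory=dict)
    contrast: tuple[str, str] = ("wildtype", "mutant")
    filter_cfg: jx.FilterConfig = field(default_factory=jx.FilterConfig)
    ir_cfg: ev.IRConfig = field(default_factory=ev.IRConfig)
    resample_n: int | None = None
    alpha_as: float = 0.01
    alpha_ir: float = 0.001

    def validate(self) -> None:
        if not self.conditions:
            raise ValueError("config field 'conditions' must name at least two libraries")
        for name in self.contrast:
            if name not in self.conditions:
                raise ValueError(f"config field 'contrast' references unknown condition {name!r}")
        n = self.resample_n or self.sim.library_depth
        if n > self.sim.library_depth:
            raise ValueError("config field 'resample_n' exceeds library_depth")


def default_run_config(outdir: str | os.PathLike, seed: int = 1) -> RunConfig:
    """The reference synthetic study: a wild-type library, a perturbed
    library with planted intron retention / alternative splice sites /
    exon skipping, and a rescue library splicing like wild type."""
    seeds = derive_seeds(seed, 1)
    return RunConfig(
        outdir=str(outdir),
        seed=seed,
        sim=replace(synth.SimConfig(), seed=seeds[0]),
        conditions={
            "wildtype": synth.ProfileSpec(),
            "mutant": synth.ProfileSpec(
                n_ir=50, n_alt5=20, n_alt3=20, n_skip=10, n_coordinated=2
            ),
            "rescue": synth.ProfileSpec(),
        },
    )


def config_from_dict(raw: Mapping, outdir: str | None = None) -> RunConfig:
    cfg = default_run_config(outdir or raw.get("outdir", "splicewatch_run"),
                             seed=int(raw.get("seed", 1)))
    sim = cfg.sim
    if "sim" in raw:
        fields = {f.name for f in dataclasses.fields(synth.SimConfig)}
        overrides = {}
        for k, v in raw["sim"].items():
            if k not in fields:
                raise ValueError(f"unknown sim field {k!r}")
            overrides[k] = tuple(v) if isinstance(v, list) else v
        sim = replace(sim, **overrides)
    conditions = cfg.conditions
    if "conditions" in raw:
        conditions = {
            name: synth.ProfileSpec(**(spec or {}))
            for name, spec in raw["conditions"].items()
        }
    return replace(
        cfg,
        sim=sim,
        conditions=conditions,
        contrast=tuple(raw.get("contrast", cfg.contrast)),
        filter_cfg=jx.FilterConfig(**raw.get("filter", {})) if "filter" in raw else cfg.filter_cfg,
        ir_cfg=ev.IRConfig(**raw.get("ir", {})) if "ir" in raw else cfg.ir_cfg,
        resample_n=raw.get("resample_n", cfg.resample_n),
        alpha_as=float(raw.get("alpha_as", cfg.alpha_as)),
        alpha_ir=float(raw.get("alpha_ir", cfg.alpha_ir)),
    )


def config_from_yaml(path: str | os.PathLike, outdir: str | None = None) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {}, outdir=outdir)


def derive_seeds(seed: int, n: int) -> list[int]:
    """Fixed fan-out of the global seed into per-stage seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


# ---------------------------------------------------------------------------
# Count assembly for differential testing
# ---------------------------------------------------------------------------

def _exon_boundary_maps(gene: GeneModel):
    ends = {e: i for i, (_, e) in enumerate(gene.exons)}
    starts = {s: i for i, (s, _) in enumerate(gene.exons)}
    return ends, starts


def event_flanking_exons(event: ev.ASEvent, gene: GeneModel) -> list[tuple[int, int]]:
    """The two annotated exons delimiting the tested splicing choice:
    the flanks of the dominant intron for alternative-SS events, the
    joined exons for skipping events."""
    ends, starts = _exon_boundary_maps(gene)
    if event.event_type in ("ALT5SS", "ALT3SS", "ALT_FIRST", "ALT_LAST"):
        assert event.dominant is not None
        left = gene.exons[ends[event.dominant[0]]]
        right = gene.exons[starts[event.dominant[1]]]
    else:
        left = gene.exons[ends[event.junction[0]]]
        right = gene.exons[starts[event.junction[1]]]
    return [left, right]


def assemble_event_counts(
    catalog_a: ev.EventCatalog,
    catalog_b: ev.EventCatalog,
    annotation: Sequence[GeneModel],
    alignments_a: Sequence[SplicedAlignment],
    alignments_b: Sequence[SplicedAlignment],
) -> tuple[list[diff.EventCounts], dict[str, ev.ASEvent]]:
    """Match events across two conditions and attach flanking-exon reads.

    The union of both catalogs is keyed by (chrom, junction, type); the
    focal count in a condition is the junction read count observed
    there (0 when absent), the denominator the distinct reads over the
    two flanking exons.
    """
    gene_map = {g.gene_id: g for g in annotation}
    union: dict[tuple, ev.ASEvent] = {}
    counts_a: dict[tuple, int] = {}
    counts_b: dict[tuple, int] = {}
    for cat, counts in ((catalog_a, counts_a), (catalog_b, counts_b)):
        for event in cat.events:
            union.setdefault(event.key, event)
            counts[event.key] = event.read_count

    exon_ids: dict[tuple[str, int, int], str] = {}
    for event in union.values():
        gene = gene_map[event.gene_id]
        for s, e in event_flanking_exons(event, gene):
            exon_ids.setdefault((event.chrom, s, e), f"{event.chrom}:{s}-{e}")
    index = expr.FeatureIndex(
        (fid, chrom, s, e) for (chrom, s, e), fid in exon_ids.items()
    )
    exon_counts_a = expr.feature_read_counts(alignments_a, index, fractional=False)
    exon_counts_b = expr.feature_read_counts(alignments_b, index, fractional=False)

    out: list[diff.EventCounts] = []
    ids: dict[str, ev.ASEvent] = {}
    for key in sorted(union):
        event = union[key]
        gene = gene_map[event.gene_id]
        fids = [
            exon_ids[(event.chrom, s, e)]
            for s, e in event_flanking_exons(event, gene)
        ]
        event_id = f"{event.event_type}:{event.chrom}:{event.junction[0]}-{event.junction[1]}"
        ids[event_id] = event
        out.append(
            diff.EventCounts(
                event_id=event_id,
                alt_a=counts_a.get(key, 0),
                exon_a=int(sum(exon_counts_a.get(f, 0) for f in fids)),
                alt_b=counts_b.get(key, 0),
                exon_b=int(sum(exon_counts_b.get(f, 0) for f in fids)),
            )
        )
    return out, ids


def assemble_intron_counts(
    calls_a: Sequence[ev.IntronRetentionCall],
    calls_b: Sequence[ev.IntronRetentionCall],
    annotation: Sequence[GeneModel],
    alignments_a: Sequence[SplicedAlignment],
    alignments_b: Sequence[SplicedAlignment],
    called_only: bool = True,
) -> list[diff.EventCounts]:
    """Per-intron counts (unspliced intron reads vs flanking-exon reads)
    for introns called retained in at least one condition."""
    by_key_a = {c.key: c for c in calls_a}
    by_key_b = {c.key: c for c in calls_b}
    keys = sorted(
        k for k in set(by_key_a) | set(by_key_b)
        if not called_only
        or (k in by_key_a and by_key_a[k].called)
        or (k in by_key_b and by_key_b[k].called)
    )
    if not keys:
        return []
    gene_map = {g.gene_id: g for g in annotation}
    exon_ids: dict[tuple[str, int, int], str] = {}
    flanks: dict[tuple, list[str]] = {}
    for key in keys:
        call = by_key_a.get(key) or by_key_b.get(key)
        gene = gene_map[call.gene_id]
        gidx = gene.introns.index(call.intron)
        pair = []
        for s, e in (gene.exons[gidx], gene.exons[gidx + 1]):
            fid = exon_ids.setdefault((gene.chrom, s, e), f"{gene.chrom}:{s}-{e}")
            pair.append(fid)
        flanks[key] = pair
    index = expr.FeatureIndex(
        (fid, chrom, s, e) for (chrom, s, e), fid in exon_ids.items()
    )
    exon_counts_a = expr.feature_read_counts(alignments_a, index, fractional=False)
    exon_counts_b = expr.feature_read_counts(alignments_b, index, fractional=False)
    out = []
    for key in keys:
        chrom, s, e = key
        out.append(
            diff.EventCounts(
                event_id=f"IR:{chrom}:{s}-{e}",
                alt_a=by_key_a[key].n_unspliced_reads if key in by_key_a else 0,
                exon_a=int(sum(exon_counts_a.get(f, 0) for f in flanks[key])),
                alt_b=by_key_b[key].n_unspliced_reads if key in by_key_b else 0,
                exon_b=int(sum(exon_counts_b.get(f, 0) for f in flanks[key])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------

def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and return the manifest.

    Stage failures abort the run with the failing stage named.  Rerunning
    with the same config and seed reproduces every output byte for byte.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": [],
    }
    state: dict = {}
    for name, stage in (
        ("simulate", _stage_simulate),
        ("junctions", _stage_junctions),
        ("nullcal", _stage_nullcal),
        ("events", _stage_events),
        ("diff", _stage_diff),
        ("sites", _stage_sites),
        ("expr", _stage_expr),
    ):
        logger.info("stage %s", name)
        try:
            outputs = stage(config, outdir, state)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"name": name, "outputs": [_describe(outdir / f) for f in outputs]})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _config_echo(config: RunConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw.pop("outdir", None)  # keep the manifest location-independent
    raw["conditions"] = {k: dataclasses.asdict(v) for k, v in config.conditions.items()}
    return json.loads(json.dumps(raw, default=list))


def _describe(path: Path) -> dict:
    data = path.read_bytes()
    rows = None
    if path.suffix in (".tsv", ".sam", ".gff3", ".fastq", ".fa"):
        rows = data.count(b"\n")
    return {
        "path": path.name,
        "bytes": len(data),
        "lines": rows,
        "sha256": hashlib.sha256(data).hexdigest(),
    }


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    seeds = derive_seeds(config.seed, 4 + 2 * len(config.conditions))
    genome, annotation = synth.make_genome_and_annotation(config.sim)
    state["genome"], state["annotation"] = genome, annotation

    outputs = ["genome.fa", "annotation.gff3"]
    swio.write_fasta(genome, outdir / "genome.fa")
    swio.write_gff3(annotation, outdir / "annotation.gff3")

    ledger_frames = []
    state["alignments"] = {}
    state["reads"] = {}
    for i, (name, spec) in enumerate(config.conditions.items()):
        profile_rng = np.random.default_rng(seeds[4 + 2 * i])
        profile = synth.build_condition_profile(
            annotation, config.sim, name, spec, profile_rng
        )
        pool, ledger = synth.simulate_isoforms(annotation, config.sim, profile)
        read_rng = np.random.default_rng(seeds[4 + 2 * i + 1])
        alignments, reads = synth.simulate_reads(
            genome, pool, config.sim, read_rng, library=name
        )
        state["alignments"][name] = alignments
        state["reads"][name] = reads
        ledger_frames.append(ledger.to_frame())
        chrom_lengths = {c: len(genome[c]) for c in genome}
        swio.write_sam(alignments, chrom_lengths, outdir / f"{name}.sam")
        swio.write_fastq(reads, outdir / f"{name}.fastq")
        outputs += [f"{name}.sam", f"{name}.fastq"]
        state.setdefault("ledger", {})[name] = ledger

    decoy_rng = np.random.default_rng(seeds[2])
    decoy_reads, decoy_refs = synth.make_decoy_reads(
        genome, annotation, config.sim, rng=decoy_rng
    )
    state["decoy_reads"], state["decoy_refs"] = decoy_reads, decoy_refs
    swio.write_fastq(decoy_reads, outdir / "decoys.fastq")
    outputs.append("decoys.fastq")

    non_empty = [f for f in ledger_frames if len(f)]
    ledger_all = (
        pd.concat(non_empty, ignore_index=True) if non_empty else ledger_frames[0]
    )
    swio.write_tsv(ledger_all, outdir / "ledger.tsv")
    outputs.append("ledger.tsv")
    state["resample_seeds"] = derive_seeds(config.seed + 1, len(config.conditions))
    return outputs


def _stage_junctions(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    n = config.resample_n or config.sim.library_depth
    state["resampled"] = {}
    state["catalogs"] = {}
    state["filtered"] = {}
    outputs = []
    for i, name in enumerate(config.conditions):
        cfg = diff.ResampleConfig(n_reads=n, seed=state["resample_seeds"][i])
        sample = diff.resample(state["alignments"][name], cfg)
        state["resampled"][name] = sample
        catalog = jx.extract_junctions(sample, state["annotation"], state["genome"])
        kept = jx.apply_filter(catalog, config.filter_cfg)
        state["catalogs"][name] = catalog
        state["filtered"][name] = kept
        swio.write_tsv(jx.junctions_to_frame(catalog, kept), outdir / f"junctions_{name}.tsv")
        outputs.append(f"junctions_{name}.tsv")
    return outputs


def _stage_nullcal(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    flank = jx.default_flank(config.sim.read_length)
    annotated_refs = jx.build_junction_refs(
        state["genome"], state["annotation"], flank=flank, mode="annotated"
    )
    random_refs = state["decoy_refs"]
    contrast_b = config.contrast[1]
    reads = list(state["reads"][contrast_b]) + list(state["decoy_reads"])
    random_records = jx.match_reads_to_refs(reads, random_refs)
    annotated_records = jx.match_reads_to_refs(reads, annotated_refs)
    report = jx.characterize_null(
        random_records, annotated_records, random_refs, annotated_refs
    )
    state["null_report"] = report
    swio.write_tsv(report.per_junction, outdir / "null_report.tsv")
    swio.write_tsv(report.survival, outdir / "null_survival.tsv")
    return ["null_report.tsv", "null_survival.tsv"]


def _stage_events(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    state["events"] = {}
    state["ir_calls"] = {}
    outputs = []
    for name in config.conditions:
        catalog = ev.classify_events(state["filtered"][name], state["annotation"])
        calls = ev.call_intron_retention(
            state["resampled"][name], state["annotation"], config.ir_cfg
        )
        state["events"][name] = catalog
        state["ir_calls"][name] = calls
        swio.write_tsv(catalog.to_frame(), outdir / f"events_{name}.tsv")
        swio.write_tsv(ev.ir_calls_to_frame(calls), outdir / f"ir_calls_{name}.tsv")
        outputs += [f"events_{name}.tsv", f"ir_calls_{name}.tsv"]
    return outputs


def _stage_diff(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    a, b = config.contrast
    n = config.resample_n or config.sim.library_depth
    event_counts, id_map = assemble_event_counts(
        state["events"][a], state["events"][b], state["annotation"],
        state["resampled"][a], state["resampled"][b],
    )
    event_results = diff.test_events(event_counts, alpha_as=config.alpha_as)
    swio.write_tsv(diff.results_to_frame(event_results), outdir / "differential_events.tsv")

    intron_counts = assemble_intron_counts(
        state["ir_calls"][a], state["ir_calls"][b], state["annotation"],
        state["resampled"][a], state["resampled"][b],
    )
    intron_results = diff.test_introns(intron_counts, alpha_ir=config.alpha_ir)
    swio.write_tsv(diff.results_to_frame(intron_results), outdir / "differential_introns.tsv")
    state["differential_events"] = event_results
    state["differential_introns"] = intron_results

    global_table = diff.global_comparison(
        state["events"][a].events, state["events"][b].events, n, n
    )
    swio.write_tsv(global_table, outdir / "global_comparison.tsv")

    # rescue readout: events elevated in the contrast condition, profiled
    # over every library in the run
    elevated = [
        r.event_id for r in event_results if r.significant and r.direction == "B_over"
    ]
    outputs = ["differential_events.tsv", "differential_introns.tsv", "global_comparison.tsv"]
    if elevated:
        junction_counts = {
            name: {j.key: j.read_count for j in state["catalogs"][name]}
            for name in config.conditions
        }
        coverage = {}
        for event_id in elevated:
            event = id_map[event_id]
            key = (event.chrom, event.junction[0], event.junction[1])
            coverage[event_id] = {
                name: junction_counts[name].get(key, 0) for name in config.conditions
            }
        rescue = diff.profile_rescue(coverage, {name: n for name in config.conditions})
        swio.write_tsv(rescue, outdir / "rescue_profile.tsv")
        state["rescue_profile"] = rescue
        outputs.append("rescue_profile.tsv")
    return outputs


def _stage_sites(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    genome, annotation = state["genome"], state["annotation"]
    donor_pfm = st.extract_site_matrix(
        genome, st.annotated_donor_sites(annotation), window=10, site_kind="donor"
    )
    acceptor_pfm = st.extract_site_matrix(
        genome, st.annotated_acceptor_sites(annotation), window=10, site_kind="acceptor"
    )
    swio.write_tsv(donor_pfm.to_frame(), outdir / "donor_pfm.tsv")
    swio.write_tsv(acceptor_pfm.to_frame(), outdir / "acceptor_pfm.tsv")
    state["donor_pfm"], state["acceptor_pfm"] = donor_pfm, acceptor_pfm

    b = config.contrast[1]
    alt_events = (
        state["events"][b].of_type("ALT5SS") + state["events"][b].of_type("ALT3SS")
    )
    hist = st.offset_distribution(alt_events)
    swio.write_tsv(hist.to_frame(), outdir / "offsets.tsv")
    state["offset_histogram"] = hist

    gene_map = {g.gene_id: g for g in annotation}
    skipped = {
        (e.gene_id, k)
        for e in state["events"][b].of_type("CASSETTE")
        for k in e.skipped_exons
    }
    alt_exons = {
        st.event_alt_ss_exon(e, gene_map[e.gene_id]) for e in alt_events
    }
    coord = st.coordination_test(skipped, alt_exons, annotation)
    state["coordination"] = coord
    rows = []
    if coord is not None:
        rows.append(
            {
                "observed_fraction": round(coord.observed_fraction, 6),
                "background_fraction": round(coord.background_fraction, 6),
                "p_value": coord.p_value,
                "skipped_with_alt": coord.table[0][0],
                "skipped_without_alt": coord.table[0][1],
                "other_with_alt": coord.table[1][0],
                "other_without_alt": coord.table[1][1],
            }
        )
    swio.write_tsv(
        pd.DataFrame(rows, columns=[
            "observed_fraction", "background_fraction", "p_value",
            "skipped_with_alt", "skipped_without_alt",
            "other_with_alt", "other_without_alt",
        ]),
        outdir / "coordination.tsv",
    )
    return ["donor_pfm.tsv", "acceptor_pfm.tsv", "offsets.tsv", "coordination.tsv"]


def _stage_expr(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    annotation = state["annotation"]
    a, b = config.contrast
    n = config.resample_n or config.sim.library_depth
    tables = {}
    frames = []
    for name in config.conditions:
        table = expr.expression_table(state["resampled"][name], annotation, n)
        table.insert(0, "condition", name)
        tables[name] = table
        frames.append(table)
    swio.write_tsv(pd.concat(frames, ignore_index=True), outdir / "expression.tsv")
    state["expression"] = tables

    # retained-intron proportions in the contrast condition
    expr_b = tables[b].set_index("feature_id")
    rows = []
    for call in state["ir_calls"][b]:
        if not call.called:
            continue
        gene_introns = next(
            g for g in annotation if g.gene_id == call.gene_id
        ).introns
        gidx = gene_introns.index(call.intron)
        fid = f"{call.gene_id}.intron{gidx}"
        prop = expr.ir_proportion(
            float(expr_b.loc[fid, "rpkm"]),
            expr.flanking_exon_rpkm(tables[b], call.gene_id, gidx, n),
            intron_id=fid,
        )
        rows.append(
            {
                "intron_id": prop.intron_id,
                "intron_rpkm": round(prop.intron_rpkm, 6),
                "flanking_exon_rpkm": round(prop.flanking_exon_rpkm, 6),
                "proportion": round(prop.proportion, 6) if prop.defined else "",
                "defined": prop.defined,
            }
        )
    ir_prop = pd.DataFrame(
        rows,
        columns=["intron_id", "intron_rpkm", "flanking_exon_rpkm", "proportion", "defined"],
    )
    swio.write_tsv(ir_prop, outdir / "ir_proportion.tsv")
    state["ir_proportion"] = ir_prop

    # functional-transcript expression for the same introns, both conditions
    func_rows = []
    for call in state["ir_calls"][b]:
        if not call.called:
            continue
        for name in (a, b):
            calls = {c.key: c for c in state["ir_calls"][name]}
            this = calls[call.key]
            gene = next(g for g in annotation if g.gene_id == call.gene_id)
            gidx = gene.introns.index(call.intron)
            fids = [f"{call.gene_id}.exon{gidx}", f"{call.gene_id}.exon{gidx + 1}"]
            total = float(
                tables[name].set_index("feature_id").loc[fids, "read_count"].sum()
            )
            functional, floored = expr.functional_expression(
                total, float(this.n_unspliced_reads)
            )
            func_rows.append(
                {
                    "intron_id": f"{call.gene_id}.intron{gidx}",
                    "condition": name,
                    "total_reads": round(total, 6),
                    "retained_intron_reads": this.n_unspliced_reads,
                    "functional_reads": round(functional, 6),
                    "floored": floored,
                }
            )
    swio.write_tsv(
        pd.DataFrame(func_rows, columns=[
            "intron_id", "condition", "total_reads",
            "retained_intron_reads", "functional_reads", "floored",
        ]),
        outdir / "functional_expression.tsv",
    )

    steps = [n // 16, n // 8, n // 4, n // 2, n]
    saturation = expr.saturation_curve(
        state["resampled"][a], annotation, steps, seed=derive_seeds(config.seed + 2, 1)[0]
    )
    swio.write_tsv(saturation, outdir / "saturation.tsv")
    profile = expr.transcript_coverage_profile(
        state["resampled"][a], annotation, n_bins=50
    )
    swio.write_tsv(profile, outdir / "coverage_profile.tsv")
    return [
        "expression.tsv", "ir_proportion.tsv", "functional_expression.tsv",
        "saturation.tsv", "coverage_profile.tsv",
    ]
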