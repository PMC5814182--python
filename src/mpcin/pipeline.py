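"""End-to-end orchestration and figure-equivalent table export.

``analyze_sample`` runs the in-memory detection chain
classify -> cluster -> junctions -> integration -> bins -> GC/panel
normalization -> segmentation -> junction refinement -> classification ->
chromosome summary -> chromoplexy; ``run_pipeline`` wraps it around files
per the run configuration, and ``demo`` seeds a full simulate+detect run
whose report carries a truth-comparison block. Reports contain no
timestamps: identical config and inputs give byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import cnv, evaluate
from . import io as mio
from .config import RunConfig
from .fragments import canonicalize
from .graph import ChromoplexyEvent, build_junction_graph, detect_chromoplexy
from .junctions import (
    CONCORDANT,
    DISCORDANT,
    TRANSGENIC,
    BreakpointJunction,
    IntegrationResult,
    classify_fragments,
    cluster_discordant,
    call_junctions,
    detect_integration_sites,
    junctions_to_frame,
)
from .signature import SignatureResult, load_cin25, paired_signature_test
from .simulate import (
    Chromoplexy,
    Deletion,
    FragmentSimParams,
    Integration,
    Inversion,
    KaryotypePlan,
    TandemDuplication,
    Translocation,
    TruthSet,
    WholeGain,
    WholeLoss,
    apply_karyotype,
    chromoplexy_chain,
    make_toy_genome,
    simulate_expression,
    simulate_mate_pairs,
)
from .simulate.genome import GenomeModel

log = logging.getLogger("mpcin")


@dataclass
class SampleResult:
    counts: dict[str, int]
    junctions: list[BreakpointJunction]
    integration: IntegrationResult
    track: cnv.CopyNumberTrack
    segments: list[cnv.CNVSegment]
    calls: list[cnv.ChromosomeCall]
    chromoplexy: list[ChromoplexyEvent]
    signature: SignatureResult | None = None
    truth_comparison: dict[str, Any] | None = None


def build_panel_tracks(
    panel_frames: list[pd.DataFrame], genome: GenomeModel, cfg: RunConfig
) -> list[cnv.CopyNumberTrack]:
    """Bin and GC-normalize each normal sample of the panel."""
    return [
        cnv.gc_normalize(cnv.bin_depth(frame, genome, cfg.bin_size)) for frame in panel_frames
    ]


def analyze_sample(
    fragments: pd.DataFrame,
    genome: GenomeModel,
    panel_tracks: list[cnv.CopyNumberTrack],
    cfg: RunConfig,
    truth: TruthSet | None = None,
) -> SampleResult:
    """Full detection chain for one sample against a prepared panel."""
    fragments = canonicalize(fragments, genome)
    category = classify_fragments(fragments, genome, cfg)
    counts = {
        "fragments": int(len(fragments)),
        "concordant": int((category == CONCORDANT).sum()),
        "discordant": int((category == DISCORDANT).sum()),
        "transgenic": int((category == TRANSGENIC).sum()),
    }
    log.info("classified fragments: %s", counts)

    discordant = fragments.loc[category == DISCORDANT]
    clusters = cluster_discordant(discordant, cfg.cluster_gap, genome)
    junctions = call_junctions(clusters, cfg.min_support, genome, cfg.expected_orientation)
    counts["clusters"] = len(clusters)
    counts["junctions"] = len(junctions)

    transgenic = fragments.loc[category == TRANSGENIC]
    integration = detect_integration_sites(transgenic, genome, cfg)
    counts["integration_sites"] = len(integration.sites)

    track = cnv.gc_normalize(cnv.bin_depth(fragments, genome, cfg.bin_size))
    track = cnv.normalize_by_panel(track, panel_tracks)
    track = cnv.mask_low_panel_bins(track, panel_tracks, cfg.panel_min_ratio)
    counts["bins_assayable"] = int(track.concat("mask").sum())
    counts["bins_masked"] = int((~track.concat("mask")).sum())

    segments = cnv.segment(track, cfg.window_w, cfg.z_threshold, cfg.merge_delta)
    segments = cnv.refine_with_junctions(segments, junctions, cfg.snap_distance)
    segments = cnv.classify_segments(segments, cfg.gain_cutoff, cfg.loss_cutoff, track.expected)
    calls = cnv.summarize_chromosomes(segments, cfg.whole_fraction, cfg.partial_min_fraction)
    counts["segments"] = len(segments)

    jgraph = build_junction_graph(junctions, cfg.locus_merge_distance)
    events = detect_chromoplexy(
        jgraph, cfg.chromoplexy_min_junctions, segments=segments, snap_distance=cfg.snap_distance
    )
    counts["chromoplexy_events"] = len(events)

    result = SampleResult(
        counts=counts,
        junctions=junctions,
        integration=integration,
        track=track,
        segments=segments,
        calls=calls,
        chromoplexy=events,
    )
    if truth is not None:
        result.truth_comparison = compare_with_truth(result, truth, genome, cfg)
    return result


def compare_with_truth(
    result: SampleResult, truth: TruthSet, genome: GenomeModel, cfg: RunConfig
) -> dict[str, Any]:
    tolerance = cfg.median_insert + 1.6449 * cfg.insert_sd
    jmatch = evaluate.match_junctions(result.junctions, truth, tolerance)
    errors = evaluate.breakpoint_errors(result.junctions, truth, jmatch)
    expected_calls = evaluate.expected_calls_from_truth(
        truth,
        genome,
        cfg.gain_cutoff,
        cfg.loss_cutoff,
        cfg.whole_fraction,
        cfg.partial_min_fraction,
    )
    expected_by_chrom = {c.chrom: c.call for c in expected_calls}
    call_by_chrom = {c.chrom: c.call for c in result.calls}
    whole_expected = {c for c, v in expected_by_chrom.items() if v in (cnv.WHOLE_GAIN, cnv.WHOLE_LOSS)}
    whole_recovered = sum(
        1 for c in whole_expected if call_by_chrom.get(c) == expected_by_chrom[c]
    )
    site_match, site_missed, site_extra = evaluate.match_integration_sites(
        result.integration.sites, truth, tolerance
    )
    return {
        "junctions_planted": len(truth.junctions),
        "junctions_recovered": len(jmatch.matched),
        "junctions_unmatched_detected": len(jmatch.unmatched_detected),
        "max_breakpoint_error": max(errors) if errors else None,
        "whole_chromosome_events_planted": len(whole_expected),
        "whole_chromosome_events_recovered": whole_recovered,
        "heatmap_matches_plan": call_by_chrom == expected_by_chrom,
        "expected_calls": expected_by_chrom,
        "integration_sites_planted": len(truth.integration_sites),
        "integration_sites_recovered": len(site_match),
        "integration_sites_extra": len(site_extra),
        "chromoplexy_planted": len(truth.chromoplexy_components),
        "chromoplexy_detected": len(result.chromoplexy),
    }


# ----------------------------------------------------------------------
# figure-equivalent exports
# ----------------------------------------------------------------------

def export_genome_plot_data(
    track: cnv.CopyNumberTrack,
    segments: list[cnv.CNVSegment],
    junctions: list[BreakpointJunction],
    integration_sites,
    dot_size: int = 30000,
) -> pd.DataFrame:
    """Plot-ready genome overview: one dot per 30 kb of copy-number data,
    one row per junction (the connecting lines) and per integration site.

    Dot color encodes the overlapping segment class: gray for normal copy
    number, blue for gain, red for loss. Masked bins are excluded; a dot
    with no assayable bins is dropped.
    """
    if dot_size % track.bin_size != 0:
        raise ValueError(f"dot_size {dot_size} must be a multiple of bin_size {track.bin_size}")
    per_dot = dot_size // track.bin_size
    color_of = {cnv.GAIN: "blue", cnv.LOSS: "red", cnv.NORMAL: "gray"}
    rows: list[dict[str, Any]] = []
    seg_by_chrom: dict[str, list[cnv.CNVSegment]] = {}
    for s in segments:
        seg_by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in track.chroms:
        values = track.cn[chrom]
        mask = track.mask[chrom] & np.isfinite(values)
        nb = len(values)
        for dot_start in range(0, nb, per_dot):
            sl = slice(dot_start, min(dot_start + per_dot, nb))
            if not mask[sl].any():
                continue
            value = float(values[sl][mask[sl]].mean())
            mid = (sl.start + min(sl.stop, nb)) / 2 * track.bin_size
            klass = cnv.NORMAL
            for s in seg_by_chrom.get(chrom, []):
                if s.start <= mid < s.end and s.klass is not None:
                    klass = s.klass
                    break
            rows.append(
                {
                    "kind": "dot",
                    "chrom": chrom,
                    "start": sl.start * track.bin_size,
                    "end": min(sl.stop * track.bin_size, track.lengths[chrom]),
                    "value": round(value, 4),
                    "color": color_of[klass],
                    "chrom2": "",
                    "pos2": "",
                    "label": "",
                }
            )
    for j in junctions:
        rows.append(
            {
                "kind": "junction",
                "chrom": j.chrom_a,
                "start": j.pos_a,
                "end": j.pos_a + 1,
                "value": j.support,
                "color": "magenta",
                "chrom2": j.chrom_b,
                "pos2": j.pos_b,
                "label": j.klass,
            }
        )
    for site in integration_sites:
        rows.append(
            {
                "kind": "integration",
                "chrom": site.chrom,
                "start": site.pos,
                "end": site.pos + 1,
                "value": site.support,
                "color": "orange" if site.transgene.lower().startswith("hu") else "green",
                "chrom2": "",
                "pos2": "",
                "label": site.transgene,
            }
        )
    return pd.DataFrame(
        rows, columns=["kind", "chrom", "start", "end", "value", "color", "chrom2", "pos2", "label"]
    )


def render_heatmap_table(
    calls_by_sample: dict[str, list[cnv.ChromosomeCall]], genome: GenomeModel
) -> pd.DataFrame:
    """Chromosome x sample grid of aneuploidy call labels.

    Rows follow genome order, columns the sample order given; inconsistent
    chromosome sets across samples are an error.
    """
    chroms = genome.genomic_chromosomes
    table = {}
    for sample, calls in calls_by_sample.items():
        by_chrom = {c.chrom: c.call for c in calls}
        if set(by_chrom) != set(chroms):
            raise ValueError(
                f"sample {sample!r} covers chromosomes {sorted(by_chrom)}, expected {sorted(chroms)}"
            )
        table[sample] = [by_chrom[c] for c in chroms]
    return pd.DataFrame(table, index=pd.Index(chroms, name="chrom"))


# ----------------------------------------------------------------------
# file-driven run + demo
# ----------------------------------------------------------------------

def _events_json(events: list[ChromoplexyEvent]) -> list[dict[str, Any]]:
    return [
        {
            "junction_ids": list(e.junction_ids),
            "chromosomes": list(e.chromosomes),
            "n_junctions": e.n_junctions,
            "n_chromosomes": e.n_chromosomes,
            "cn_boundary_fraction": e.cn_boundary_fraction,
        }
        for e in events
    ]


def _relativize_paths(cfg: RunConfig) -> RunConfig:
    """Echo input paths relative to outdir: report bytes independent of cwd."""
    base = Path(cfg.outdir or ".").resolve()

    def rel(p: str | None) -> str | None:
        if p is None:
            return None
        try:
            return str(Path(p).resolve().relative_to(base))
        except ValueError:
            return str(Path(p).name)

    return cfg.replace(
        genome=rel(cfg.genome),
        fragments=rel(cfg.fragments),
        panel=[rel(p) for p in cfg.panel],
        expression=rel(cfg.expression),
        manifest=rel(cfg.manifest),
        gene_list=rel(cfg.gene_list),
        outdir=".",
    )


def build_report(result: SampleResult, cfg: RunConfig) -> dict[str, Any]:
    report: dict[str, Any] = {
        "config": _relativize_paths(cfg).to_dict(),
        "counts": result.counts,
        "junctions": junctions_to_frame(result.junctions).to_dict(orient="records"),
        "integration_sites": [
            {"transgene": s.transgene, "chrom": s.chrom, "pos": s.pos, "support": s.support}
            for s in result.integration.sites
        ],
        "chromosome_calls": {c.chrom: c.call for c in result.calls},
        "variant_fractions": {c.chrom: round(c.variant_fraction, 4) for c in result.calls},
        "chromoplexy": _events_json(result.chromoplexy),
    }
    if result.signature is not None:
        report["signature"] = result.signature.table.round(6).to_dict(orient="records")
        report["signature_missing"] = result.signature.missing
    if result.truth_comparison is not None:
        report["truth_comparison"] = result.truth_comparison
    return report


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run the file-driven pipeline per the config; write artifacts + report."""
    for stage, path in (("genome", cfg.genome), ("fragments", cfg.fragments)):
        if path is None:
            raise ValueError(f"config is missing the {stage} path")
        if not Path(path).exists():
            raise FileNotFoundError(f"{stage}: no such file {path}")
    for path in cfg.panel:
        if not Path(path).exists():
            raise FileNotFoundError(f"panel: no such file {path}")
    if not cfg.panel:
        raise ValueError("config must list at least one panel fragment file")
    outdir = Path(cfg.outdir or ".")
    outdir.mkdir(parents=True, exist_ok=True)

    genome = mio.read_genome_json(cfg.genome)
    fragments = mio.read_fragments(cfg.fragments, genome)
    panel_frames = [mio.read_fragments(p, genome) for p in cfg.panel]
    panel_tracks = build_panel_tracks(panel_frames, genome, cfg)

    truth = None
    truth_path = Path(cfg.fragments).with_suffix(".truth.json")
    if truth_path.exists():
        truth = mio.read_truth_json(truth_path)

    result = analyze_sample(fragments, genome, panel_tracks, cfg, truth=truth)

    if cfg.expression and cfg.manifest:
        counts = mio.read_expression_tsv(cfg.expression)
        manifest = mio.read_manifest_tsv(cfg.manifest)
        genes = mio.read_gene_list(cfg.gene_list) if cfg.gene_list else load_cin25()
        result.signature = paired_signature_test(
            counts, manifest, genes, B=cfg.permutations, seed=cfg.seed
        )

    mio.write_junctions_tsv(result.junctions, outdir / "junctions.tsv")
    mio.write_sites(result.integration.sites, outdir / "integration_sites.bed", outdir / "integration_sites.tsv")
    mio.write_track_tsv(result.track, outdir / "bins.tsv")
    mio.write_segments_bed(result.segments, outdir / "segments.bed")
    heatmap = render_heatmap_table({"sample": result.calls}, genome)
    heatmap.to_csv(outdir / "heatmap.tsv", sep="\t")
    plot_data = export_genome_plot_data(
        result.track, result.segments, result.junctions, result.integration.sites
    )
    plot_data.to_csv(outdir / "genome_plot.tsv", sep="\t", index=False)
    (outdir / "chromoplexy.json").write_text(
        json.dumps(_events_json(result.chromoplexy), sort_keys=True, indent=1)
    )
    if result.signature is not None:
        result.signature.table.to_csv(outdir / "signature.tsv", sep="\t", index=False)

    report = build_report(result, cfg)
    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report


def default_demo_plan(genome: GenomeModel, seed: int) -> KaryotypePlan:
    """The seeded demo karyotype: one event of every kind."""
    L = genome.lengths["1"]
    events = [
        Deletion("1", int(0.3 * L), int(0.5 * L)),
        WholeGain("2"),
        TandemDuplication("3", int(0.4 * L), int(0.64 * L)),
        WholeLoss("4"),
        chromoplexy_chain(("5", "6"), genome, n_junctions=6, seed=seed + 17),
        Inversion("7", int(0.2 * L), int(0.4 * L)),
        Translocation("7", int(0.8 * L), "8", int(0.2 * L)),
    ]
    if "huYAP" in genome.transgenes:
        events.append(Integration("huYAP", "8", int(0.6 * L)))
    if "muAkt" in genome.transgenes:
        events.append(Integration("muAkt", "2", int(0.6 * L)))
    return KaryotypePlan(events=events, seed=seed)


def demo(outdir: str | Path, seed: int = 0, cfg: RunConfig | None = None) -> dict[str, Any]:
    """Seeded end-to-end demonstration: simulate, write inputs, run, report.

    Produces the same artifacts as ``run_pipeline`` plus the simulated
    inputs and truth set; the report carries a truth-comparison block.
    Byte-identical outputs for identical seed and config.
    """
    cfg = cfg or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = make_toy_genome(
        n_autosomes=8,
        autosome_length=500_000,
        bin_size=cfg.bin_size,
        transgenes=("huYAP", "muAkt"),
        seed=seed,
        with_sequence=False,
    )
    plan = default_demo_plan(genome, seed)
    derived, truth = apply_karyotype(genome, plan, min_sv_span=cfg.discordance_distance)
    params = FragmentSimParams(
        median_insert=cfg.median_insert,
        insert_sd=cfg.insert_sd,
        mean_fragments_per_kb=20.0,
        gc_bias_slope=0.5,
        noise_rate=0.002,
        seed=seed + 1,
    )
    fragments = simulate_mate_pairs(derived, params)

    diploid, _ = apply_karyotype(genome, KaryotypePlan(events=[]))
    panel_paths = []
    for i in range(3):
        normal = simulate_mate_pairs(
            diploid,
            FragmentSimParams(
                median_insert=cfg.median_insert,
                insert_sd=cfg.insert_sd,
                mean_fragments_per_kb=20.0,
                gc_bias_slope=0.5,
                noise_rate=0.002,
                seed=seed + 100 + i,
            ),
        )
        path = outdir / f"normal{i + 1}.bedpe"
        mio.write_fragments(normal, path)
        panel_paths.append(str(path))

    signature_genes = [g.capitalize() for g in load_cin25()]
    effects = {g: 1.0 for g in signature_genes}
    effects["Foxm1"] = 3.0
    expr = simulate_expression(
        n_genes=200,
        n_pairs=4,
        signature_genes=signature_genes,
        effect_log2fc=effects,
        dispersion=0.1,
        seed=seed + 2,
    )
    truth.expression_effects = expr.effects

    mio.write_genome_json(genome, outdir / "genome.json")
    mio.write_fragments(fragments, outdir / "sample.bedpe")
    mio.write_truth_json(truth, outdir / "sample.truth.json")
    mio.write_expression_tsv(expr.counts, outdir / "expression.tsv")
    mio.write_manifest_tsv(expr.manifest, outdir / "manifest.tsv")

    run_cfg = cfg.replace(
        genome=str(outdir / "genome.json"),
        fragments=str(outdir / "sample.bedpe"),
        panel=panel_paths,
        expression=str(outdir / "expression.tsv"),
        manifest=str(outdir / "manifest.tsv"),
        outdir=str(outdir),
        seed=seed,
    )
    return run_pipeline(run_cfg)
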