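"""End-to-end orchestration: simulate/load -> coverage -> enrichment ->
clusters -> word stats -> HMM -> metagene -> ranking -> report.

``run_all`` drives every stage on one run directory and writes plain-text
(TSV/BED/YAML) outputs per stage plus a resolved-config snapshot, so a run
is reproducible from its directory alone. All randomness flows from the
single ``seed`` in the config.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation_io, clusters as cl, coverage as cov, hmm_motif, metagene
from . import motif_stats, ranking, synthetic_data
from .annotation_io import GenomeSequence, TranscriptModel

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, defaulting to the printed constants
    of the study design (cluster filters, top-N sizes, bin counts, HMM
    parameters) with the synthetic generator's defaults for data."""

    data_dir: str = "data"
    out_dir: str = "run"
    seed: int = 0
    # cluster calling / filtering
    cluster_gap_max: int = 15
    min_cluster_reads: int = 6
    min_expression: float = 5.0          # RNA-seq reads per nucleotide
    # segmentation
    seg_window: int = 10
    seg_ratio: float = 2.0
    min_seg_len: int = 10
    # selections
    top_clusters_word: int = 25000
    top_clusters_zscore: int = 3000
    top_n: int = 200
    # windows
    crosslink_halfwidth: int = 5
    flank_extent: int = 50
    n_background_samples: int = 20
    # metagene
    bins: tuple[int, int, int] = (20, 50, 50)
    coverage_min: float = 0.30
    # HMM
    t1: float = 0.95
    emit_main: float = 0.9
    min_motif_len: int = 4
    merge_gap: int = 50
    # reporting
    enrichment_threshold: float = 3.0
    replicates: int = 2

    def resolved(self) -> dict:
        d = asdict(self)
        d["bins"] = list(self.bins)
        return d


@dataclass
class RunContext:
    config: PipelineConfig
    models: list[TranscriptModel]
    genome: GenomeSequence
    reads: dict[str, pd.DataFrame]
    truth: synthetic_data.GroundTruth | None = None
    representatives: dict[str, TranscriptModel] = field(default_factory=dict)
    indexes: dict[str, cov.LibraryIndex] = field(default_factory=dict)
    expression: dict[str, pd.Series] = field(default_factory=dict)
    tracks: dict[str, dict[str, cov.CoverageTrack]] = field(default_factory=dict)
    starts: dict[str, dict[str, cov.ReadStartTrack]] = field(default_factory=dict)
    enrichment: dict[str, dict[str, cov.EnrichmentTrack]] = field(default_factory=dict)
    results: dict = field(default_factory=dict)


def _timer(name):
    class _T:
        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, *exc):
            log.info("stage %-12s %.1fs", name, time.time() - self.t0)

    return _T()


# ---------------------------------------------------------------------------
# stage: load

def load_stage(config: PipelineConfig) -> RunContext:
    """Load annotation/genome/reads from ``data_dir`` (synthetic layout)."""
    d = Path(config.data_dir)
    models, genome = annotation_io.load_annotation(d / "annotation.gtf", d / "genome.fa")
    reads = {}
    for bed in sorted(d.glob("*_rep*.bed")):
        reads[bed.stem] = cov.read_bed6(bed)
    truth = None
    gt = d / "ground_truth.tsv"
    if gt.exists():
        df = pd.read_csv(gt, sep="\t")
        truth = synthetic_data.GroundTruth(
            targets=set(df.loc[df.is_target, "transcript_id"]),
            motif_spans={
                r.transcript_id: (r.motif_start, r.motif_end)
                for r in df.itertuples() if r.motif_start >= 0
            },
            ua_core_spans={
                r.transcript_id: (r.core_start, r.core_end)
                for r in df.itertuples() if r.core_start >= 0
            },
            expression=df.set_index("transcript_id")["expression"],
            expected_enrichment=df.set_index("transcript_id")["expected_enrichment"],
        )
    return RunContext(config=config, models=models, genome=genome,
                      reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# stage: coverage + representatives

def coverage_stage(ctx: RunContext) -> None:
    cfg = ctx.config
    for name, df in ctx.reads.items():
        ctx.indexes[name] = cov.LibraryIndex(df)
    rnaseq_names = sorted(n for n in ctx.reads if n.startswith("rnaseq"))
    pooled_rna = pd.concat([ctx.reads[n] for n in rnaseq_names], ignore_index=True)
    ctx.indexes["rnaseq_pool"] = cov.LibraryIndex(pooled_rna)
    fracs = cov.coverage_fractions(ctx.indexes["rnaseq_pool"], ctx.models)
    ctx.representatives = annotation_io.pick_representative(
        ctx.models, fracs, cfg.coverage_min
    )
    ctx.results["coverage_fractions"] = fracs
    reps = ctx.representatives

    roles = {"rnaseq": "rnaseq", "iclip": "clip", "pariclip": "clip",
             "rip_ip": "rip_ip", "rip_input": "rip_input"}
    clip_pools = {"iclip_pool": [n for n in ctx.reads if n.startswith("iclip")],
                  "pariclip_pool": [n for n in ctx.reads if n.startswith("pariclip")],
                  "rip_ip_pool": [n for n in ctx.reads if n.startswith("rip_ip")],
                  "rip_input_pool": [n for n in ctx.reads if n.startswith("rip_input")]}
    for pool, names in clip_pools.items():
        if names:
            ctx.indexes[pool] = cov.LibraryIndex(
                pd.concat([ctx.reads[n] for n in names], ignore_index=True)
            )
    for name, index in ctx.indexes.items():
        role = next((r for p, r in roles.items() if name.startswith(p)), "clip")
        tr = {}
        st = {}
        is_clip = role == "clip"
        for gene, m in reps.items():
            tr[m.transcript_id] = cov.count_base_calls(index, m, library_role=role)
            if is_clip:
                st[m.transcript_id] = cov.crosslink_starts(index, m)
        ctx.tracks[name] = tr
        if is_clip:
            ctx.starts[name] = st
    for name in list(ctx.tracks):
        if name.startswith("rnaseq") or name.startswith("rip_input"):
            ctx.expression[name] = pd.Series({
                tid: cl.expression_per_nt(t, _model(ctx, tid))
                for tid, t in ctx.tracks[name].items()
            })


def _model(ctx: RunContext, tid: str) -> TranscriptModel:
    if not hasattr(ctx, "_by_tid"):
        ctx._by_tid = {m.transcript_id: m for m in ctx.models}
    return ctx._by_tid[tid]


# ---------------------------------------------------------------------------
# stage: enrichment

NORMALIZATION = {
    # CLIP dataset -> matching RNA-seq control (replicate-matched for iCLIP,
    # pooled controls for PAR-iCLIP, as in the library design)
    "iclip_rep1": "rnaseq_rep1",
    "iclip_rep2": "rnaseq_rep2",
    "pariclip_rep1": "rnaseq_pool",
    "pariclip_rep2": "rnaseq_pool",
    "iclip_pool": "rnaseq_pool",
    "pariclip_pool": "rnaseq_pool",
}


def enrichment_stage(ctx: RunContext) -> None:
    for clip_name, rna_name in NORMALIZATION.items():
        if clip_name not in ctx.tracks or rna_name not in ctx.tracks:
            continue
        tracks = {}
        for tid, clip_track in ctx.tracks[clip_name].items():
            tracks[tid] = cov.enrichment(
                clip_track, ctx.tracks[rna_name][tid], _model(ctx, tid)
            )
        ctx.enrichment[clip_name] = tracks
    # RIP factors per replicate and pooled
    rip = {}
    for suffix in [f"rep{r}" for r in range(1, ctx.config.replicates + 1)] + ["pool"]:
        ip_name, in_name = f"rip_ip_{suffix}", f"rip_input_{suffix}"
        if ip_name not in ctx.tracks:
            continue
        rip[suffix] = pd.Series({
            tid: cov.rip_enrichment_factor(
                ctx.tracks[ip_name][tid], ctx.tracks[in_name][tid], _model(ctx, tid)
            )
            for tid in ctx.tracks[ip_name]
        })
    ctx.results["rip_factors"] = rip


# ---------------------------------------------------------------------------
# stage: clusters

def cluster_stage(ctx: RunContext, clip_name: str = "iclip_pool") -> None:
    cfg = ctx.config
    expr = ctx.expression["rnaseq_pool"]
    all_clusters: list[cl.Cluster] = []
    segments: list[cl.ClusterSegment] = []
    for tid, track in ctx.tracks[clip_name].items():
        m = _model(ctx, tid)
        e = ctx.enrichment[clip_name][tid]
        cs = cl.call_clusters(ctx.starts[clip_name][tid], track, m, e,
                              gap_max=cfg.cluster_gap_max)
        all_clusters.extend(cs)
        for c in cl.filter_clusters(cs, expr.to_dict(), cfg.min_cluster_reads,
                                    cfg.min_expression):
            segments.extend(
                cl.segment_cluster(c, e, cfg.min_seg_len, cfg.seg_window,
                                   cfg.seg_ratio, model=m)
            )
    ctx.results["clusters"] = all_clusters
    ctx.results["segments"] = segments
    ctx.results["top_segments"] = cl.rank_and_take(
        segments, cfg.top_clusters_zscore, region="3utr"
    )


# ---------------------------------------------------------------------------
# stage: word statistics

def word_stage(ctx: RunContext) -> None:
    cfg = ctx.config
    reps = {m.transcript_id: m for m in ctx.representatives.values()}
    top = ctx.results["top_segments"]
    seqs = {
        tid: ctx.genome.transcript_sequence(m)
        for tid, m in reps.items()
    }
    windows = [
        cl.crosslink_windows(s, reps[s.transcript_id].L,
                             cfg.crosslink_halfwidth, cfg.flank_extent)
        for s in top
    ]
    fg_counts = motif_stats.count_tetramers(seqs, windows)
    expressed = {
        tid: m for tid, m in reps.items()
        if ctx.expression["rnaseq_pool"].get(tid, 0) >= cfg.min_expression
    } or reps
    bg_samples = []
    bg_segments_first: list[cl.ClusterSegment] = []
    for i in range(cfg.n_background_samples):
        rng = np.random.default_rng([cfg.seed, 100, i])
        bg = cl.sample_background(expressed, len(top), top, rng,
                                  clamp_lengths=True)
        if i == 0:
            bg_segments_first = bg
        bw = [
            cl.crosslink_windows(s, reps[s.transcript_id].L,
                                 cfg.crosslink_halfwidth, cfg.flank_extent)
            for s in bg
        ]
        bg_samples.append(motif_stats.count_tetramers(seqs, bw))
    ctx.results["tetramer_table"] = motif_stats.zscores(fg_counts, bg_samples)
    fg_anchored = [(seqs[s.transcript_id], s.span[0]) for s in top]
    bg_anchored = [(seqs[s.transcript_id], s.span[0]) for s in bg_segments_first]
    ctx.results["profile_ua"] = motif_stats.positional_profile(
        fg_anchored, bg_anchored, motif_stats.UA_WORDS)
    ctx.results["profile_ca"] = motif_stats.positional_profile(
        fg_anchored, bg_anchored, motif_stats.CA_WORDS)
    seg_seqs = [seqs[s.transcript_id][s.span[0]:s.span[1]] for s in top]
    ctx.results["maca"] = motif_stats.maca_cooccurrence(
        seg_seqs, rng=np.random.default_rng([cfg.seed, 101]))
    # 3'UTR tag density vs 3'UTR length
    dens, lens = [], []
    clip_name = "iclip_pool"
    for tid, m in reps.items():
        a, b = m.region_interval(2)
        if b - a < 1:
            continue
        dens.append(ctx.tracks[clip_name][tid].counts[a:b].sum() / (b - a))
        lens.append(b - a)
    rho, p = motif_stats.utr_length_correlation(dens, lens)
    ctx.results["utr_length_corr"] = dict(rho=rho, p=p, n=len(dens))


# ---------------------------------------------------------------------------
# stage: metagene (enrichment)

def metagene_stage(ctx: RunContext, clip_name: str = "iclip_pool") -> None:
    cfg = ctx.config
    binned = []
    for gene, m in ctx.representatives.items():
        e = ctx.enrichment[clip_name][m.transcript_id]
        if not e.defined:
            continue
        binned.append(metagene.bin_track(e.e, m.region_lengths, cfg.bins))
    ctx.results["metagene_enrichment"] = metagene.average_profiles(
        binned, cfg.bins, "mean_enrichment_per_nt")


# ---------------------------------------------------------------------------
# stage: HMM motif annotation

def hmm_stage(ctx: RunContext, outdir: Path | None = None) -> None:
    cfg = ctx.config
    hmm = hmm_motif.build_hmm(cfg.t1, cfg.emit_main)
    cache = outdir / "motif_annotations.bed" if outdir else None
    if cache is not None and cache.exists():
        df = pd.read_csv(cache, sep="\t", header=None, names=cov.BED6_COLS)
        anns = [
            hmm_motif.MotifAnnotation(r.start, r.end, r.name, r.strand, r.chrom)
            for r in df.itertuples()
        ]
        log.info("hmm: reloaded %d annotations from %s", len(anns), cache)
    else:
        anns = hmm_motif.annotate_genome(
            hmm, ctx.genome, min_len=cfg.min_motif_len, max_gap=cfg.merge_gap)
    ctx.results["hmm"] = hmm
    ctx.results["motif_annotations"] = anns
    reps = {m.transcript_id: m for m in ctx.representatives.values()}
    stats, tracks = hmm_motif.count_motifs_per_transcript(anns, reps)
    ctx.results["motif_counts"] = stats
    binned = [
        metagene.bin_track(tracks[tid], m.region_lengths, cfg.bins)
        for tid, m in reps.items()
    ]
    if binned:
        ctx.results["metagene_motifs"] = metagene.average_profiles(
            binned, cfg.bins, "mean_motifs_per_nt")


# ---------------------------------------------------------------------------
# stage: ranking

def ranking_stage(ctx: RunContext) -> None:
    cfg = ctx.config
    reps = {m.transcript_id: m for m in ctx.representatives.values()}
    rankings: dict[str, list[ranking.DatasetRanking]] = {
        "iclip": [], "pariclip": [], "rip": []}
    for r in range(1, cfg.replicates + 1):
        for method in ("iclip", "pariclip"):
            name = f"{method}_rep{r}"
            if name not in ctx.enrichment:
                continue
            scores = pd.Series({
                tid: cov.mean_region_enrichment(tr, reps[tid], region=2)
                for tid, tr in ctx.enrichment[name].items()
            })
            expr_name = NORMALIZATION[name]
            expr = ctx.expression.get(expr_name, ctx.expression["rnaseq_pool"])
            rankings[method].append(ranking.rank_dataset(name, scores, expr))
        rip_scores = ctx.results["rip_factors"].get(f"rep{r}")
        if rip_scores is not None:
            expr = ctx.expression.get(f"rip_input_rep{r}",
                                      ctx.expression["rnaseq_pool"])
            rankings["rip"].append(
                ranking.rank_dataset(f"rip_rep{r}", rip_scores, expr))
    ctx.results["rankings"] = rankings
    ctx.results["merged_rankings"] = {
        m: ranking.merge_replicates(rs) for m, rs in rankings.items() if len(rs) >= 2
    }
    ctx.results["intersection"] = ranking.top_n_intersections(
        rankings, cfg.top_n)
    # pooled enrichment curves
    clip_scores = pd.Series({
        tid: cov.mean_region_enrichment(tr, reps[tid], region=2)
        for tid, tr in ctx.enrichment.get("iclip_pool", {}).items()
    })
    curve, n_above = ranking.enrichment_curve(clip_scores, cfg.enrichment_threshold)
    ctx.results["clip_curve"] = curve
    ctx.results["n_three_fold_clip"] = n_above
    rip_pool = ctx.results["rip_factors"].get("pool")
    if rip_pool is not None:
        # restrict the RIP curve to expressed transcripts, as for CLIP
        retained = ranking.expression_filter(ctx.expression["rnaseq_pool"])
        curve_r, n_above_r = ranking.enrichment_curve(
            rip_pool.reindex([t for t in retained if t in rip_pool.index]),
            cfg.enrichment_threshold)
        ctx.results["rip_curve"] = curve_r
        ctx.results["n_three_fold_rip"] = n_above_r


# ---------------------------------------------------------------------------
# stage: report

def report_stage(ctx: RunContext) -> dict:
    cfg = ctx.config
    summary: dict = {
        "n_transcripts": len(ctx.models),
        "n_representatives": len(ctx.representatives),
        "n_clusters": len(ctx.results.get("clusters", [])),
        "n_segments": len(ctx.results.get("segments", [])),
        "utr_length_corr": ctx.results.get("utr_length_corr"),
    }
    rep = ctx.results.get("intersection")
    if rep is not None:
        summary["pool_sizes"] = {k: int(v) for k, v in rep.pool_sizes.items()}
        summary["final_intersection_size"] = len(rep.final)
        summary["n_three_fold_clip"] = int(ctx.results.get("n_three_fold_clip", 0))
        summary["n_three_fold_rip"] = int(ctx.results.get("n_three_fold_rip", 0))
    mg = ctx.results.get("metagene_enrichment")
    if mg is not None:
        summary["metagene_utr3_cds_ratio"] = float(
            np.nanmean(mg.bins_3utr) / np.nanmean(mg.bins_cds))
    if rep is not None and ctx.truth is not None and ctx.truth.targets:
        final = rep.final
        truth = ctx.truth.targets
        tp = len(final & truth)
        summary["target_recovery"] = tp / len(truth)
        summary["false_positive_fraction"] = (
            (len(final) - tp) / len(final) if final else 0.0)
    ctx.results["summary"] = summary
    return summary


# ---------------------------------------------------------------------------

def _segments_frame(segs: list[cl.ClusterSegment]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(transcript_id=s.transcript_id, start=s.span[0], end=s.span[1],
             parent_start=s.parent_span[0], parent_end=s.parent_span[1],
             max_enrichment=s.max_enrichment, region=s.region,
             read_count=s.read_count)
        for s in segs
    ])


def write_outputs(ctx: RunContext, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(ctx.config.resolved(), fh)
    annotation_io.write_transcript_table(ctx.models, outdir / "transcripts.tsv")
    pd.DataFrame({
        "transcript_id": list(ctx.expression["rnaseq_pool"].index),
        "reads_per_nt": ctx.expression["rnaseq_pool"].to_numpy(),
    }).to_csv(outdir / "expression.tsv", sep="\t", index=False)
    if "segments" in ctx.results:
        _segments_frame(ctx.results["segments"]).to_csv(
            outdir / "segments.tsv", sep="\t", index=False)
        by_tid = {m.transcript_id: m for m in ctx.models}
        cl.segments_to_bed6(ctx.results["segments"], by_tid).to_csv(
            outdir / "segments.bed", sep="\t", header=False, index=False)
    if "tetramer_table" in ctx.results:
        ctx.results["tetramer_table"].to_csv(outdir / "tetramer_zscores.tsv", sep="\t")
        ctx.results["profile_ua"].to_csv(outdir / "profile_ua.tsv", sep="\t", index=False)
        ctx.results["profile_ca"].to_csv(outdir / "profile_ca.tsv", sep="\t", index=False)
        ctx.results["maca"].to_csv(outdir / "maca_cooccurrence.tsv", sep="\t", index=False)
    if "hmm" in ctx.results:
        with open(outdir / "hmm_config.yaml", "w") as fh:
            yaml.safe_dump(ctx.results["hmm"].to_dict(), fh)
        anns = ctx.results["motif_annotations"]
        pd.DataFrame([
            dict(chrom=a.chrom, start=a.start, end=a.end, name=a.motif_type,
                 score=0, strand=a.strand)
            for a in anns
        ]).to_csv(outdir / "motif_annotations.bed", sep="\t", header=False, index=False)
    for quantity, key in [("enrichment", "metagene_enrichment"),
                          ("motifs", "metagene_motifs")]:
        if key in ctx.results:
            ctx.results[key].to_frame().to_csv(
                outdir / f"metagene_{quantity}.tsv", sep="\t", index=False)
    if "rankings" in ctx.results:
        rdir = outdir / "rankings"
        rdir.mkdir(exist_ok=True)
        for method, rs in ctx.results["rankings"].items():
            for r in rs:
                r.table.to_csv(rdir / f"{r.dataset_id}.tsv", sep="\t")
        ctx.results["intersection"].to_frame().to_csv(
            outdir / "intersection.tsv", sep="\t", index=False)
        pd.DataFrame({"transcript_id": sorted(ctx.results["intersection"].final)}) \
            .to_csv(outdir / "final_targets.tsv", sep="\t", index=False)
        ctx.results["clip_curve"].to_csv(outdir / "curve_clip.tsv", sep="\t", index=False)
        if "rip_curve" in ctx.results:
            ctx.results["rip_curve"].to_csv(outdir / "curve_rip.tsv", sep="\t", index=False)
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(ctx.results.get("summary", {}), fh, sort_keys=False)


def run_all(
    config: PipelineConfig,
    synth_config: synthetic_data.SyntheticConfig | None = None,
) -> RunContext:
    """Run every stage; if ``synth_config`` is given the dataset is
    simulated into ``data_dir`` first (reusing it if already present)."""
    outdir = Path(config.out_dir)
    data_dir = Path(config.data_dir)
    if synth_config is not None:
        if (data_dir / "manifest.yaml").exists():
            log.info("reusing existing dataset in %s", data_dir)
        else:
            with _timer("simulate"):
                synthetic_data.generate_dataset(synth_config, data_dir)
    with _timer("load"):
        ctx = load_stage(config)
    with _timer("coverage"):
        coverage_stage(ctx)
    with _timer("enrichment"):
        enrichment_stage(ctx)
    with _timer("clusters"):
        cluster_stage(ctx)
    with _timer("words"):
        word_stage(ctx)
    with _timer("metagene"):
        metagene_stage(ctx)
    with _timer("hmm"):
        hmm_stage(ctx, outdir)
    with _timer("ranking"):
        ranking_stage(ctx)
    with _timer("report"):
        report_stage(ctx)
        write_outputs(ctx, outdir)
    return ctx
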