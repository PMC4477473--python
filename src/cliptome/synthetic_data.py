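"""Synthetic transcriptome and CLIP/RIP/RNA-seq read simulator.

The generator emulates the statistical structure the analysis assumes: a
compact transcriptome with 5'UTR/CDS/3'UTR architecture, log-normal
gene-level expression, and an RNA-binding protein whose binding is 3'UTR
biased and concentrated at planted composite motifs (a UA-rich core
flanked by CA-rich repeat blocks) in a known subset of true target
transcripts. Replicate libraries are independent multinomial draws, so
replicate agreement is sampling-limited as in real data.

Model of binding used by ``simulate_clip``: a true target transcript's
overall CLIP sampling weight is multiplied by ``binding_enrichment``, so
the transcript-level CLIP enrichment of targets over non-targets is the
configured fold change; *within* a target 3'UTR a fraction
``motif_fraction`` of reads cross-link at the planted UA core (Gaussian
positional jitter, sd ``crosslink_offset_sd``), producing the read-start
pileup that defines cross-link regions. Genes are single exon: the
simulator emulates mature-mRNA-space signal, and spliced projection is
exercised against hand-built multi-exon models in the test-suite.

True targets are drawn among genes expressed clearly above the mean
(>1.3x), because CLIP/RIP can only rank transcripts that pass the
expression filter; drawing targets uniformly would cap recovery by
construction rather than by method performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation_io import TranscriptModel, GenomeSequence, reverse_complement
from .coverage import BED6_COLS

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    n_true_targets: int = 200
    # log-normal length parameters (mean of log, sd of log), minimum length
    utr5_len: tuple[float, float, int] = (np.log(150), 0.4, 30)
    cds_len: tuple[float, float, int] = (np.log(900), 0.4, 150)
    utr3_len: tuple[float, float, int] = (np.log(600), 0.5, 120)
    expression_lognorm: tuple[float, float] = (0.0, 1.0)
    target_expression_margin: float = 1.3   # targets drawn where expr > margin*mean
    # composite motif template: (CA)x ca_block, gap, UA core, gap, (CAA)x caa_block
    ca_block: int = 6
    ua_core: str = "UUAUU"
    caa_block: int = 4
    gap_range: tuple[int, int] = (5, 20)
    binding_enrichment: float = 5.0
    motif_fraction: float = 0.7
    region_weights: tuple[float, float, float] = (0.5, 0.5, 4.0)
    crosslink_offset_sd: float = 2.0
    read_length: int = 50
    rnaseq_library_size: int = 1_000_000
    clip_library_size: int = 400_000
    rip_library_size: int = 400_000
    replicates: int = 2
    cooperative_alpha: float | None = None  # tag rate per nt ~ utr3_len**alpha
    genes_per_chrom: int = 200
    gene_spacing: int = 1000
    seed: int = 0


@dataclass
class GroundTruth:
    targets: set[str]
    motif_spans: dict[str, tuple[int, int]]       # transcript coords, full template
    ua_core_spans: dict[str, tuple[int, int]]     # transcript coords, UA core
    expression: pd.Series = field(default_factory=pd.Series)
    expected_enrichment: pd.Series = field(default_factory=pd.Series)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid in self.expression.index:
            span = self.motif_spans.get(tid)
            core = self.ua_core_spans.get(tid)
            rows.append(dict(
                transcript_id=tid,
                is_target=tid in self.targets,
                motif_start=span[0] if span else -1,
                motif_end=span[1] if span else -1,
                core_start=core[0] if core else -1,
                core_end=core[1] if core else -1,
                expression=float(self.expression[tid]),
                expected_enrichment=float(self.expected_enrichment.get(tid, np.nan)),
            ))
        return pd.DataFrame(rows)


def _sample_lengths(rng, params, n):
    mu, sigma, lo = params
    return np.maximum(np.round(rng.lognormal(mu, sigma, n)).astype(int), lo)


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return _DNA[rng.integers(0, 4, n)].tobytes().decode()


def composite_template(config: SyntheticConfig, rng: np.random.Generator) -> tuple[str, tuple[int, int]]:
    """One realization of the planted template; returns (sequence,
    UA-core span within the template)."""
    g1 = int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
    g2 = int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
    gap1 = "".join(rng.choice(list("ACGU"), g1))
    gap2 = "".join(rng.choice(list("ACGU"), g2))
    left = "CA" * config.ca_block
    right = "CAA" * config.caa_block
    seq = left + gap1 + config.ua_core + gap2 + right
    core_start = len(left) + g1
    return seq, (core_start, core_start + len(config.ua_core))


def generate_transcriptome(
    config: SyntheticConfig,
    outdir: str | Path,
    rng: np.random.Generator | None = None,
) -> tuple[list[TranscriptModel], GenomeSequence, GroundTruth]:
    """Build a synthetic genome + annotation, write FASTA/GTF, and return
    transcript models, indexed genome and the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_genes
    u5 = _sample_lengths(rng, config.utr5_len, n)
    cds = _sample_lengths(rng, config.cds_len, n)
    u3 = _sample_lengths(rng, config.utr3_len, n)
    L = u5 + cds + u3
    expr = pd.Series(
        rng.lognormal(*config.expression_lognorm, n),
        index=[f"tx{i:05d}" for i in range(n)],
    )
    eligible = np.flatnonzero(
        expr.to_numpy() > config.target_expression_margin * expr.mean()
    )
    if eligible.size < config.n_true_targets:
        eligible = np.argsort(expr.to_numpy())[::-1][: max(config.n_true_targets, 1)]
    targets_idx = rng.choice(eligible, size=config.n_true_targets, replace=False)
    is_target = np.zeros(n, dtype=bool)
    is_target[targets_idx] = True

    strands = np.where(rng.random(n) < 0.5, "+", "-")
    models: list[TranscriptModel] = []
    motif_spans: dict[str, tuple[int, int]] = {}
    core_spans: dict[str, tuple[int, int]] = {}
    chrom_seqs: dict[str, str] = {}
    gi = 0
    chrom_idx = 0
    while gi < n:
        chrom = f"chrS{chrom_idx + 1}"
        parts: list[str] = []
        pos = 0
        for _ in range(min(config.genes_per_chrom, n - gi)):
            tid = expr.index[gi]
            ln = int(L[gi])
            # transcript-sense sequence (DNA letters; planted motifs use T for U)
            dna = _rand_dna(rng, ln)
            if is_target[gi]:
                utr3_start = int(u5[gi] + cds[gi])
                for _try in range(20):
                    tmpl, (c0, c1) = composite_template(config, rng)
                    if len(tmpl) <= int(u3[gi]):
                        break
                else:
                    raise RuntimeError(
                        f"{tid}: motif template longer than 3'UTR after retries"
                    )
                off = int(rng.integers(utr3_start, ln - len(tmpl) + 1)) \
                    if ln - len(tmpl) >= utr3_start else utr3_start
                t = tmpl.replace("U", "T")
                dna = dna[:off] + t + dna[off + len(t):]
                motif_spans[tid] = (off, off + len(t))
                core_spans[tid] = (off + c0, off + c1)
            genomic = dna if strands[gi] == "+" else reverse_complement(dna)
            parts.append(_rand_dna(rng, config.gene_spacing))
            start = pos + config.gene_spacing
            parts.append(genomic)
            end = start + ln
            if strands[gi] == "+":
                cds_span = (start + int(u5[gi]), start + int(u5[gi] + cds[gi]))
            else:
                cds_span = (start + int(u3[gi]), start + int(u3[gi] + cds[gi]))
            models.append(
                TranscriptModel(tid, f"g{tid[2:]}", chrom, strands[gi],
                                ((start, end),), cds_span)
            )
            pos = end
            gi += 1
        parts.append(_rand_dna(rng, config.gene_spacing))
        chrom_seqs[chrom] = "".join(parts)
        chrom_idx += 1

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in chrom_seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    write_gtf(models, outdir / "annotation.gtf")
    genome = GenomeSequence(fasta)

    truth = GroundTruth(
        targets={expr.index[i] for i in np.flatnonzero(is_target)},
        motif_spans=motif_spans,
        ua_core_spans=core_spans,
        expression=expr,
        expected_enrichment=pd.Series(
            np.where(is_target, config.binding_enrichment, 1.0), index=expr.index
        ),
    )
    return models, genome, truth


def write_gtf(models: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for a, b in m.exons:
                fh.write(f"{m.chrom}\tsynth\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}\n")
            if m.cds_span:
                a, b = m.cds_span
                fh.write(f"{m.chrom}\tsynth\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# Read simulation

def _reads_frame(models, gene_idx, t_starts, read_len, name):
    """Project transcript-space read starts to genomic BED6 rows."""
    chroms, starts, ends, strands = [], [], [], []
    for k, m in enumerate(models):
        mask = gene_idx == k
        if not mask.any():
            continue
        ts = t_starts[mask]
        te = np.minimum(ts + read_len, m.L)
        gstart, gend = m.span
        if m.strand == "+":
            gs, ge = gstart + ts, gstart + te
        else:
            ge, gs = gend - ts, gend - te
        chroms.append(np.full(ts.size, m.chrom, dtype=object))
        starts.append(gs)
        ends.append(ge)
        strands.append(np.full(ts.size, m.strand, dtype=object))
    if not chroms:
        return pd.DataFrame(columns=BED6_COLS)
    df = pd.DataFrame({
        "chrom": np.concatenate(chroms),
        "start": np.concatenate(starts).astype(np.int64),
        "end": np.concatenate(ends).astype(np.int64),
        "name": name,
        "score": 0,
        "strand": np.concatenate(strands),
    })
    return df[BED6_COLS]


def simulate_rnaseq(
    models: list[TranscriptModel],
    expression: pd.Series,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Uniform-coverage RNA-seq reads; per-gene counts multinomial with
    probabilities proportional to expression * length."""
    L = np.array([m.L for m in models])
    w = expression.reindex([m.transcript_id for m in models]).to_numpy() * L
    p = w / w.sum()
    counts = rng.multinomial(config.rnaseq_library_size, p)
    gene_idx = np.repeat(np.arange(len(models)), counts)
    max_start = np.maximum(L[gene_idx] - config.read_length, 0)
    t_starts = (rng.random(gene_idx.size) * (max_start + 1)).astype(np.int64)
    return _reads_frame(models, gene_idx, t_starts, config.read_length, "rnaseq")


def _region_sampler(m: TranscriptModel, weights) -> tuple[np.ndarray, np.ndarray]:
    """(per-region start offsets, probabilities) for region-weighted draws."""
    u5, cds, u3 = m.region_lengths
    lens = np.array([u5, cds, u3], dtype=float)
    w = lens * np.asarray(weights, float)
    total = w.sum()
    return lens, (w / total if total > 0 else np.array([0, 1.0, 0]))


def simulate_clip(
    models: list[TranscriptModel],
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One CLIP replicate: cross-link positions region-weighted, boosted on
    true targets and concentrated at planted UA cores (see module docs)."""
    L = np.array([m.L for m in models])
    tids = [m.transcript_id for m in models]
    expr = truth.expression.reindex(tids).to_numpy()
    region_w = np.array([
        np.dot(m.region_lengths, config.region_weights) for m in models
    ])
    boost = np.array([
        config.binding_enrichment if t in truth.targets else 1.0 for t in tids
    ])
    w = expr * region_w * boost
    if config.cooperative_alpha is not None:
        u3 = np.array([m.region_lengths[2] for m in models], dtype=float)
        w = w * np.maximum(u3, 1.0) ** config.cooperative_alpha
    counts = rng.multinomial(config.clip_library_size, w / w.sum())
    gene_idx_parts, xl_parts = [], []
    for k, m in enumerate(models):
        c = int(counts[k])
        if c == 0:
            continue
        tid = tids[k]
        lens, p_region = _region_sampler(m, config.region_weights)
        offsets = np.r_[0, np.cumsum(lens)][:3]
        core = truth.ua_core_spans.get(tid) if tid in truth.targets else None
        n_motif = rng.binomial(c, config.motif_fraction) if core else 0
        n_bg = c - n_motif
        xs = []
        if n_bg:
            reg = rng.choice(3, size=n_bg, p=p_region)
            u = rng.random(n_bg)
            xs.append((offsets[reg] + u * lens[reg]).astype(np.int64))
        if n_motif:
            center = (core[0] + core[1]) // 2
            jitter = rng.normal(0.0, config.crosslink_offset_sd, n_motif)
            x = np.clip(np.round(center + jitter), 0, m.L - 2).astype(np.int64)
            xs.append(x)
        x = np.concatenate(xs)
        x = np.clip(x, 0, m.L - 2)
        gene_idx_parts.append(np.full(x.size, k))
        xl_parts.append(x)
    gene_idx = np.concatenate(gene_idx_parts) if gene_idx_parts else np.empty(0, int)
    xl = np.concatenate(xl_parts) if xl_parts else np.empty(0, np.int64)
    # read starts one nucleotide 3' of the cross-link site (iCLIP truncation)
    t_starts = np.minimum(xl + 1, L[gene_idx] - 1)
    return _reads_frame(models, gene_idx, t_starts, config.read_length, "clip")


def simulate_rip(
    models: list[TranscriptModel],
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One RIP replicate: (IP, input). Input follows expression; IP weights
    true targets by binding_enrichment. Positions are uniform along the
    transcript (RIP carries no positional signal)."""
    L = np.array([m.L for m in models])
    tids = [m.transcript_id for m in models]
    expr = truth.expression.reindex(tids).to_numpy()
    base = expr * L
    boost = np.array([
        config.binding_enrichment if t in truth.targets else 1.0 for t in tids
    ])
    frames = []
    for w, name in [(base * boost, "rip_ip"), (base, "rip_input")]:
        counts = rng.multinomial(config.rip_library_size, w / w.sum())
        gene_idx = np.repeat(np.arange(len(models)), counts)
        max_start = np.maximum(L[gene_idx] - config.read_length, 0)
        t_starts = (rng.random(gene_idx.size) * (max_start + 1)).astype(np.int64)
        frames.append(_reads_frame(models, gene_idx, t_starts,
                                   config.read_length, name))
    return frames[0], frames[1]


# ---------------------------------------------------------------------------
# Full dataset

def generate_dataset(
    config: SyntheticConfig, outdir: str | Path
) -> dict:
    """Generate genome, annotation, ground truth and all replicate read
    sets on disk; returns the in-memory handles in a dict.

    Layout: genome.fa, annotation.gtf, ground_truth.tsv, manifest.yaml and
    BED6 read files rnaseq_rep*.bed, iclip_rep*.bed, pariclip_rep*.bed,
    rip_ip_rep*.bed, rip_input_rep*.bed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    models, genome, truth = generate_transcriptome(config, outdir, root)
    data: dict = dict(models=models, genome=genome, truth=truth, config=config,
                      reads={})
    for rep in range(1, config.replicates + 1):
        streams = {
            "rnaseq": simulate_rnaseq(models, truth.expression, config,
                                      np.random.default_rng([config.seed, 1, rep])),
            "iclip": simulate_clip(models, truth, config,
                                   np.random.default_rng([config.seed, 2, rep])),
            "pariclip": simulate_clip(models, truth, config,
                                      np.random.default_rng([config.seed, 3, rep])),
        }
        ip, inp = simulate_rip(models, truth, config,
                               np.random.default_rng([config.seed, 4, rep]))
        streams["rip_ip"], streams["rip_input"] = ip, inp
        for name, df in streams.items():
            df.to_csv(outdir / f"{name}_rep{rep}.bed", sep="\t",
                      header=False, index=False)
            data["reads"][f"{name}_rep{rep}"] = df
    truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    def _plain(v):
        if isinstance(v, tuple):
            return [_plain(x) for x in v]
        if isinstance(v, np.floating):
            return float(v)
        if isinstance(v, np.integer):
            return int(v)
        return v

    cfg = {k: _plain(v) for k, v in asdict(config).items()}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"config": cfg, "seed": config.seed}, fh)
    return data
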