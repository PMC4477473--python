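"""CLIP-tag cluster calling, segmentation, filtering, ranking and windows.

Clusters are maximal CLIP-covered runs on a transcript (nearby runs merged
across small gaps). Because CLIP clusters can span entire 3'UTRs, each
cluster is further segmented at sharp changes of the normalized enrichment
so that highly enriched sub-regions can be ranked separately from weakly
covered ones. The cross-link region of a segment is a small window at its
5' start (where iCLIP read starts pile up), with flanking windows on both
sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotation_io import TranscriptModel
from .coverage import CoverageTrack, EnrichmentTrack, ReadStartTrack

log = logging.getLogger(__name__)

REGION_NAMES = {0: "5utr", 1: "cds", 2: "3utr"}


@dataclass
class Cluster:
    transcript_id: str
    span: tuple[int, int]           # transcript half-open interval
    read_count: int                 # read starts within the span
    max_enrichment: float
    region: str                     # 5utr | cds | 3utr (majority base overlap)

    @property
    def start_position(self) -> int:
        return self.span[0]


@dataclass
class ClusterSegment:
    transcript_id: str
    parent_span: tuple[int, int]
    span: tuple[int, int]
    max_enrichment: float
    region: str = "3utr"
    read_count: int = 0


@dataclass
class CrossLinkWindows:
    transcript_id: str
    crosslink_region: tuple[int, int]
    flanks: tuple[tuple[int, int], tuple[int, int]]


def _majority_region(model: TranscriptModel, span: tuple[int, int]) -> str:
    lab = model.region_labels()[span[0]:span[1]]
    if lab.size == 0:
        return "cds"
    counts = np.bincount(lab, minlength=3)
    return REGION_NAMES[int(np.argmax(counts))]


def call_clusters(
    starts: ReadStartTrack,
    counts: CoverageTrack,
    model: TranscriptModel,
    enrich: EnrichmentTrack | None = None,
    gap_max: int = 15,
) -> list[Cluster]:
    """Maximal runs of covered positions, merging runs <= gap_max apart."""
    covered = counts.counts > 0
    if not covered.any():
        return []
    idx = np.flatnonzero(covered)
    breaks = np.flatnonzero(np.diff(idx) > gap_max + 1)
    run_starts = np.r_[idx[0], idx[breaks + 1]]
    run_ends = np.r_[idx[breaks] + 1, idx[-1] + 1]
    out = []
    for a, b in zip(run_starts, run_ends):
        a, b = int(a), int(b)
        max_e = float(enrich.e[a:b].max()) if enrich is not None and enrich.defined else 0.0
        out.append(
            Cluster(
                transcript_id=model.transcript_id,
                span=(a, b),
                read_count=int(starts.starts[a:b].sum()),
                max_enrichment=max_e,
                region=_majority_region(model, (a, b)),
            )
        )
    return out


def filter_clusters(
    clusters: list[Cluster],
    expression: dict[str, float],
    min_reads: int = 6,
    min_expression: float = 5.0,
) -> list[Cluster]:
    """Discard small clusters (< min_reads reads) and clusters on lowly
    expressed transcripts (< min_expression RNA-seq reads per nucleotide)."""
    return [
        c
        for c in clusters
        if c.read_count >= min_reads
        and expression.get(c.transcript_id, 0.0) >= min_expression
    ]


def _window_means(e: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Left/right w-nt window means at each interior boundary p in [w, n-w]."""
    c = np.r_[0.0, np.cumsum(e)]
    p = np.arange(w, e.size - w + 1)
    left = (c[p] - c[p - w]) / w
    right = (c[p + w] - c[p]) / w
    return p, np.stack([left, right])


def segment_cluster(
    cluster: Cluster,
    enrich: EnrichmentTrack,
    min_seg_len: int = 10,
    window: int = 10,
    ratio: float = 2.0,
    model: TranscriptModel | None = None,
) -> list[ClusterSegment]:
    """Split a cluster where the enrichment level changes sharply.

    A boundary is a candidate cut when the ratio of the adjacent
    ``window``-nt mean enrichments exceeds ``ratio`` (or falls below its
    reciprocal). Within each maximal run of consecutive candidates only the
    sharpest change (largest |log ratio|) is cut, so a single step edge
    yields a single boundary. Segments shorter than ``min_seg_len`` are
    merged into the neighbour with the closer mean. Segments always tile
    the parent span exactly.
    """
    a, b = cluster.span
    e = enrich.e[a:b]
    n = e.size
    cuts: list[int] = []
    if n >= 2 * window:
        eps = 1e-12
        p, (left, right) = _window_means(e, window)
        logr = np.log((right + eps) / (left + eps))
        cand = np.flatnonzero(np.abs(logr) > np.log(ratio))
        if cand.size:
            group_breaks = np.flatnonzero(np.diff(cand) > 1)
            groups = np.split(cand, group_breaks + 1)
            for g in groups:
                best = g[np.argmax(np.abs(logr[g]))]
                cuts.append(int(p[best]))
    bounds = [0] + sorted(set(cuts)) + [n]
    bounds = [x for i, x in enumerate(bounds) if i == 0 or x > bounds[i - 1]]
    segs = [(s, t) for s, t in zip(bounds, bounds[1:])]

    # merge too-short segments into the neighbour with the closer mean
    def seg_mean(seg: tuple[int, int]) -> float:
        return float(e[seg[0]:seg[1]].mean())

    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i, (s, t) in enumerate(segs):
            if t - s >= min_seg_len:
                continue
            m = seg_mean((s, t))
            cand_idx = []
            if i > 0:
                cand_idx.append(i - 1)
            if i < len(segs) - 1:
                cand_idx.append(i + 1)
            j = min(cand_idx, key=lambda k: abs(seg_mean(segs[k]) - m))
            lo = min(segs[i][0], segs[j][0])
            hi = max(segs[i][1], segs[j][1])
            segs[min(i, j)] = (lo, hi)
            del segs[max(i, j)]
            changed = True
            break

    out = []
    for s, t in segs:
        span = (a + s, a + t)
        # a segment's region is decided by its own bases, not the parent's:
        # a whole-transcript cluster still yields 3'UTR-labelled sub-segments
        region = _majority_region(model, span) if model is not None else cluster.region
        out.append(
            ClusterSegment(
                transcript_id=cluster.transcript_id,
                parent_span=cluster.span,
                span=span,
                max_enrichment=float(e[s:t].max()),
                region=region,
                read_count=cluster.read_count,
            )
        )
    return out


def rank_and_take(
    segments: list[ClusterSegment], n: int, region: str | None = "3utr"
) -> list[ClusterSegment]:
    """Top-n segments by max enrichment (optionally restricted to a region).

    Descending by max_enrichment; ties break by (transcript_id, span start)
    so the order is a permutation-stable total order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    pool = [s for s in segments if region is None or s.region == region]
    pool.sort(key=lambda s: (-s.max_enrichment, s.transcript_id, s.span[0]))
    if n > len(pool):
        log.info("requested %d segments, only %d available", n, len(pool))
    return pool[:n]


def crosslink_windows(
    segment: ClusterSegment | Cluster,
    L: int,
    halfwidth: int = 5,
    flank_extent: int = 50,
) -> CrossLinkWindows:
    """Cross-link region [s-hw, s+hw) at the segment's 5' start s, flanked
    by [s-flank, s-hw) and [s+hw, s+flank), all clipped to [0, L)."""
    s = segment.span[0]
    xl = (max(0, s - halfwidth), min(L, s + halfwidth))
    left = (max(0, s - flank_extent), xl[0])
    right = (xl[1], min(L, s + flank_extent))
    return CrossLinkWindows(segment.transcript_id, xl, (left, right))


def sample_background(
    models: dict[str, TranscriptModel],
    n: int,
    foreground: list[ClusterSegment],
    rng: np.random.Generator | int,
    clamp_lengths: bool = False,
) -> list[ClusterSegment]:
    """Random 3'UTR intervals, length-matched to the foreground segments.

    Lengths are resampled with replacement from the foreground length
    distribution; placement is uniform over 3'UTRs of the supplied
    (expressed) transcripts that can host the drawn length and that do not
    overlap a foreground segment on the same transcript.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if n == 0:
        return []
    lengths = np.array([s.span[1] - s.span[0] for s in foreground])
    if lengths.size == 0:
        raise ValueError("no foreground segments to match lengths against")
    utrs = []
    for tid, m in models.items():
        a, b = m.region_interval(2)
        if b > a:
            utrs.append((tid, a, b))
    if not utrs:
        raise ValueError("no 3'UTRs available")
    fg_by_tid: dict[str, list[tuple[int, int]]] = {}
    for s in foreground:
        fg_by_tid.setdefault(s.transcript_id, []).append(s.span)
    utrs.sort(key=lambda u: u[2] - u[1])
    utr_lens = np.array([b - a for _, a, b in utrs])
    max_utr = int(utr_lens[-1])
    out: list[ClusterSegment] = []
    n_overlapping = 0
    for _ in range(n):
        ln = int(lengths[rng.integers(lengths.size)])
        if ln > max_utr:
            # segments labelled 3'UTR by majority overlap can outgrow every
            # available UTR; callers may clamp instead of failing
            if not clamp_lengths:
                raise ValueError("foreground length exceeds every 3'UTR")
            ln = max_utr
        # sample uniformly among the UTRs that can host this length;
        # prefer placements avoiding foreground, fall back when the UTR
        # space is too densely covered to avoid it (dense desk-scale data)
        lo = int(np.searchsorted(utr_lens, ln))
        placed = None
        for attempt in range(100):
            tid, a, b = utrs[lo + int(rng.integers(len(utrs) - lo))]
            start = int(rng.integers(a, b - ln + 1))
            span = (start, start + ln)
            overlaps = any(
                span[0] < t and s < span[1] for s, t in fg_by_tid.get(tid, [])
            )
            if not overlaps or attempt == 99:
                placed = (tid, span)
                n_overlapping += overlaps
                break
        tid, span = placed
        out.append(
            ClusterSegment(
                transcript_id=tid, parent_span=span, span=span,
                max_enrichment=0.0, region="3utr",
            )
        )
    if n_overlapping:
        log.info("background sampling: %d/%d intervals overlap foreground "
                 "(UTR space densely covered)", n_overlapping, n)
    return out


def segments_to_bed6(
    segments: list[ClusterSegment],
    models: dict[str, TranscriptModel],
) -> "pd.DataFrame":
    """Genomic BED6 of segments: score = max enrichment x100, capped 1000.

    BED6 carries no blocks, so a segment spanning an intron is written as
    its enclosing genomic span.
    """
    import pandas as pd

    rows = []
    for s in segments:
        m = models[s.transcript_id]
        g = m.genomic_positions()[s.span[0]:s.span[1]]
        rows.append(dict(
            chrom=m.chrom, start=int(g.min()), end=int(g.max()) + 1,
            name=f"{s.transcript_id}:{s.span[0]}-{s.span[1]}",
            score=min(1000, int(round(s.max_enrichment * 100))),
            strand=m.strand,
        ))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


def expression_per_nt(rnaseq: CoverageTrack, model: TranscriptModel) -> float:
    """Average RNA-seq base calls per nucleotide over the transcript."""
    return float(rnaseq.counts.sum() / model.L) if model.L else 0.0
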