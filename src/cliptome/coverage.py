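"""Per-nucleotide base-call counting and enrichment normalization.

A mapped read set is a BED6-style DataFrame (chrom, start, end, name,
score, strand). Coverage is counted in spliced-transcript space: a read
contributes one base call to every exonic transcript position its genomic
interval covers. Libraries are stranded: only reads whose strand matches
the transcript's are counted toward it.

The central statistic is the per-position CLIP enrichment

    e_i = (M * L * c_i) / (N * sum_j r_j)

where c_i are CLIP base calls at transcript position i, N the total
confidently mapped CLIP reads in the library, r_j the RNA-seq base calls
over the transcript of spliced length L, and M the RNA-seq library size.
e_i == 1 means CLIP signal exactly proportional to transcript abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import TranscriptModel

log = logging.getLogger(__name__)

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=BED6_COLS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLS)


@dataclass
class CoverageTrack:
    transcript_id: str
    counts: np.ndarray          # length-L int vector of base calls
    library_size: int           # total mapped reads in the whole library
    library_role: str           # clip | rnaseq | rip_ip | rip_input

    def __post_init__(self) -> None:
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ReadStartTrack:
    transcript_id: str
    starts: np.ndarray          # inferred cross-link sites per position

    @property
    def total(self) -> int:
        return int(self.starts.sum())


@dataclass
class EnrichmentTrack:
    transcript_id: str
    e: np.ndarray               # per-position enrichment
    defined: bool = True        # False when the transcript has no RNA-seq signal


class LibraryIndex:
    """Fast per-transcript read lookup for one library.

    Reads are bucketed by (chrom, strand) and sorted by start so that the
    reads overlapping a genomic span are a contiguous slice (assuming a
    bounded read length, taken as the library's maximum).
    """

    def __init__(self, reads: pd.DataFrame, library_size: int | None = None):
        self.library_size = int(library_size if library_size is not None else len(reads))
        self._buckets: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self._max_len = 0
        if len(reads):
            self._max_len = int((reads["end"] - reads["start"]).max())
            for key, grp in reads.groupby(["chrom", "strand"], sort=False):
                s = grp["start"].to_numpy(np.int64)
                e = grp["end"].to_numpy(np.int64)
                order = np.argsort(s, kind="stable")
                self._buckets[key] = (s[order], e[order])

    def overlapping(self, model: TranscriptModel) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of same-strand reads overlapping the model span."""
        bucket = self._buckets.get((model.chrom, model.strand))
        if bucket is None:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        s, e = bucket
        a, b = model.span
        lo = np.searchsorted(s, a - self._max_len, side="left")
        hi = np.searchsorted(s, b, side="left")
        s, e = s[lo:hi], e[lo:hi]
        keep = e > a
        return s[keep], e[keep]


def _exon_offsets(model: TranscriptModel) -> list[tuple[int, int, int]]:
    """(genomic_start, genomic_end, transcript_offset) per exon, 5'->3'."""
    exons = model.exons if model.strand == "+" else model.exons[::-1]
    out, off = [], 0
    for a, b in exons:
        out.append((a, b, off))
        off += b - a
    return out


def _project_intervals(
    model: TranscriptModel, s: np.ndarray, e: np.ndarray
) -> np.ndarray:
    """Accumulate genomic read intervals into a transcript coverage vector."""
    diff = np.zeros(model.L + 1, dtype=np.int64)
    for a, b, off in _exon_offsets(model):
        lo = np.maximum(s, a)
        hi = np.minimum(e, b)
        m = hi > lo
        if not m.any():
            continue
        lo, hi = lo[m], hi[m]
        if model.strand == "+":
            t0, t1 = off + lo - a, off + hi - a
        else:
            t0, t1 = off + (b - hi), off + (b - lo)
        np.add.at(diff, t0, 1)
        np.add.at(diff, t1, -1)
    return np.cumsum(diff[:-1])


def count_base_calls(
    reads: pd.DataFrame | LibraryIndex,
    model: TranscriptModel,
    library_size: int | None = None,
    library_role: str = "clip",
) -> CoverageTrack:
    """Count per-position base calls on one transcript from one library.

    ``library_size`` defaults to the number of reads in the input (the whole
    library, not just this transcript). Reads on other chromosomes/strands
    are ignored; no deduplication happens here.
    """
    index = reads if isinstance(reads, LibraryIndex) else LibraryIndex(reads, library_size)
    s, e = index.overlapping(model)
    counts = _project_intervals(model, s, e)
    n = library_size if library_size is not None else index.library_size
    return CoverageTrack(model.transcript_id, counts, n, library_role)


def crosslink_starts(
    reads: pd.DataFrame | LibraryIndex, model: TranscriptModel
) -> ReadStartTrack:
    """Infer cross-link sites: one nucleotide 5' of each read's first base.

    iCLIP truncation places the cross-linked nucleotide immediately upstream
    of the read start; a read starting at transcript position 0 is clamped
    to 0. Reads whose first base is intronic are skipped.
    """
    index = reads if isinstance(reads, LibraryIndex) else LibraryIndex(reads)
    s, e = index.overlapping(model)
    first = s if model.strand == "+" else e - 1
    starts = np.zeros(model.L, dtype=np.int64)
    assigned = 0
    for a, b, off in _exon_offsets(model):
        m = (first >= a) & (first < b)
        if not m.any():
            continue
        g = first[m]
        t = off + (g - a) if model.strand == "+" else off + (b - 1 - g)
        site = np.maximum(t - 1, 0)
        np.add.at(starts, site, 1)
        assigned += int(m.sum())
    skipped = len(first) - assigned
    if skipped:
        log.debug("%s: %d reads with intronic first base skipped",
                  model.transcript_id, skipped)
    return ReadStartTrack(model.transcript_id, starts)


def enrichment(
    clip: CoverageTrack, rnaseq: CoverageTrack, model: TranscriptModel
) -> EnrichmentTrack:
    """Per-position enrichment e_i = M*L*c_i / (N * sum r_j).

    Undefined (flagged, not zero) when the transcript has no RNA-seq signal.
    """
    if model.L == 0:
        raise ValueError(f"{model.transcript_id}: zero-length transcript")
    if clip.transcript_id != rnaseq.transcript_id:
        raise ValueError("tracks are for different transcripts")
    r_sum = rnaseq.counts.sum()
    if r_sum == 0:
        return EnrichmentTrack(model.transcript_id, np.zeros(model.L), defined=False)
    M, N, L = rnaseq.library_size, clip.library_size, model.L
    e = (M * L * clip.counts.astype(float)) / (N * float(r_sum))
    return EnrichmentTrack(model.transcript_id, e, defined=True)


def mean_region_enrichment(track: EnrichmentTrack, model: TranscriptModel,
                           region: int = 2) -> float:
    """Mean e_i over one region (default 3'UTR); NaN if undefined/empty."""
    if not track.defined:
        return float("nan")
    a, b = model.region_interval(region)
    if b <= a:
        return float("nan")
    return float(track.e[a:b].mean())


def rip_enrichment_factor(
    ip: CoverageTrack, inp: CoverageTrack, model: TranscriptModel
) -> float:
    """Whole-transcript RIP ratio (IP fraction of library) / (input fraction).

    Per-nucleotide and whole-transcript forms coincide: the transcript
    length cancels. NaN when the input has no signal on the transcript.
    """
    if ip.transcript_id != inp.transcript_id:
        raise ValueError("tracks are for different transcripts")
    inp_sum = inp.counts.sum()
    if inp_sum == 0:
        return float("nan")
    return float((ip.counts.sum() / ip.library_size) / (inp_sum / inp.library_size))


def collapse_duplicates(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse identical (chrom, start, strand) records to one read.

    PCR-duplicate collapsing normally happens upstream (barcoded iCLIP
    protocols); this flag-style helper exists for synthetic-data realism.
    """
    return reads.drop_duplicates(subset=["chrom", "start", "strand"]).reset_index(drop=True)


def write_enrichment_tsv(
    tracks: dict[str, EnrichmentTrack], path: str | Path
) -> None:
    """Per-position enrichment in transcript space (long TSV)."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\tenrichment\n")
        for tid, t in tracks.items():
            if not t.defined:
                continue
            for i, v in enumerate(t.e):
                fh.write(f"{tid}\t{i}\t{v:g}\n")


def write_enrichment_bedgraph(
    tracks: dict[str, EnrichmentTrack],
    models: dict[str, TranscriptModel],
    path: str | Path,
) -> None:
    """Genomic-projection bedGraph of enrichment (equal-value runs merged).

    Positions covered by no transcript are omitted; minus-strand values
    project onto the forward genomic axis as is usual for bedGraph.
    """
    rows: list[tuple[str, int, int, float]] = []
    for tid, t in tracks.items():
        if not t.defined:
            continue
        m = models[tid]
        g = m.genomic_positions()
        order = np.argsort(g)
        gpos, vals = g[order], t.e[order]
        run_start = 0
        for i in range(1, len(gpos) + 1):
            if (i == len(gpos) or gpos[i] != gpos[i - 1] + 1
                    or vals[i] != vals[run_start]):
                if vals[run_start] != 0:
                    rows.append((m.chrom, int(gpos[run_start]),
                                 int(gpos[i - 1]) + 1, float(vals[run_start])))
                run_start = i
    rows.sort()
    with open(path, "w") as fh:
        for chrom, a, b, v in rows:
            fh.write(f"{chrom}\t{a}\t{b}\t{v:g}\n")


def coverage_fractions(
    index: LibraryIndex, models: list[TranscriptModel]
) -> dict[str, float]:
    """Fraction of spliced positions with >=1 base call, per transcript."""
    out = {}
    for m in models:
        s, e = index.overlapping(m)
        cov = _project_intervals(m, s, e)
        out[m.transcript_id] = float((cov > 0).mean()) if m.L else 0.0
    return out
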