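"""Transcript models, genome sequence access, and coordinate projection.

Transcript coordinates are 0-based, half-open, and run 5'->3' in transcript
orientation (position 0 is the transcript's 5' end regardless of genomic
strand). Genomic coordinates are 0-based half-open BED-style throughout;
GTF input is converted on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """DNA sense-strand string -> RNA alphabet (T->U), uppercased."""
    return seq.upper().replace("T", "U")


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript with coordinate maps.

    ``exons`` are genomic half-open intervals, stored sorted by genomic
    start; ``cds_span`` is the genomic [start, end) of the coding region or
    ``None`` for non-coding transcripts. Region lengths partition the
    spliced length ``L`` into 5'UTR / CDS / 3'UTR.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_span: tuple[int, int] | None = None
    _tx2gen: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b) in exons:
            if b <= a:
                raise ValueError(f"{self.transcript_id}: empty exon [{a},{b})")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 < b0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons
        # genomic position of each transcript coordinate, 5'->3'
        blocks = [np.arange(a, b) for a, b in exons]
        gpos = np.concatenate(blocks) if blocks else np.empty(0, dtype=int)
        if self.strand == "-":
            gpos = gpos[::-1]
        self._tx2gen = gpos
        if self.cds_span is not None:
            ca, cb = self.cds_span
            inside = self._exonic_mask(np.array([ca, cb - 1]))
            if not inside.all():
                raise ValueError(
                    f"{self.transcript_id}: CDS [{ca},{cb}) not inside exons"
                )

    # -- basic geometry ---------------------------------------------------
    @property
    def L(self) -> int:
        return int(self._tx2gen.size)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    def _exonic_mask(self, gpos: np.ndarray) -> np.ndarray:
        mask = np.zeros(gpos.shape, dtype=bool)
        for a, b in self.exons:
            mask |= (gpos >= a) & (gpos < b)
        return mask

    # -- region partition -------------------------------------------------
    def region_labels(self) -> np.ndarray:
        """Per-transcript-position label: 0=5'UTR, 1=CDS, 2=3'UTR.

        Non-coding transcripts are labelled entirely 3'UTR-free: all
        positions get 1 (treated as a single unpartitioned body).
        """
        lab = np.ones(self.L, dtype=np.int8)
        if self.cds_span is None:
            return lab
        ca, cb = self.cds_span
        g = self._tx2gen
        in_cds = (g >= ca) & (g < cb)
        idx = np.flatnonzero(in_cds)
        lab[: idx[0]] = 0
        lab[idx[-1] + 1 :] = 2
        return lab

    @property
    def region_lengths(self) -> tuple[int, int, int]:
        if self.cds_span is None:
            return (0, self.L, 0)
        lab = self.region_labels()
        return (int((lab == 0).sum()), int((lab == 1).sum()), int((lab == 2).sum()))

    def region_interval(self, region: int) -> tuple[int, int]:
        """Transcript [start, end) of region 0/1/2; empty interval if absent."""
        lab = self.region_labels()
        idx = np.flatnonzero(lab == region)
        if idx.size == 0:
            return (0, 0)
        return (int(idx[0]), int(idx[-1]) + 1)

    # -- coordinate maps ----------------------------------------------------
    def to_genomic_coords(self, t: int) -> int:
        return int(self._tx2gen[t])

    def genomic_positions(self) -> np.ndarray:
        """Genomic position of each transcript coordinate (read-only view)."""
        return self._tx2gen

    def to_transcript_coords(
        self, start: int, end: int
    ) -> tuple[int, int] | None:
        """Project a genomic interval to spliced-transcript coordinates.

        Returns the smallest transcript interval containing all exonic bases
        of [start, end), or None if the interval is entirely intronic or
        outside the transcript.
        """
        g = self._tx2gen
        hit = np.flatnonzero((g >= start) & (g < end))
        if hit.size == 0:
            return None
        return int(hit[0]), int(hit[-1]) + 1

    def transcript_mask(self, start: int, end: int) -> np.ndarray:
        """Boolean over transcript positions covered by genomic [start,end)."""
        g = self._tx2gen
        return (g >= start) & (g < end)


class GenomeSequence:
    """Indexed FASTA accessor with strand-aware, RNA-space extraction."""

    def __init__(self, fasta_path: str | Path):
        self._fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    @property
    def chroms(self) -> list[str]:
        return list(self._fa.keys())

    def chrom_length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """DNA sequence of genomic [start,end); minus strand -> revcomp."""
        seq = str(self._fa[chrom][start:end])
        return reverse_complement(seq) if strand == "-" else seq

    def fetch_rna(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        return to_rna(self.fetch(chrom, start, end, strand))

    def transcript_sequence(self, model: TranscriptModel, rna: bool = True) -> str:
        parts = [str(self._fa[model.chrom][a:b]) for a, b in model.exons]
        seq = "".join(parts)
        if model.strand == "-":
            seq = reverse_complement(seq)
        return to_rna(seq) if rna else seq


# ---------------------------------------------------------------------------
# Annotation parsing

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path: Path) -> list[TranscriptModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "chrom", "source", "feature", "start", "end",
            "score", "strand", "frame", "attributes",
        ],
        dtype={"chrom": str},
    )
    df = df[df["feature"].isin(["exon", "CDS"])]
    models: list[TranscriptModel] = []
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        attrs = dict(_ATTR_RE.findall(row.attributes))
        tid = attrs.get("transcript_id")
        gid = attrs.get("gene_id", tid)
        if tid is None:
            raise ValueError(f"{path}: record {i}: missing transcript_id attribute")
        # GTF is 1-based closed; convert to 0-based half-open
        iv = (int(row.start) - 1, int(row.end))
        meta.setdefault(tid, (gid, row.chrom, row.strand))
        (exons if row.feature == "exon" else cds).setdefault(tid, []).append(iv)
    for tid, (gid, chrom, strand) in meta.items():
        if tid not in exons:
            continue
        cds_span = None
        if tid in cds:
            ivs = cds[tid]
            cds_span = (min(a for a, _ in ivs), max(b for _, b in ivs))
        try:
            models.append(
                TranscriptModel(tid, gid, chrom, strand, tuple(exons[tid]), cds_span)
            )
        except ValueError as exc:
            log.warning("dropping transcript %s: %s", tid, exc)
    return models


def _parse_bed12(path: Path) -> list[TranscriptModel]:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, dtype={"chrom": str})
    models = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
            starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
            exons = tuple(
                (row.start + s, row.start + s + sz) for s, sz in zip(starts, sizes)
            )
            thick = (int(row.thickStart), int(row.thickEnd))
            cds_span = None if thick[0] >= thick[1] else thick
            models.append(
                TranscriptModel(
                    str(row.name), str(row.name), row.chrom, row.strand,
                    exons, cds_span,
                )
            )
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"{path}: line {i + 1}: unparsable BED12 record: {exc}")
    return models


def load_annotation(
    annotation_path: str | Path, genome_path: str | Path
) -> tuple[list[TranscriptModel], GenomeSequence]:
    """Load a GTF or BED12 annotation plus an indexed FASTA genome.

    Transcripts whose CDS falls outside their exons are dropped with a
    warning; transcripts on chromosomes absent from the genome raise.
    """
    annotation_path = Path(annotation_path)
    genome = GenomeSequence(genome_path)
    if annotation_path.suffix.lower() in {".bed", ".bed12"}:
        models = _parse_bed12(annotation_path)
    else:
        models = _parse_gtf(annotation_path)
    known = set(genome.chroms)
    for m in models:
        if m.chrom not in known:
            raise ValueError(f"annotation chromosome {m.chrom!r} not in genome")
    return models, genome


def group_by_gene(models: Iterable[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    return by_gene


def pick_representative(
    models: Iterable[TranscriptModel],
    coverage_fraction: Mapping[str, float],
    min_coverage: float = 0.30,
) -> dict[str, TranscriptModel]:
    """One representative per gene: the longest protein-coding isoform with
    RNA-seq coverage (fraction of spliced positions with >=1 base call) of
    at least ``min_coverage``. Ties on length break by smallest
    transcript_id. Genes with no qualifying isoform are omitted.
    """
    reps: dict[str, TranscriptModel] = {}
    for gene, isoforms in group_by_gene(models).items():
        candidates = [
            m
            for m in isoforms
            if m.is_coding
            and coverage_fraction.get(m.transcript_id, 0.0) >= min_coverage
        ]
        if not candidates:
            continue
        candidates.sort(key=lambda m: (-m.L, m.transcript_id))
        reps[gene] = candidates[0]
    return reps


def write_transcript_table(models: Sequence[TranscriptModel], path: str | Path) -> None:
    rows = []
    for m in models:
        u5, c, u3 = m.region_lengths
        rows.append(
            dict(
                transcript_id=m.transcript_id, gene_id=m.gene_id, chrom=m.chrom,
                strand=m.strand, L=m.L, len_5utr=u5, len_cds=c, len_3utr=u3,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
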