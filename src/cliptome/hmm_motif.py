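"""Composite CA/UA motif annotation with a small hand-set HMM.

The model has a uniform background state plus two 2-state motif modules:
a CA module (states emitting C and A, wired to generate CA and CAA
repeats) and a UA module (states emitting U and A, generating UA/UU-rich
cores). A single parameter t1 (default 0.95) is the probability of
staying inside the current motif module; its mass is shared uniformly
over the allowed intra-module transitions, and 1-t1 exits to background,
making motif length geometric with mean 1/(1-t1) = 20 nt. Each motif
state emits its designated letter with probability 0.9 and every other
letter with 0.1/3.

Viterbi decoding produces maximum-probability state paths; maximal runs
of one module become CA or UA instances, and alternating instances at
most 50 nt apart are merged into composite sites (lone instances are
discarded). The topology is data, not code: a different state diagram is
a config change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotation_io import GenomeSequence, TranscriptModel

log = logging.getLogger(__name__)

_BASES = "ACGU"
_OBS_CODE = np.full(128, 4, dtype=np.uint8)  # 4 = unknown -> uniform emission
for _i, _c in enumerate(_BASES):
    _OBS_CODE[ord(_c)] = _i
    _OBS_CODE[ord(_c.lower())] = _i
_OBS_CODE[ord("T")] = 3
_OBS_CODE[ord("t")] = 3


@dataclass
class CompositeMotifHMM:
    """HMM over {background, motif-module} states with explicit tables."""

    state_names: tuple[str, ...]
    modules: tuple[str | None, ...]       # None = background, else module label
    transitions: np.ndarray               # (S, S), rows sum to 1
    emissions: np.ndarray                 # (S, 4) over A,C,G,U
    t1: float = 0.95
    emit_main: float = 0.9
    _log_trans: np.ndarray = field(init=False, repr=False)
    _log_emit: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.transitions, float)
        E = np.asarray(self.emissions, float)
        if not np.allclose(A.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if not np.allclose(E.sum(axis=1), 1.0):
            raise ValueError("emission rows must sum to 1")
        self.transitions, self.emissions = A, E
        with np.errstate(divide="ignore"):
            self._log_trans = np.log(A)
            # column 4: unknown observation, uniformly uninformative
            self._log_emit = np.log(
                np.column_stack([E, np.full(E.shape[0], 0.25)])
            )

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def log_initial(self) -> np.ndarray:
        # uniform start: chunked genome decoding makes "start" arbitrary
        return np.full(self.n_states, -np.log(self.n_states))

    def to_dict(self) -> dict:
        return dict(
            t1=float(self.t1),
            emit_main=float(self.emit_main),
            states=list(self.state_names),
            modules=[m if m is not None else "background" for m in self.modules],
            transitions=[[float(x) for x in row] for row in self.transitions],
            emissions=[[float(x) for x in row] for row in self.emissions],
        )

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeMotifHMM":
        return cls(
            state_names=tuple(d["states"]),
            modules=tuple(None if m == "background" else m for m in d["modules"]),
            transitions=np.array(d["transitions"], float),
            emissions=np.array(d["emissions"], float),
            t1=float(d["t1"]),
            emit_main=float(d["emit_main"]),
        )


def build_hmm(t1: float = 0.95, emit_main: float = 0.9) -> CompositeMotifHMM:
    """Default 5-state topology: B, C_ca, A_ca, U_ua, A_ua.

    B emits uniformly and moves to {B, C_ca, U_ua} with probability 1/3
    each. Motif states keep probability t1 inside their module (shared
    uniformly over allowed intra-module moves) and exit to B with 1-t1:
    C_ca -> A_ca only (forcing CA/CAA alternation); A_ca -> {C_ca, A_ca};
    U_ua and A_ua -> {U_ua, A_ua}.
    """
    if not (0.0 < t1 < 1.0):
        raise ValueError("t1 must be in (0, 1)")
    if not (0.25 < emit_main <= 1.0):
        raise ValueError("emit_main must be in (0.25, 1]")
    names = ("B", "C_ca", "A_ca", "U_ua", "A_ua")
    modules = (None, "CA", "CA", "UA", "UA")
    S = len(names)
    A = np.zeros((S, S))
    B, C_CA, A_CA, U_UA, A_UA = range(S)
    A[B, [B, C_CA, U_UA]] = 1 / 3
    A[C_CA, A_CA] = t1
    A[C_CA, B] = 1 - t1
    A[A_CA, [C_CA, A_CA]] = t1 / 2
    A[A_CA, B] = 1 - t1
    for s in (U_UA, A_UA):
        A[s, [U_UA, A_UA]] = t1 / 2
        A[s, B] = 1 - t1
    rest = (1 - emit_main) / 3
    E = np.full((S, 4), 0.25)
    for s, letter in [(C_CA, "C"), (A_CA, "A"), (U_UA, "U"), (A_UA, "A")]:
        E[s] = rest
        E[s, _BASES.index(letter)] = emit_main
    return CompositeMotifHMM(names, modules, A, E, t1=t1, emit_main=emit_main)


# ---------------------------------------------------------------------------
# Viterbi decoding

def encode_observations(seq: str) -> np.ndarray:
    return _OBS_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def viterbi(hmm: CompositeMotifHMM, seq: str) -> np.ndarray:
    """Maximum-probability state path (log space); ties prefer the lowest
    state index, i.e. background."""
    if not seq:
        return np.empty(0, dtype=np.int64)
    return viterbi_batch(hmm, [seq])[0]


def viterbi_batch(hmm: CompositeMotifHMM, seqs: list[str]) -> list[np.ndarray]:
    """Decode many sequences, vectorizing the DP across same-length groups."""
    out: list[np.ndarray | None] = [None] * len(seqs)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    logA = hmm._log_trans
    logE = hmm._log_emit
    S = hmm.n_states
    for T, idxs in by_len.items():
        if T == 0:
            for i in idxs:
                out[i] = np.empty(0, dtype=np.int64)
            continue
        n = len(idxs)
        obs = np.stack([encode_observations(seqs[i]) for i in idxs])
        delta = hmm.log_initial[None, :] + logE[:, obs[:, 0]].T
        bp = np.zeros((n, T, S), dtype=np.uint8)
        for t in range(1, T):
            cand = delta[:, :, None] + logA[None, :, :]   # (n, from, to)
            bp[:, t] = np.argmax(cand, axis=1)
            delta = np.max(cand, axis=1) + logE[:, obs[:, t]].T
        path = np.empty((n, T), dtype=np.int64)
        path[:, -1] = np.argmax(delta, axis=1)
        rows = np.arange(n)
        for t in range(T - 1, 0, -1):
            path[:, t - 1] = bp[rows, t, path[:, t]]
        for k, i in enumerate(idxs):
            out[i] = path[k]
    return out  # type: ignore[return-value]


def path_log_probability(hmm: CompositeMotifHMM, seq: str, path: np.ndarray) -> float:
    """Log probability of one (path, sequence) pair under the model."""
    obs = encode_observations(seq)
    if len(path) != len(obs):
        raise ValueError("path/sequence length mismatch")
    if len(path) == 0:
        return 0.0
    s = hmm.log_initial[path[0]]
    s = s + hmm._log_emit[path[0], obs[0]]
    for t in range(1, len(path)):
        s = s + hmm._log_trans[path[t - 1], path[t]]
        s = s + hmm._log_emit[path[t], obs[t]]
    return float(s)


# ---------------------------------------------------------------------------
# Post-processing

@dataclass
class MotifAnnotation:
    start: int
    end: int
    motif_type: str                     # CA | UA | composite
    strand: str = "+"
    chrom: str | None = None
    components: tuple[tuple[int, int, str], ...] = ()

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def decode_motifs(
    hmm: CompositeMotifHMM, path: np.ndarray, min_len: int = 4,
    bridge_gap: int = 3,
) -> list[MotifAnnotation]:
    """Maximal same-module state runs -> CA / UA instances.

    Same-module runs separated by at most ``bridge_gap`` background
    positions are bridged into one instance first (runs closer than a
    tetramer are not independent instances); runs still shorter than
    ``min_len`` are then dropped.
    """
    modules = np.array(
        [m if m is not None else "" for m in hmm.modules], dtype=object
    )
    if path.size == 0:
        return []
    lab = modules[path]
    runs: list[list] = []  # [start, end, module]
    i = 0
    n = path.size
    while i < n:
        j = i
        while j < n and lab[j] == lab[i]:
            j += 1
        if lab[i]:
            runs.append([i, j, str(lab[i])])
        i = j
    bridged: list[list] = []
    for r in runs:
        if bridged and r[2] == bridged[-1][2] and r[0] - bridged[-1][1] <= bridge_gap:
            bridged[-1][1] = r[1]
        else:
            bridged.append(r)
    return [
        MotifAnnotation(a, b, t) for a, b, t in bridged if b - a >= min_len
    ]


def merge_composites(
    instances: list[MotifAnnotation], max_gap: int = 50
) -> list[MotifAnnotation]:
    """Merge alternating-type instance chains (gap <= max_gap) into
    composite sites; instances in no chain of length >= 2 are dropped.

    Same-type instances closer than ``max_gap`` are first coalesced into
    one instance (a motif element decoded as two nearby runs is one
    element, and same-type pairs alone never form a composite), so the
    chain step only ever sees alternating neighbours.
    """
    inst = sorted(instances, key=lambda m: (m.start, m.end))
    coalesced: list[MotifAnnotation] = []
    for m in inst:
        prev = coalesced[-1] if coalesced else None
        if (prev is not None and m.motif_type == prev.motif_type
                and m.start - prev.end <= max_gap):
            coalesced[-1] = MotifAnnotation(
                prev.start, max(prev.end, m.end), prev.motif_type,
                strand=prev.strand, chrom=prev.chrom)
        else:
            coalesced.append(m)
    inst = coalesced
    out: list[MotifAnnotation] = []
    chain: list[MotifAnnotation] = []

    def flush() -> None:
        if len(chain) >= 2:
            out.append(
                MotifAnnotation(
                    chain[0].start, chain[-1].end, "composite",
                    strand=chain[0].strand, chrom=chain[0].chrom,
                    components=tuple(
                        (m.start, m.end, m.motif_type) for m in chain
                    ),
                )
            )
        chain.clear()

    for m in inst:
        if chain and (
            m.motif_type == chain[-1].motif_type
            or m.start - chain[-1].end > max_gap
        ):
            flush()
        chain.append(m)
    flush()
    return out


def annotate_sequence(
    hmm: CompositeMotifHMM, seq: str, min_len: int = 4, max_gap: int = 50
) -> list[MotifAnnotation]:
    """Viterbi -> instances -> composites for one sequence."""
    path = viterbi(hmm, seq)
    return merge_composites(decode_motifs(hmm, path, min_len), max_gap)


def annotate_genome(
    hmm: CompositeMotifHMM,
    genome: GenomeSequence,
    both_strands: bool = True,
    chunk_size: int = 100_000,
    overlap: int = 500,
    min_len: int = 4,
    max_gap: int = 50,
) -> list[MotifAnnotation]:
    """Composite-motif annotations over a whole genome, both strands.

    Chromosomes are decoded in overlapping chunks; instances touching a
    chunk edge (possibly truncated) are dropped because the overlap
    guarantees they re-appear intact in the neighbouring chunk. Identical
    instances from overlapping chunks are deduplicated before merging.
    """
    if overlap < 200:
        raise ValueError("chunk overlap must be >= 200 nt")
    out: list[MotifAnnotation] = []
    strands = "+-" if both_strands else "+"
    for chrom in genome.chroms:
        clen = genome.chrom_length(chrom)
        for strand in strands:
            seen: set[tuple[int, int, str]] = set()
            instances: list[MotifAnnotation] = []
            step = max(chunk_size - overlap, 1)
            bounds = []
            for cstart in range(0, clen, step):
                bounds.append((cstart, min(cstart + chunk_size, clen)))
                if bounds[-1][1] >= clen:
                    break
            chunk_seqs = [genome.fetch_rna(chrom, a, b, strand) for a, b in bounds]
            paths = viterbi_batch(hmm, chunk_seqs)
            for (cstart, cend), path in zip(bounds, paths):
                for m in decode_motifs(hmm, path, min_len):
                    if strand == "+":
                        g0, g1 = cstart + m.start, cstart + m.end
                    else:
                        g0 = cstart + (cend - cstart) - m.end
                        g1 = cstart + (cend - cstart) - m.start
                    truncated = (
                        (m.start == 0 and cstart > 0)
                        or (m.end == cend - cstart and cend < clen)
                    )
                    if truncated:
                        continue
                    key = (g0, g1, m.motif_type)
                    if key in seen:
                        continue
                    seen.add(key)
                    instances.append(
                        MotifAnnotation(g0, g1, m.motif_type, strand, chrom)
                    )
            out.extend(merge_composites(instances, max_gap))
    return out


def count_motifs_per_transcript(
    annotations: list[MotifAnnotation],
    models: dict[str, TranscriptModel],
) -> tuple[dict[str, dict], dict[str, np.ndarray]]:
    """Composite counts and densities per transcript region.

    A composite straddling a region boundary counts toward the region
    holding the majority of its exonic bases. Also returns a per-nucleotide
    composite-coverage track per transcript (how many composites cover each
    position) for metagene profiling.
    """
    by_chrom: dict[tuple[str, str], list[MotifAnnotation]] = {}
    for a in annotations:
        by_chrom.setdefault((a.chrom, a.strand), []).append(a)
    for lst in by_chrom.values():
        lst.sort(key=lambda a: a.start)
    stats: dict[str, dict] = {}
    tracks: dict[str, np.ndarray] = {}
    for tid, model in models.items():
        anns = by_chrom.get((model.chrom, model.strand), [])
        span_a, span_b = model.span
        starts = np.array([a.start for a in anns])
        lo = int(np.searchsorted(starts, span_a - 10_000)) if anns else 0
        labels = model.region_labels()
        track = np.zeros(model.L, dtype=np.int64)
        counts = np.zeros(3, dtype=np.int64)
        for a in anns[lo:]:
            if a.start >= span_b:
                break
            if a.end <= span_a:
                continue
            mask = model.transcript_mask(a.start, a.end)
            if not mask.any():
                continue
            track += mask
            region_votes = np.bincount(labels[mask], minlength=3)
            counts[int(np.argmax(region_votes))] += 1
        u5, cds, u3 = model.region_lengths
        stats[tid] = dict(
            n_5utr=int(counts[0]), n_cds=int(counts[1]), n_3utr=int(counts[2]),
            density_5utr=counts[0] / u5 if u5 else float("nan"),
            density_cds=counts[1] / cds if cds else float("nan"),
            density_3utr=counts[2] / u3 if u3 else float("nan"),
        )
        tracks[tid] = track
    return stats, tracks
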