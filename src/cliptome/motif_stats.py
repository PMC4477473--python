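"""Positional k-mer statistics around CLIP cross-link regions.

Tetramer (4-mer) occurrences are counted separately in cross-link regions
and flanks of enriched cluster segments and turned into Z-scores against
repeatedly resampled background intervals from 3'UTRs. KH-domain proteins
read tetranucleotides, which motivates the word length. A positional
profile aligned at segment starts shows where word families sit relative
to the cross-link site, and a lag histogram of MACA (M = A or C) matches
exposes the periodic repeat structure of CA-rich elements.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import CrossLinkWindows

log = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"
UA_WORDS = ("UAUA", "AUAU", "AUUU", "UAUU", "UUAU", "UUUU")
CA_WORDS = ("ACAC", "CACA", "AACA", "ACAA", "CAAA", "AAAC", "CAAC")

ALL_TETRAMERS = ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=4)]

_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _c in enumerate(RNA_ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_CODE[ord("T")] = 3  # tolerate DNA-alphabet input
_CODE[ord("t")] = 3


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A=0, C=1, G=2, U/T=3; 255 = invalid)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def tetramer_codes(seq: str) -> np.ndarray:
    """Base-4 code of the tetramer starting at each position (-1 invalid)."""
    s = encode(seq).astype(np.int64)
    if s.size < 4:
        return np.empty(0, dtype=np.int64)
    k = s[:-3] * 64 + s[1:-2] * 16 + s[2:-1] * 4 + s[3:]
    bad = (s[:-3] > 3) | (s[1:-2] > 3) | (s[2:-1] > 3) | (s[3:] > 3)
    k[bad] = -1
    return k


def word_index(words: Iterable[str]) -> np.ndarray:
    return np.array([ALL_TETRAMERS.index(w) for w in words])


def count_tetramers(
    sequences: Mapping[str, str], windows: Sequence[CrossLinkWindows]
) -> pd.DataFrame:
    """Tetramer counts assigned by occurrence start position.

    An occurrence at position p (covering p..p+3) counts toward the
    cross-link column if p lies in the cross-link region and toward the
    flank column if p lies in either flank. Overlapping occurrences all
    count; occurrences containing non-ACGU letters are skipped.
    """
    xl = np.zeros(256, dtype=np.int64)
    fl = np.zeros(256, dtype=np.int64)
    codes_cache: dict[str, np.ndarray] = {}
    for w in windows:
        seq_codes = codes_cache.get(w.transcript_id)
        if seq_codes is None:
            seq_codes = tetramer_codes(sequences[w.transcript_id])
            codes_cache[w.transcript_id] = seq_codes
        for target, (a, b) in [(xl, w.crosslink_region), (fl, w.flanks[0]),
                               (fl, w.flanks[1])]:
            a, b = max(0, a), min(seq_codes.size, b)
            if b <= a:
                continue
            k = seq_codes[a:b]
            k = k[k >= 0]
            if k.size:
                target += np.bincount(k, minlength=256)
    return pd.DataFrame(
        {"word": ALL_TETRAMERS, "crosslink": xl, "flank": fl}
    ).set_index("word")


def zscores(
    foreground: pd.DataFrame, background_samples: Sequence[pd.DataFrame]
) -> pd.DataFrame:
    """Per-word Z-scores of foreground counts against resampled backgrounds.

    Z = (obs - mean_bg) / sd_bg per region, with the background moments
    taken over the supplied samples (each a count table from one background
    draw). Words whose background never varies get NaN.
    """
    if len(background_samples) < 2:
        raise ValueError("need at least 2 background samples")
    if len(background_samples) < 20:
        log.warning("only %d background samples; Z-scores will be noisy",
                    len(background_samples))
    out = foreground.copy()
    for col in ("crosslink", "flank"):
        bg = np.stack([b[col].to_numpy(float) for b in background_samples])
        mu = bg.mean(axis=0)
        sd = bg.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (foreground[col].to_numpy(float) - mu) / sd
        z[sd == 0] = np.nan
        out[f"z_{col}"] = z
    return out


def _occurrence_freq(
    anchored: Sequence[tuple[str, int]],
    word_idx: np.ndarray,
    halfwidth: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(counts, exposure) of word-set occurrence starts per relative offset."""
    span = 2 * halfwidth + 1
    counts = np.zeros(span)
    exposure = np.zeros(span)
    for seq, anchor in anchored:
        k = tetramer_codes(seq)
        lo = max(0, anchor - halfwidth)
        hi = min(k.size, anchor + halfwidth + 1)
        if hi <= lo:
            continue
        d = np.arange(lo, hi) - anchor + halfwidth
        exposure[d] += 1
        kk = k[lo:hi]
        hit = np.isin(kk, word_idx)
        counts[d[hit]] += 1
    return counts, exposure


def positional_profile(
    foreground: Sequence[tuple[str, int]],
    background: Sequence[tuple[str, int]],
    words: Iterable[str],
    halfwidth: int = 50,
    smooth: int = 5,
) -> pd.DataFrame:
    """Positional enrichment of a word family around segment starts.

    ``foreground``/``background`` are (sequence, anchor) pairs; offset d=0
    is the anchor (segment 5' start). The profile is the per-offset
    frequency of word starts in the foreground divided by the same
    frequency in the background, then smoothed with a centred running mean
    over ``smooth`` positions (smooth=1 returns the raw ratio). Offsets
    with zero background frequency are NaN.
    """
    widx = word_index(words)
    if widx.size == 0:
        raise ValueError("empty word set")
    fc, fe = _occurrence_freq(foreground, widx, halfwidth)
    bc, be = _occurrence_freq(background, widx, halfwidth)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_freq = np.where(fe > 0, fc / np.maximum(fe, 1), np.nan)
        b_freq = np.where(be > 0, bc / np.maximum(be, 1), np.nan)
        ratio = f_freq / b_freq
    ratio[(be == 0) | (b_freq == 0)] = np.nan
    if smooth > 1:
        kernel = np.ones(smooth)
        valid = np.isfinite(ratio)
        num = np.convolve(np.where(valid, ratio, 0.0), kernel, mode="same")
        den = np.convolve(valid.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore"):
            ratio = np.where(den > 0, num / den, np.nan)
    offsets = np.arange(-halfwidth, halfwidth + 1)
    return pd.DataFrame({"offset": offsets, "enrichment": ratio})


# ---------------------------------------------------------------------------
# MACA co-occurrence

def iupac_expand(pattern: str) -> list[str]:
    """Expand an IUPAC RNA pattern into concrete words (supports M = A/C)."""
    table = {"M": "AC", "A": "A", "C": "C", "G": "G", "U": "U"}
    pools = [table[c] for c in pattern]
    return ["".join(p) for p in itertools.product(*pools)]


def match_starts(seq: str, words: Iterable[str]) -> np.ndarray:
    k = tetramer_codes(seq)
    return np.flatnonzero(np.isin(k, word_index(words)))


def _lag_histogram(seqs: Iterable[str], words: list[str], max_lag: int) -> np.ndarray:
    hist = np.zeros(max_lag + 1, dtype=np.int64)
    for seq in seqs:
        pos = match_starts(seq, words)
        if pos.size < 2:
            continue
        lags = (pos[None, :] - pos[:, None]).ravel()
        lags = lags[(lags >= 1) & (lags <= max_lag)]
        hist += np.bincount(lags, minlength=max_lag + 1)
    return hist


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (random Eulerian walk)."""
    n = len(seq)
    if n < 3:
        return seq
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(adj)
    # pick per-vertex terminal edges forming a tree into `last`
    for _ in range(1000):
        terminal = {
            v: adj[v][rng.integers(len(adj[v]))] for v in vertices if v != last
        }
        ok = True
        for v in terminal:
            seen, cur = {v}, v
            while cur != last:
                cur = terminal.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - pathological composition
        return seq
    shuffled_adj = {}
    for v in vertices:
        edges = list(adj[v])
        if v != last:
            edges.remove(terminal[v])
        rng.shuffle(edges)
        if v != last:
            edges.append(terminal[v])
        shuffled_adj[v] = edges
    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(n - 1):
        nxt = shuffled_adj[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def maca_cooccurrence(
    sequences: Sequence[str],
    max_lag: int = 30,
    pattern: str = "MACA",
    n_shuffles: int = 10,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Normalized co-occurrence of MACA matches as a function of lag.

    For every ordered pair of match starts p1 < p2 within a sequence the
    lag p2-p1 <= max_lag is histogrammed; the histogram is divided by the
    mean histogram from dinucleotide-shuffled copies of the same sequences
    (preserving composition and local dinucleotide structure).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    words = iupac_expand(pattern)
    obs = _lag_histogram(sequences, words, max_lag)
    null = np.zeros(max_lag + 1, dtype=float)
    for _ in range(n_shuffles):
        shuffled = [dinucleotide_shuffle(s, rng) for s in sequences]
        null += _lag_histogram(shuffled, words, max_lag)
    null /= max(n_shuffles, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = obs / null
    norm[null == 0] = np.nan
    lags = np.arange(max_lag + 1)
    return pd.DataFrame({"lag": lags[1:], "observed": obs[1:],
                         "expected": null[1:], "normalized": norm[1:]})


def utr_length_correlation(
    tags_per_nt: Sequence[float], utr_lengths: Sequence[float]
) -> tuple[float, float]:
    """Spearman correlation of 3'UTR tag density vs 3'UTR length."""
    x = np.asarray(tags_per_nt, float)
    y = np.asarray(utr_lengths, float)
    if x.size < 3:
        raise ValueError("need at least 3 transcripts")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
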