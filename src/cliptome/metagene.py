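"""Standardized transcript (metagene) profiles.

Each transcript's 5'UTR, CDS and 3'UTR are divided into a fixed number of
bins (defaults 20/50/50); a bin's value is the mean of the per-nucleotide
values falling into it, and profiles are averaged bin-wise across
transcripts. Regions shorter than their bin count leave the unfilled bins
missing (NaN) rather than zero, so short transcripts do not drag the
cross-transcript average down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import TranscriptModel

DEFAULT_BINS = (20, 50, 50)


@dataclass
class MetageneProfile:
    bins_5utr: np.ndarray
    bins_cds: np.ndarray
    bins_3utr: np.ndarray
    n_transcripts: int
    quantity: str = "mean_enrichment_per_nt"

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.bins_5utr, self.bins_cds, self.bins_3utr])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, arr in [("5utr", self.bins_5utr), ("cds", self.bins_cds),
                           ("3utr", self.bins_3utr)]:
            for i, v in enumerate(arr):
                rows.append(dict(region=label, bin=i, value=v,
                                 n_transcripts=self.n_transcripts))
        return pd.DataFrame(rows)


def _bin_region(values: np.ndarray, n_bins: int) -> np.ndarray:
    out = np.full(n_bins, np.nan)
    ln = values.size
    if ln == 0:
        return out
    which = (np.arange(ln) * n_bins) // ln  # floor(pos * B / len)
    sums = np.bincount(which, weights=values, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    filled = counts > 0
    out[filled] = sums[filled] / counts[filled]
    return out


def bin_track(
    values: np.ndarray,
    region_lengths: tuple[int, int, int],
    bins: tuple[int, int, int] = DEFAULT_BINS,
) -> np.ndarray:
    """Bin a per-nucleotide track into the fixed 5'UTR/CDS/3'UTR bins.

    ``values`` must have length sum(region_lengths); the returned vector
    has length sum(bins) with NaN marking empty bins.
    """
    u5, cds, u3 = region_lengths
    values = np.asarray(values, dtype=float)
    if values.size != u5 + cds + u3:
        raise ValueError("track length does not match region lengths")
    parts = [
        _bin_region(values[:u5], bins[0]),
        _bin_region(values[u5:u5 + cds], bins[1]),
        _bin_region(values[u5 + cds:], bins[2]),
    ]
    return np.concatenate(parts)


def bin_transcript_track(
    values: np.ndarray, model: TranscriptModel,
    bins: tuple[int, int, int] = DEFAULT_BINS,
) -> np.ndarray:
    return bin_track(values, model.region_lengths, bins)


def average_profiles(
    binned: list[np.ndarray],
    bins: tuple[int, int, int] = DEFAULT_BINS,
    quantity: str = "mean_enrichment_per_nt",
) -> MetageneProfile:
    """Bin-wise mean across transcripts, ignoring missing (NaN) bins."""
    if not binned:
        raise ValueError("no transcripts to average")
    mat = np.vstack(binned)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
    b0, b1, b2 = bins
    return MetageneProfile(
        bins_5utr=mean[:b0],
        bins_cds=mean[b0:b0 + b1],
        bins_3utr=mean[b0 + b1:],
        n_transcripts=mat.shape[0],
        quantity=quantity,
    )
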