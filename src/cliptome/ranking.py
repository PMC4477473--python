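"""Transcript ranking per dataset and multi-experiment intersection.

Each dataset (iCLIP / PAR-iCLIP replicate or RIP-seq replicate) yields a
per-transcript score: mean 3'UTR enrichment per nucleotide for CLIP, or
the whole-transcript RIP enrichment factor. Transcripts whose expression
does not exceed the dataset's mean expression are excluded first.
Replicates are merged by rank sum, the top-n lists of the two replicates
of each method are intersected into a per-method pool, and the final
targetome is the intersection of the three method pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class DatasetRanking:
    dataset_id: str
    table: pd.DataFrame  # index transcript_id; columns: score, rank, expression

    @property
    def transcripts(self) -> list[str]:
        return list(self.table.index)

    def top(self, n: int) -> set[str]:
        if n > len(self.table):
            log.info("%s: top-%d requested, only %d ranked",
                     self.dataset_id, n, len(self.table))
        return set(self.table.sort_values("rank").index[:n])


@dataclass
class IntersectionReport:
    pools: dict[str, set[str]]
    final: set[str]
    n_top: int
    pool_sizes: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.pool_sizes = {k: len(v) for k, v in self.pools.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(set_name=k, size=len(v)) for k, v in self.pools.items()]
        rows.append(dict(set_name="final_intersection", size=len(self.final)))
        return pd.DataFrame(rows)


def expression_filter(
    expression: pd.Series, max_n: int | None = None
) -> list[str]:
    """Transcripts expressed strictly above the dataset mean, optionally
    truncated to the max_n most expressed."""
    if len(expression) == 0:
        raise ValueError("empty expression table")
    kept = expression[expression > expression.mean()]
    kept = kept.sort_values(ascending=False)
    if max_n is not None:
        kept = kept.iloc[:max_n]
    return list(kept.index)


def rank_dataset(
    dataset_id: str,
    scores: pd.Series,
    expression: pd.Series,
    max_n: int | None = None,
) -> DatasetRanking:
    """Rank retained transcripts by score, descending; ties by id.

    ``scores`` is mean 3'UTR enrichment (CLIP) or RIP factor per
    transcript; NaN scores are excluded with a log message. A degenerate
    all-equal score vector is flagged.
    """
    retained = expression_filter(expression, max_n)
    s = scores.reindex(retained)
    n_undef = int(s.isna().sum())
    if n_undef:
        log.info("%s: %d transcripts with undefined score excluded",
                 dataset_id, n_undef)
    s = s.dropna()
    if len(s) > 1 and s.nunique() == 1:
        log.warning("%s: all scores identical; ranking is degenerate", dataset_id)
    order = sorted(s.index, key=lambda t: (-s[t], t))
    table = pd.DataFrame(
        {
            "score": s.reindex(order),
            "rank": np.arange(1, len(order) + 1),
            "expression": expression.reindex(order),
        }
    )
    return DatasetRanking(dataset_id, table)


def merge_replicates(rankings: list[DatasetRanking]) -> DatasetRanking:
    """Rank-sum merge over the transcripts retained in every replicate."""
    if len(rankings) < 2:
        raise ValueError("need at least 2 rankings to merge")
    common = set(rankings[0].table.index)
    for r in rankings[1:]:
        common &= set(r.table.index)
    if not common:
        raise ValueError("no transcript retained in all replicates")
    rank_sum = sum(r.table["rank"].reindex(sorted(common)) for r in rankings)
    order = sorted(common, key=lambda t: (rank_sum[t], t))
    table = pd.DataFrame(
        {
            "score": -rank_sum.reindex(order).astype(float),
            "rank": np.arange(1, len(order) + 1),
            "expression": rankings[0].table["expression"].reindex(order),
        }
    )
    merged_id = "+".join(r.dataset_id for r in sorted(rankings, key=lambda r: r.dataset_id))
    return DatasetRanking(merged_id, table)


def top_n_intersections(
    method_rankings: dict[str, list[DatasetRanking]], n: int = 200
) -> IntersectionReport:
    """Per-method pools (intersection of replicate top-n lists) and their
    overall intersection (the conservative targetome)."""
    pools: dict[str, set[str]] = {}
    for method, reps in method_rankings.items():
        pool: set[str] | None = None
        for r in reps:
            t = r.top(n)
            pool = t if pool is None else pool & t
        pools[method] = pool or set()
    final = None
    for pool in pools.values():
        final = pool if final is None else final & pool
    return IntersectionReport(pools=pools, final=final or set(), n_top=n)


def enrichment_curve(
    scores: pd.Series, threshold: float = 3.0
) -> tuple[pd.DataFrame, int]:
    """Descending per-transcript enrichment curve + count above threshold.

    ``scores`` should come from pooled replicates (counts and library sizes
    summed before normalization, under which the enrichment statistic is
    invariant to duplicating a library).
    """
    s = scores.dropna().sort_values(ascending=False)
    curve = pd.DataFrame(
        {"transcript_id": s.index, "enrichment": s.to_numpy(),
         "rank": np.arange(1, len(s) + 1)}
    )
    return curve, int((s > threshold).sum())
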