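"""Transcript-abundance utilities: RPKM, cumulative read fraction, and
cross-sample agreement of log expression.

Non-normalized RNA libraries are dominated by a handful of very highly
expressed transcripts; the cumulative mapped-read curve by expression rank
quantifies that skew (e.g. the rank at which half of all mapped reads are
accounted for). Agreement of log10 RPKM between the two parents indicates
whether bulk frequency comparisons are sensible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np

from .types import ExpressionRecord, UnigeneRecord


def rpkm(mapped_reads: int, length_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return mapped_reads * 1.0e9 / (length_bp * total_mapped_reads)


def expression_table(
    counts: Mapping[str, int], lengths: Iterable[UnigeneRecord]
) -> List[ExpressionRecord]:
    """Build per-unigene expression records from a mapped-read counts table."""
    total = sum(counts.values())
    records = []
    for u in lengths:
        if u.unigene_id not in counts:
            continue
        reads = counts[u.unigene_id]
        records.append(
            ExpressionRecord(
                u.unigene_id, reads, u.length_bp,
                rpkm(reads, u.length_bp, total),
            )
        )
    return records


@dataclass
class CumulativeCurve:
    """Unigenes ranked by RPKM (descending; ties by unigene_id) with the
    cumulative fraction of mapped reads at each rank."""

    records: List[ExpressionRecord]
    cumulative: np.ndarray  # same order as records; last entry == 1.0

    def rank_at(self, fraction: float) -> int:
        """Smallest 1-based rank whose cumulative fraction >= ``fraction``."""
        idx = int(np.searchsorted(self.cumulative, fraction, side="left"))
        if idx >= len(self.cumulative):
            raise ValueError(f"cumulative curve never reaches {fraction}")
        return idx + 1


def cumulative_mapped_fraction(
    records: Sequence[ExpressionRecord],
) -> CumulativeCurve:
    """Rank records by expression and accumulate their mapped-read share."""
    total = sum(r.mapped_reads for r in records)
    if total <= 0:
        raise ValueError("no mapped reads")
    ranked = sorted(records, key=lambda r: (-r.rpkm, r.unigene_id))
    cum = np.cumsum([r.mapped_reads for r in ranked]) / total
    cum[-1] = 1.0  # exact despite float accumulation
    return CumulativeCurve(ranked, cum)


def log_rpkm_r2(
    records_a: Sequence[ExpressionRecord],
    records_b: Sequence[ExpressionRecord],
) -> float:
    """Squared Pearson correlation of log10 RPKM over co-expressed unigenes.

    Unigenes absent from, or with zero RPKM in, either sample are dropped.
    Requires at least two shared expressed unigenes.
    """
    a: Dict[str, float] = {r.unigene_id: r.rpkm for r in records_a if r.rpkm > 0}
    b: Dict[str, float] = {r.unigene_id: r.rpkm for r in records_b if r.rpkm > 0}
    shared = sorted(a.keys() & b.keys())
    if len(shared) < 2:
        raise ValueError(
            f"need >=2 unigenes expressed in both samples, got {len(shared)}"
        )
    x = np.log10([a[u] for u in shared])
    y = np.log10([b[u] for u in shared])
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
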