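"""Reporting helpers: percentage formatting and the BFR-vs-expression-rank
export table (the data layer behind a BFR scatter ordered by expression)."""

from __future__ import annotations

import math
from typing import Dict, List, Sequence

from .types import BFRRecord, ExpressionRecord
from .expression import cumulative_mapped_fraction


def percent(numerator: float, denominator: float, decimals: int = 1) -> str:
    """Format ``numerator/denominator`` as a percentage string.

    ``percent(1619, 3427)`` -> ``'47.2%'``; ``percent(25, 30, 0)`` -> ``'83%'``.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return f"{100.0 * numerator / denominator:.{decimals}f}%"


def percent_value(numerator: float, denominator: float, decimals: int = 1) -> float:
    """The numeric value behind :func:`percent` (rounded the same way)."""
    return float(percent(numerator, denominator, decimals).rstrip("%"))


def bfr_rank_table(
    records: Sequence[BFRRecord],
    expression: Sequence[ExpressionRecord],
) -> List[dict]:
    """Join BFR records with the expression rank of their unigene.

    One row per non-excluded, depth-passing record, ordered by expression
    rank: ``{unigene_id, pos, rank, rpkm, bfr}``. This is the tabular layer
    behind plotting BFR against unigene expression rank.
    """
    curve = cumulative_mapped_fraction(expression)
    rank_of: Dict[str, int] = {
        r.unigene_id: i + 1 for i, r in enumerate(curve.records)
    }
    rpkm_of = {r.unigene_id: r.rpkm for r in expression}
    rows = [
        {
            "unigene_id": r.unigene_id,
            "pos": r.pos,
            "rank": rank_of[r.unigene_id],
            "rpkm": rpkm_of[r.unigene_id],
            "bfr": r.bfr,
        }
        for r in records
        if r.passes_depth and not r.excluded and r.unigene_id in rank_of
    ]
    rows.sort(key=lambda row: (row["rank"], row["unigene_id"], row["pos"]))
    return rows
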