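"""Bulk frequency ratio (BFR) screening of candidate varietal SNPs.

At each candidate SNP the frequency of the informative base is measured in
the two phenotype bulks and the ratio oriented by parental origin: for a
SNP whose informative base comes from the low-phenotype parent, BFR is the
frequency in the low bulk divided by the frequency in the high bulk, and
vice versa. A tightly linked SNP is enriched in its matching bulk, so the
oriented ratio is large; unlinked SNPs hover around 1.

In a tetraploid the informative base of a hemi-SNP is diluted by the
co-expressed homoeologue, so its bulk frequency tends to 0.5 (not 1.0) even
at complete linkage, assuming balanced homoeologue expression; simple SNPs
tend to 1.0/0.0. Records whose denominator frequency is zero are flagged
``excluded`` (reported, never silently dropped) and are left out of
threshold summaries.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .types import BASES, BFRRecord, PileupColumn, VarietalSNP

PileupIndex = Mapping[Tuple[str, int], PileupColumn]


def informative_base_frequency(
    column: PileupColumn, base: str, acgt_only: bool = False
) -> float:
    """Frequency of ``base`` in one column; NaN when depth is zero.

    By default the denominator is the total column depth (including
    ``n_other``); ``acgt_only`` restricts it to substitution-callable bases.
    """
    denom = (
        sum(column.counts.get(b, 0) for b in BASES)
        if acgt_only
        else column.depth
    )
    if denom == 0:
        return float("nan")
    return column.counts.get(base, 0) / denom


def bulk_frequency_ratio(
    f_high: float, f_low: float, origin: str, low_parent: str = "A"
) -> float:
    """Oriented ratio of bulk frequencies; NaN flags an excluded record.

    ``origin`` names the parent (label) contributing the informative base;
    ``low_parent`` declares which parent label is the low-phenotype parent.
    The numerator is the frequency in the bulk matching the origin. Zero (or
    undefined) denominator => NaN.
    """
    if math.isnan(f_high) or math.isnan(f_low):
        return float("nan")
    numerator, denominator = (
        (f_low, f_high) if origin == low_parent else (f_high, f_low)
    )
    if denominator == 0.0:
        return float("nan")
    return numerator / denominator


def _depth_and_freq(
    pileup: PileupIndex, key: Tuple[str, int], base: str, acgt_only: bool
) -> Tuple[int, float]:
    col = pileup.get(key)
    if col is None:
        return 0, float("nan")
    return col.depth, informative_base_frequency(col, base, acgt_only)


def select_one_per_unigene(
    snps: Sequence[VarietalSNP],
    high_pileup: PileupIndex,
    low_pileup: PileupIndex,
) -> List[VarietalSNP]:
    """Keep the best-covered SNP per unigene.

    The SNP maximising ``min(depth_high, depth_low)`` wins; ties break to
    the smallest position.
    """
    best: Dict[str, Tuple[int, int, VarietalSNP]] = {}
    for snp in snps:
        key = (snp.unigene_id, snp.pos)
        dh = high_pileup.get(key).depth if key in high_pileup else 0
        dl = low_pileup.get(key).depth if key in low_pileup else 0
        score = min(dh, dl)
        cur = best.get(snp.unigene_id)
        if cur is None or score > cur[0] or (score == cur[0] and snp.pos < cur[1]):
            best[snp.unigene_id] = (score, snp.pos, snp)
    return [best[u][2] for u in sorted(best)]


def bsa_screen(
    snps: Sequence[VarietalSNP],
    high_pileup: PileupIndex,
    low_pileup: PileupIndex,
    min_depth: int = 8,
    threshold: float = 3.0,
    one_per_unigene: bool = False,
    low_parent: str = "A",
    acgt_only: bool = False,
) -> List[BFRRecord]:
    """Compute a :class:`BFRRecord` for every (selected) candidate SNP.

    Every evaluated SNP yields a record; a SNP absent from a bulk's pileup
    gets depth 0, an undefined frequency and ``passes_depth=False``.
    Deterministic: output follows the (unigene, pos) order of the input
    selection.
    """
    if one_per_unigene:
        snps = select_one_per_unigene(snps, high_pileup, low_pileup)
    records: List[BFRRecord] = []
    for snp in snps:
        key = (snp.unigene_id, snp.pos)
        depth_high, f_high = _depth_and_freq(
            high_pileup, key, snp.informative_base, acgt_only
        )
        depth_low, f_low = _depth_and_freq(
            low_pileup, key, snp.informative_base, acgt_only
        )
        bfr = bulk_frequency_ratio(f_high, f_low, snp.origin, low_parent)
        excluded = math.isnan(bfr)
        passes_depth = depth_high >= min_depth and depth_low >= min_depth
        records.append(
            BFRRecord(
                unigene_id=snp.unigene_id,
                pos=snp.pos,
                snp_type=snp.snp_type,
                origin=snp.origin,
                informative_base=snp.informative_base,
                f_high=f_high,
                f_low=f_low,
                depth_high=depth_high,
                depth_low=depth_low,
                bfr=bfr,
                excluded=excluded,
                passes_depth=passes_depth,
                passes_threshold=(
                    passes_depth and not excluded and bfr >= threshold
                ),
            )
        )
    return records


def threshold_summary(
    records: Iterable[BFRRecord],
    cutoffs: Sequence[float] = tuple(range(2, 11)),
) -> List[dict]:
    """Counts and percentages of SNPs at or above each BFR cutoff.

    The population is depth-passing, non-excluded records; percentages are
    relative to that population. Empty input yields all-zero rows.
    """
    values = [
        r.bfr for r in records if r.passes_depth and not r.excluded
    ]
    total = len(values)
    rows = []
    for cutoff in cutoffs:
        count = sum(1 for v in values if v >= cutoff)
        rows.append(
            {
                "cutoff": float(cutoff),
                "count": count,
                "percent": (100.0 * count / total) if total else 0.0,
            }
        )
    return rows
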