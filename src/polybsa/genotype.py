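"""Per-position consensus genotyping from pileup counts.

In a tetraploid, reads from both homoeologous gene copies co-map to one
consensus unigene, so a position where the two copies differ legitimately
shows two bases in a homozygous individual. The caller therefore reports
either a single base or a two-base IUPAC ambiguity (R/Y/S/W/K/M); three or
more qualifying bases are treated as a no-call (likely collapsed paralogues)
and never enter SNP classification.

The rule is count-based and deterministic: a base qualifies as an allele
when it has at least ``min_allele_reads`` reads AND at least
``min_allele_fraction`` of the column depth (ties at the boundary are
inclusive). Positions below ``min_depth`` are no-calls.
"""

from __future__ import annotations

import csv
from typing import Dict, Iterable, List, Optional, Tuple

from .types import BASES, GenotypeCall, PileupColumn

#: Two-base IUPAC ambiguity codes (plus the four singletons).
IUPAC_ENCODE = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
IUPAC_DECODE = {code: alleles for alleles, code in IUPAC_ENCODE.items()}


def iupac_code(alleles: Iterable[str]) -> str:
    """Encode a set of one or two bases as its IUPAC character."""
    key = frozenset(alleles)
    if not 1 <= len(key) <= 2:
        raise ValueError(
            f"IUPAC encoding defined for 1 or 2 alleles, got {sorted(key)}"
        )
    try:
        return IUPAC_ENCODE[key]
    except KeyError:
        raise ValueError(f"not a base set: {sorted(key)}") from None


def iupac_decode(code: str) -> frozenset:
    """Decode an IUPAC character back to its base set."""
    try:
        return IUPAC_DECODE[code]
    except KeyError:
        raise ValueError(f"not a singleton/pair IUPAC code: {code!r}") from None


def call_genotype(
    column: PileupColumn,
    min_depth: int = 8,
    min_allele_reads: int = 2,
    min_allele_fraction: float = 0.2,
) -> Optional[GenotypeCall]:
    """Call the consensus genotype for one column, or ``None`` (no-call)."""
    if column.depth < min_depth:
        return None
    alleles = [
        b
        for b in BASES
        if column.counts.get(b, 0) >= min_allele_reads
        and column.counts.get(b, 0) / column.depth >= min_allele_fraction
    ]
    if len(alleles) not in (1, 2):
        return None
    allele_set = frozenset(alleles)
    return GenotypeCall(
        unigene_id=column.unigene_id,
        pos=column.pos,
        alleles=allele_set,
        code=IUPAC_ENCODE[allele_set],
        depth=column.depth,
        allele_counts={b: column.counts.get(b, 0) for b in BASES},
    )


def call_sample(
    columns: Iterable[PileupColumn],
    min_depth: int = 8,
    min_allele_reads: int = 2,
    min_allele_fraction: float = 0.2,
) -> Dict[Tuple[str, int], GenotypeCall]:
    """Genotype every column of one sample; no-calls are dropped."""
    calls: Dict[Tuple[str, int], GenotypeCall] = {}
    for col in columns:
        call = call_genotype(
            col,
            min_depth=min_depth,
            min_allele_reads=min_allele_reads,
            min_allele_fraction=min_allele_fraction,
        )
        if call is not None:
            calls[(col.unigene_id, col.pos)] = call
    return calls


_CALL_COLUMNS = ["unigene_id", "pos", "code", "depth", "A", "C", "G", "T"]


def write_calls(calls: Dict[Tuple[str, int], GenotypeCall], path: str) -> None:
    """Write per-sample calls as TSV (one row per called position)."""
    with open(path, "wt", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(_CALL_COLUMNS)
        for key in sorted(calls):
            c = calls[key]
            writer.writerow(
                [c.unigene_id, c.pos, c.code, c.depth]
                + [c.allele_counts.get(b, 0) for b in BASES]
            )


def read_calls(path: str) -> Dict[Tuple[str, int], GenotypeCall]:
    """Read a calls TSV written by :func:`write_calls`."""
    calls: Dict[Tuple[str, int], GenotypeCall] = {}
    with open(path, "rt", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        unknown = [h for h in (reader.fieldnames or []) if h not in _CALL_COLUMNS]
        if unknown:
            raise ValueError(f"{path}: unknown column(s) {', '.join(unknown)}")
        for row in reader:
            alleles = iupac_decode(row["code"])
            call = GenotypeCall(
                unigene_id=row["unigene_id"],
                pos=int(row["pos"]),
                alleles=alleles,
                code=row["code"],
                depth=int(row["depth"]),
                allele_counts={b: int(row[b]) for b in BASES},
            )
            calls[(call.unigene_id, call.pos)] = call
    return calls
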