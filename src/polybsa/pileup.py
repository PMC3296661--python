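"""Reading samtools-mpileup text pileups and FASTA references.

The pileup dialect is the samtools mpileup text format (5 or 6 tab-separated
columns: name, 1-based position, reference base, depth, read bases, optional
base qualities). Substitution evidence only: indel blocks are consumed but do
not occupy a depth slot; deletion placeholders ('*'), N calls and reference
skips ('<'/'>') are counted in ``n_other``.
"""

from __future__ import annotations

import io
from typing import Dict, Iterable, Iterator, List, Tuple, Union

from Bio import SeqIO

from .types import BASES, PileupColumn, UnigeneRecord

PathOrHandle = Union[str, "io.TextIOBase"]

_SPECIALS = ("^", "$", "+", "-")


class PileupParseError(ValueError):
    """Raised for malformed pileup lines; message names the line number."""


def _loc(line_number) -> str:
    return f"line {line_number}" if line_number is not None else "line"


def parse_pileup_line(
    line: str,
    line_number: int | None = None,
    min_base_quality: int | None = None,
    quality_offset: int = 33,
) -> PileupColumn:
    """Parse one mpileup text line into a :class:`PileupColumn`.

    '.'/',' resolve to the reference base; letters to themselves (case folds
    strand); '^' consumes exactly one mapping-quality character; '$' is
    consumed; '+n'/'-n' indel blocks are consumed without counting; '*', 'N'
    and '<'/'>' count in ``n_other``. When ``min_base_quality`` is set and a
    quality column is present, bases below the threshold are moved to
    ``n_other``.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise PileupParseError(
            f"{_loc(line_number)}: expected >=5 tab-separated fields, "
            f"got {len(fields)}"
        )
    unigene_id, pos_s, ref, depth_s, bases = fields[:5]
    quals = fields[5] if len(fields) > 5 else None
    try:
        pos = int(pos_s)
    except ValueError:
        raise PileupParseError(
            f"{_loc(line_number)}: malformed position field {pos_s!r}"
        ) from None
    try:
        depth = int(depth_s)
    except ValueError:
        raise PileupParseError(
            f"{_loc(line_number)}: malformed depth field {depth_s!r}"
        ) from None
    ref_base = ref.upper()

    counts = dict.fromkeys(BASES, 0)
    n_other = 0

    use_quals = min_base_quality is not None and quals is not None
    if not use_quals and not any(c in bases for c in _SPECIALS):
        # Fast path: plain substitution columns (what the simulator emits).
        for b in BASES:
            counts[b] = bases.count(b) + bases.count(b.lower())
        n_ref = bases.count(".") + bases.count(",")
        if ref_base in counts:
            counts[ref_base] += n_ref
        else:
            n_other += n_ref
        n_other += len(bases) - n_ref - sum(
            bases.count(b) + bases.count(b.lower()) for b in BASES
        )
    else:
        i = 0
        read_index = 0
        n = len(bases)
        while i < n:
            c = bases[i]
            if c == "^":
                i += 2  # '^' + one mapping-quality character
                continue
            if c == "$":
                i += 1
                continue
            if c in "+-":
                j = i + 1
                while j < n and bases[j].isdigit():
                    j += 1
                try:
                    indel_len = int(bases[i + 1 : j])
                except ValueError:
                    raise PileupParseError(
                        f"{_loc(line_number)}: malformed indel block at "
                        f"offset {i}"
                    ) from None
                i = j + indel_len
                continue
            # A read-base symbol (occupies one depth slot).
            qual_ok = True
            if use_quals:
                if read_index >= len(quals):
                    raise PileupParseError(
                        f"{_loc(line_number)}: quality string shorter than "
                        "read bases"
                    )
                qual_ok = (
                    ord(quals[read_index]) - quality_offset >= min_base_quality
                )
            read_index += 1
            if c in ".,":
                base = ref_base
            else:
                base = c.upper()
            if base in counts and qual_ok:
                counts[base] += 1
            else:
                n_other += 1
            i += 1

    total = sum(counts.values()) + n_other
    if total != depth:
        raise PileupParseError(
            f"{_loc(line_number)}: parsed {total} read bases but depth "
            f"field says {depth}"
        )
    try:
        return PileupColumn(unigene_id, pos, ref_base, depth, counts, n_other)
    except ValueError as exc:
        raise PileupParseError(f"{_loc(line_number)}: {exc}") from None


def _open(source: PathOrHandle):
    if hasattr(source, "read"):
        return source, False
    return open(source, "rt"), True


def read_pileup(
    source: PathOrHandle, min_base_quality: int | None = None
) -> Iterator[PileupColumn]:
    """Stream :class:`PileupColumn` records from an mpileup text file."""
    handle, close = _open(source)
    try:
        for i, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            yield parse_pileup_line(
                line, line_number=i, min_base_quality=min_base_quality
            )
    finally:
        if close:
            handle.close()


def load_pileup_index(
    source: PathOrHandle, min_base_quality: int | None = None
) -> Dict[Tuple[str, int], PileupColumn]:
    """Load a whole pileup into a ``{(unigene_id, pos): column}`` index."""
    return {
        (col.unigene_id, col.pos): col
        for col in read_pileup(source, min_base_quality=min_base_quality)
    }


def read_unigene_lengths(source: PathOrHandle) -> List[UnigeneRecord]:
    """Read per-unigene lengths from a FASTA reference, in input order.

    Raises ``ValueError`` on duplicate sequence identifiers.
    """
    handle, close = _open(source)
    try:
        records: List[UnigeneRecord] = []
        seen = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate unigene identifier: {rec.id}")
            seen.add(rec.id)
            records.append(UnigeneRecord(rec.id, len(rec.seq)))
        return records
    finally:
        if close:
            handle.close()


def write_mpileup(columns: Iterable[PileupColumn], path: str) -> None:
    """Write columns back out as mpileup text ('.' for reference matches)."""
    with open(path, "wt") as out:
        for col in columns:
            parts = []
            for base in BASES:
                k = col.counts.get(base, 0)
                if k:
                    parts.append(("." if base == col.ref_base else base) * k)
            parts.append("N" * col.n_other)
            out.write(
                f"{col.unigene_id}\t{col.pos}\t{col.ref_base}\t"
                f"{col.depth}\t{''.join(parts)}\n"
            )
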