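"""Tab-separated read/write for the pipeline's record types.

Columns are addressed by header name, so files with reordered columns read
back identically; an unknown header is an error naming the offending column.
NaN BFR values (excluded records) serialize as an empty field, optional
strings as empty fields.
"""

from __future__ import annotations

import csv
import math
from typing import Iterable, List, Optional, Sequence, Type

from .types import BFRRecord, DensityReport, ExpressionRecord, VarietalSNP


def _opt_str(value: str) -> Optional[str]:
    return value if value != "" else None


def _from_bool(value) -> str:
    return "true" if value else "false"


def _to_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1"):
        return True
    if v in ("false", "0"):
        return False
    raise ValueError(f"not a boolean field: {value!r}")


def _from_float(value: float) -> str:
    return "" if math.isnan(value) else repr(float(value))


def _to_float(value: str) -> float:
    return float("nan") if value == "" else float(value)


def _identity(value):
    return value


# schema: ordered (column, to_text, from_text) per record type
_SCHEMAS = {
    VarietalSNP: [
        ("unigene_id", str, str),
        ("pos", str, int),
        ("snp_type", str, str),
        ("genotype_a", str, str),
        ("genotype_b", str, str),
        ("informative_base", str, str),
        ("origin", str, str),
        ("shared_base", lambda v: v if v is not None else "", _opt_str),
        ("depth_a", str, int),
        ("depth_b", str, int),
    ],
    BFRRecord: [
        ("unigene_id", str, str),
        ("pos", str, int),
        ("snp_type", str, str),
        ("origin", str, str),
        ("informative_base", str, str),
        ("f_high", _from_float, _to_float),
        ("f_low", _from_float, _to_float),
        ("depth_high", str, int),
        ("depth_low", str, int),
        ("bfr", _from_float, _to_float),
        ("excluded", _from_bool, _to_bool),
        ("passes_depth", _from_bool, _to_bool),
        ("passes_threshold", _from_bool, _to_bool),
    ],
    DensityReport: [
        ("unigene_id", str, str),
        ("n_snps", str, int),
        ("length_bp", str, int),
        ("density", _from_float, _to_float),
        ("retained", _from_bool, _to_bool),
    ],
    ExpressionRecord: [
        ("unigene_id", str, str),
        ("mapped_reads", str, int),
        ("length_bp", str, int),
        ("rpkm", _from_float, _to_float),
    ],
}


def write_records(records: Iterable, path: str, record_type: Type) -> None:
    """Write records of ``record_type`` to a header-bearing TSV file."""
    schema = _SCHEMAS[record_type]
    with open(path, "wt", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow([name for name, _, _ in schema])
        for rec in records:
            writer.writerow(
                [to_text(getattr(rec, name)) for name, to_text, _ in schema]
            )


def read_records(path: str, record_type: Type) -> List:
    """Read a TSV written by :func:`write_records` back into records.

    Column order is immaterial; unknown headers raise ``ValueError``.
    """
    schema = _SCHEMAS[record_type]
    known = {name: from_text for name, _, from_text in schema}
    with open(path, "rt", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        headers: Sequence[str] = reader.fieldnames or []
        unknown = [h for h in headers if h not in known]
        if unknown:
            raise ValueError(
                f"{path}: unknown column(s) {', '.join(unknown)}"
            )
        missing = [name for name in known if name not in headers]
        if missing:
            raise ValueError(
                f"{path}: missing column(s) {', '.join(missing)}"
            )
        records = []
        for row in reader:
            kwargs = {name: known[name](row[name]) for name in known}
            records.append(record_type(**kwargs))
        return records
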