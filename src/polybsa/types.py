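"""Core record types shared across the pipeline stages.

All positions are 1-based, matching samtools mpileup. A "unigene" is a
consensus transcript used as the alignment reference; in a polyploid it
collapses the homoeologous gene copies, which is what makes inter-homoeologue
polymorphisms (IHPs) and hemi-SNPs appear in the first place.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

#: Canonical base order used throughout (indexes into count arrays).
BASES = ("A", "C", "G", "T")


@dataclass
class PileupColumn:
    """One reference position in one sample.

    ``counts`` holds substitution-callable base counts only; indels,
    deletions ('*'), N and reference skips are tallied in ``n_other`` so that
    ``sum(counts.values()) + n_other == depth`` always holds.
    """

    unigene_id: str
    pos: int
    ref_base: str
    depth: int
    counts: Mapping[str, int]
    n_other: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        total = sum(self.counts.values()) + self.n_other
        if total != self.depth:
            raise ValueError(
                f"{self.unigene_id}:{self.pos}: counts+n_other ({total}) "
                f"!= depth ({self.depth})"
            )


@dataclass(frozen=True)
class UnigeneRecord:
    unigene_id: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.unigene_id}: length must be positive")


@dataclass(frozen=True)
class GenotypeCall:
    """Per-parent consensus at one position: one base, or a two-base
    ambiguity (IUPAC code) signalling co-expression of homoeologues."""

    unigene_id: str
    pos: int
    alleles: frozenset
    code: str
    depth: int
    allele_counts: Mapping[str, int] = field(default_factory=dict, hash=False)


@dataclass(frozen=True)
class VarietalSNP:
    """A classified polymorphism between the two parental lines.

    ``informative_base`` is the allele private to ``origin``'s parent; it is
    the base whose bulk frequencies drive the BFR. ``shared_base`` is the
    base common to both parents (hemi-SNPs only).
    """

    unigene_id: str
    pos: int
    snp_type: str  # "hemi" | "simple"
    genotype_a: str
    genotype_b: str
    informative_base: str
    origin: str  # "A" | "B"
    shared_base: Optional[str]
    depth_a: int
    depth_b: int


@dataclass(frozen=True)
class DensityReport:
    unigene_id: str
    n_snps: int
    length_bp: int
    density: float  # SNPs per kb
    retained: bool


@dataclass(frozen=True, eq=False)
class BFRRecord:
    """Per-SNP bulk informative-base frequencies and oriented ratio.

    ``bfr`` is NaN when the record is excluded (zero denominator frequency or
    a bulk with no coverage); ``excluded`` flags exactly those cases.
    Equality treats NaN fields as equal so round-tripped excluded records
    compare identical.
    """

    unigene_id: str
    pos: int
    snp_type: str
    origin: str
    informative_base: str
    f_high: float
    f_low: float
    depth_high: int
    depth_low: int
    bfr: float
    excluded: bool
    passes_depth: bool
    passes_threshold: bool

    def _key(self):
        out = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and math.isnan(v):
                v = None
            out.append(v)
        return tuple(out)

    def __eq__(self, other):
        if not isinstance(other, BFRRecord):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self):
        return hash(self._key())


@dataclass(frozen=True)
class ExpressionRecord:
    unigene_id: str
    mapped_reads: int
    length_bp: int
    rpkm: float
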