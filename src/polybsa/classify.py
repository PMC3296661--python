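"""Varietal SNP classification from two parental genotype-call sets.

The two parents are genotyped independently; positions called in both with
differing genotypes form the symmetric difference of the two call sets.
Each such position is classified:

* **IHP** — identical allele sets in both parents (the fixed difference is
  between homoeologous genomes, present in both varieties; not a marker).
* **hemi-SNP** — one parent shows a two-base ambiguity whose members include
  the other parent's single base. The pair member absent from the other
  parent is the informative base, private to the ambiguous parent.
* **simple SNP** — each parent a single, different base (single-copy gene or
  one genome expressed).
* **complex** — any other pattern (two different pairs, pair vs non-member
  singleton); reported separately, never emitted as a varietal SNP.

Classification compares the parents with EACH OTHER only; agreement with
the consensus reference base is irrelevant, because the reference collapses
the homoeologous genomes.

The SNP-density filter drops every SNP of any unigene whose density exceeds
``max_density`` SNPs/kb (strictly greater), the signature of collapsed
paralogues rather than true allelic variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .types import DensityReport, GenotypeCall, UnigeneRecord, VarietalSNP

IHP = "IHP"
HEMI = "hemi"
SIMPLE = "simple"
COMPLEX = "complex"


def classify_pair(
    call_a: GenotypeCall, call_b: GenotypeCall
) -> Tuple[str, VarietalSNP | None]:
    """Classify one co-called position; returns ``(kind, record-or-None)``.

    A :class:`VarietalSNP` record accompanies hemi and simple kinds only.
    """
    if (call_a.unigene_id, call_a.pos) != (call_b.unigene_id, call_b.pos):
        raise ValueError(
            f"position mismatch: {call_a.unigene_id}:{call_a.pos} vs "
            f"{call_b.unigene_id}:{call_b.pos}"
        )
    a, b = call_a.alleles, call_b.alleles
    if a == b:
        return IHP, None

    def record(snp_type, informative, origin, shared):
        return VarietalSNP(
            unigene_id=call_a.unigene_id,
            pos=call_a.pos,
            snp_type=snp_type,
            genotype_a=call_a.code,
            genotype_b=call_b.code,
            informative_base=informative,
            origin=origin,
            shared_base=shared,
            depth_a=call_a.depth,
            depth_b=call_b.depth,
        )

    if len(a) == 2 and len(b) == 1 and b < a:
        (shared,) = b
        (informative,) = a - b
        return HEMI, record(HEMI, informative, "A", shared)
    if len(b) == 2 and len(a) == 1 and a < b:
        (shared,) = a
        (informative,) = b - a
        return HEMI, record(HEMI, informative, "B", shared)
    if len(a) == 1 and len(b) == 1:
        # Informative base taken from parent A's side by convention; the
        # BSA stage treats simple SNPs symmetrically (frequencies tend to
        # 1/0 rather than 0.5/0).
        (base_a,) = a
        return SIMPLE, record(SIMPLE, base_a, "A", None)
    return COMPLEX, None


@dataclass
class ScanResult:
    """Varietal SNPs plus the per-kind tallies of every co-called position."""

    snps: List[VarietalSNP]
    complex_sites: List[Tuple[str, int, str, str]]  # (unigene, pos, code_a, code_b)
    n_ihp: int
    n_shared_identical: int  # co-called, same genotype (not polymorphic)


def varietal_snp_scan(
    calls_a: Mapping[Tuple[str, int], GenotypeCall],
    calls_b: Mapping[Tuple[str, int], GenotypeCall],
) -> ScanResult:
    """Scan two per-parent call sets and emit hemi/simple varietal SNPs.

    Only positions called in BOTH parents are considered (no cross-parent
    evidence otherwise); IHP and complex positions are excluded from the SNP
    list. Output is sorted by (unigene_id, pos).
    """
    snps: List[VarietalSNP] = []
    complex_sites: List[Tuple[str, int, str, str]] = []
    n_ihp = 0
    n_same = 0
    for key in sorted(calls_a.keys() & calls_b.keys()):
        call_a, call_b = calls_a[key], calls_b[key]
        if call_a.alleles == call_b.alleles:
            # same two-base ambiguity in both parents = an IHP; identical
            # singletons are just invariant positions
            if len(call_a.alleles) == 2:
                n_ihp += 1
            else:
                n_same += 1
            continue
        kind, rec = classify_pair(call_a, call_b)
        if kind == COMPLEX:
            complex_sites.append((key[0], key[1], call_a.code, call_b.code))
        else:
            snps.append(rec)
    return ScanResult(snps, complex_sites, n_ihp, n_same)


def snp_density_filter(
    snps: Sequence[VarietalSNP],
    lengths: Iterable[UnigeneRecord],
    max_density: float = 5.0,
) -> Tuple[List[VarietalSNP], List[DensityReport]]:
    """Drop all SNPs of unigenes with > ``max_density`` SNPs/kb.

    Density is ``n_snps * 1000 / length_bp``; equality with the threshold is
    retained. Reports cover every unigene carrying at least one SNP, sorted
    by unigene_id. Missing length records raise ``KeyError`` naming the
    unigene.
    """
    length_by_id = {u.unigene_id: u.length_bp for u in lengths}
    per_unigene: Dict[str, List[VarietalSNP]] = {}
    for snp in snps:
        per_unigene.setdefault(snp.unigene_id, []).append(snp)

    retained: List[VarietalSNP] = []
    reports: List[DensityReport] = []
    for unigene_id in sorted(per_unigene):
        if unigene_id not in length_by_id:
            raise KeyError(f"no length record for unigene {unigene_id}")
        group = per_unigene[unigene_id]
        length_bp = length_by_id[unigene_id]
        density = len(group) * 1000.0 / length_bp
        keep = density <= max_density
        reports.append(
            DensityReport(unigene_id, len(group), length_bp, density, keep)
        )
        if keep:
            retained.extend(group)
    retained.sort(key=lambda s: (s.unigene_id, s.pos))
    return retained, reports
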