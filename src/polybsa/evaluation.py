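"""Benchmark experiments run against the simulator's ground truth.

These drive the package end to end under controlled conditions and measure
how faithfully each stage recovers what was planted: exact recovery of the
varietal SNP set on noise-free data, BFR enrichment of target-linked SNPs,
and the tetraploid 0.5 frequency ceiling of hemi-SNP informative bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import bsa
from .genotype import call_sample
from .classify import varietal_snp_scan
from .simulate import SimConfig, SimDataset, simulate_dataset
from .types import VarietalSNP


def _snp_key(s) -> tuple:
    return (
        s.unigene_id, s.pos, s.snp_type, s.informative_base,
        s.origin, s.shared_base,
    )


@dataclass
class ScanAccuracy:
    precision: float
    recall: float
    n_planted: int
    n_found: int


def scan_accuracy(
    dataset: SimDataset, min_allele_fraction: float = 0.05
) -> ScanAccuracy:
    """Precision/recall of the varietal SNP scan against planted truth.

    SNPs are matched on position, type, informative base, origin and shared
    base. The relaxed allele fraction suits noise-free input, where any
    observed base is a real allele.
    """
    calls_a = call_sample(
        dataset.pileups["parent_a"].values(),
        min_allele_fraction=min_allele_fraction,
    )
    calls_b = call_sample(
        dataset.pileups["parent_b"].values(),
        min_allele_fraction=min_allele_fraction,
    )
    found = {_snp_key(s) for s in varietal_snp_scan(calls_a, calls_b).snps}
    planted = {
        _snp_key(s) for u in dataset.truth.unigenes for s in u.snps
    }
    tp = len(found & planted)
    return ScanAccuracy(
        precision=tp / len(found) if found else 1.0,
        recall=tp / len(planted) if planted else 1.0,
        n_planted=len(planted),
        n_found=len(found),
    )


def truth_snps_as_candidates(dataset: SimDataset) -> List[VarietalSNP]:
    """Planted SNPs re-expressed as classifier records (depths unknown)."""
    out = []
    for u in dataset.truth.unigenes:
        for s in u.snps:
            out.append(
                VarietalSNP(
                    s.unigene_id, s.pos, s.snp_type, s.genotype_a,
                    s.genotype_b, s.informative_base, s.origin,
                    s.shared_base, 0, 0,
                )
            )
    return out


def _enrichment_config(seed: int) -> SimConfig:
    # ten linked unigenes: five within 0.5 cM of the target, five spread
    # across the interval; half the set segregates independently
    t = 6.1
    return SimConfig(
        n_unigenes=24,
        mean_length_bp=1000,
        linked_map_positions=[t, t - 0.3, t + 0.3, t - 0.45, t + 0.45,
                              t - 2.0, t + 2.0, t - 4.0, t + 4.0, 1.0],
        unlinked_polymorphic_fraction=0.5,
        mean_depth=120.0,
        error_rate=0.0,
        expression_sigma=0.0,
        seed=seed,
    )


@dataclass
class EnrichmentResult:
    """BFR behaviour of target-linked vs unlinked SNPs over repeated runs."""

    fraction_seeds_all_linked_enriched: float
    median_unlinked_bfr: float
    n_linked_snps: int
    n_unlinked_snps: int


def enrichment_experiment(
    seeds: Sequence[int],
    threshold: float = 3.0,
    linked_radius_cM: float = 0.5,
) -> EnrichmentResult:
    """High-depth, noise-free BSA on repeated simulated crosses.

    A target-linked SNP counts as enriched when its oriented BFR reaches
    ``threshold`` or its denominator frequency is exactly zero (complete
    depletion in the opposite bulk — stronger evidence still). Unlinked
    BFRs are pooled across seeds for the median.
    """
    n_all_pass = 0
    unlinked: List[float] = []
    n_linked_total = 0
    for seed in seeds:
        config = _enrichment_config(seed)
        ds = simulate_dataset(config)
        records = bsa.bsa_screen(
            truth_snps_as_candidates(ds),
            ds.pileups["high"],
            ds.pileups["low"],
            min_depth=8,
            threshold=threshold,
        )
        by_unigene = {u.unigene_id: u for u in ds.truth.unigenes}
        target = config.target_locus_cM
        all_pass = True
        for rec in records:
            u = by_unigene[rec.unigene_id]
            if u.map_cM is not None and abs(u.map_cM - target) <= linked_radius_cM:
                n_linked_total += 1
                if not (rec.excluded or rec.bfr >= threshold):
                    all_pass = False
            elif u.unlinked_polymorphic and not rec.excluded:
                unlinked.append(rec.bfr)
        n_all_pass += all_pass
    return EnrichmentResult(
        fraction_seeds_all_linked_enriched=n_all_pass / len(seeds),
        median_unlinked_bfr=float(np.median(unlinked)),
        n_linked_snps=n_linked_total,
        n_unlinked_snps=len(unlinked),
    )


def hemi_frequency_experiment(seed: int, depth: float = 400.0) -> Dict[str, float]:
    """Mean informative-base frequency at planted hemi-SNPs in the origin
    parent, on noise-free data with balanced homoeologue expression.

    With both homoeologues expressed 1:1 the private allele occupies half
    of the origin parent's reads, so the frequency tends to 0.5.
    """
    config = SimConfig(
        n_unigenes=10,
        mean_length_bp=1000,
        mean_depth=depth,
        error_rate=0.0,
        expression_sigma=0.0,
        single_copy_fraction=0.0,
        seed=seed,
    )
    ds = simulate_dataset(config)
    freqs = []
    for u in ds.truth.unigenes:
        for s in u.snps:
            if s.snp_type != "hemi":
                continue
            sample = "parent_a" if s.origin == "A" else "parent_b"
            col = ds.pileups[sample].get((s.unigene_id, s.pos))
            if col is None:
                continue
            freqs.append(
                bsa.informative_base_frequency(col, s.informative_base)
            )
    return {
        "mean_frequency": float(np.mean(freqs)),
        "n_sites": len(freqs),
    }
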