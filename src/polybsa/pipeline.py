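"""End-to-end pipeline: genotype -> classify -> density-filter -> BSA -> summary.

Given a unigene FASTA reference and four mpileup files (two parents, two
phenotype bulks), runs each stage with the configured thresholds, writes the
tabular outputs (snps.tsv, density.tsv, bfr.tsv) plus a JSON summary of the
per-stage counts and a BFR-threshold breakdown, and logs filter counts to
stderr. Re-running with identical inputs and configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Optional

from . import bsa, classify, genotype, pileup, tables
from .types import BFRRecord, DensityReport, VarietalSNP

logger = logging.getLogger("polybsa")


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    ``low_parent`` declares which parent label ("A" or "B") is the
    low-phenotype parent; BFR orientation follows this declaration.
    """

    reference: str
    pileup_a: str
    pileup_b: str
    pileup_high: str
    pileup_low: str
    out_dir: str = "."
    min_depth: int = 8
    min_allele_reads: int = 2
    min_allele_fraction: float = 0.2
    max_density: float = 5.0
    bfr_threshold: float = 3.0
    one_per_unigene: bool = False
    low_parent: str = "A"
    min_base_quality: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be a positive integer")
        if self.bfr_threshold <= 0:
            raise ValueError("bfr_threshold must be positive")
        if self.low_parent not in ("A", "B"):
            raise ValueError("low_parent must be 'A' or 'B'")


@dataclass
class PipelineResult:
    snps: List[VarietalSNP]
    density_reports: List[DensityReport]
    bfr_records: List[BFRRecord]
    summary: Dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write snps.tsv, density.tsv, bfr.tsv, summary.json."""
    os.makedirs(config.out_dir, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("genotype")
        lengths = pileup.read_unigene_lengths(config.reference)
        call_kwargs = dict(
            min_depth=config.min_depth,
            min_allele_reads=config.min_allele_reads,
            min_allele_fraction=config.min_allele_fraction,
        )
        calls_a = genotype.call_sample(
            pileup.read_pileup(config.pileup_a, config.min_base_quality),
            **call_kwargs,
        )
        calls_b = genotype.call_sample(
            pileup.read_pileup(config.pileup_b, config.min_base_quality),
            **call_kwargs,
        )
        logger.info("called %d / %d positions (parent A / B)", len(calls_a), len(calls_b))
    except Exception as exc:
        raise PipelineError("genotype", exc) from exc

    try:
        stage("classify")
        scan = classify.varietal_snp_scan(calls_a, calls_b)
        logger.info(
            "candidates: %d varietal, %d IHP, %d complex",
            len(scan.snps), scan.n_ihp, len(scan.complex_sites),
        )
    except Exception as exc:
        raise PipelineError("classify", exc) from exc

    try:
        stage("density-filter")
        retained, density_reports = classify.snp_density_filter(
            scan.snps, lengths, max_density=config.max_density
        )
        n_removed = len(scan.snps) - len(retained)
        logger.info("density filter removed %d SNPs", n_removed)
    except Exception as exc:
        raise PipelineError("density-filter", exc) from exc

    try:
        stage("bsa")
        high = pileup.load_pileup_index(config.pileup_high, config.min_base_quality)
        low = pileup.load_pileup_index(config.pileup_low, config.min_base_quality)
        records = bsa.bsa_screen(
            retained,
            high,
            low,
            min_depth=config.min_depth,
            threshold=config.bfr_threshold,
            one_per_unigene=config.one_per_unigene,
            low_parent=config.low_parent,
        )
        logger.info(
            "bsa: %d records, %d depth-passing, %d threshold-passing",
            len(records),
            sum(r.passes_depth for r in records),
            sum(r.passes_threshold for r in records),
        )
    except Exception as exc:
        raise PipelineError("bsa", exc) from exc

    try:
        stage("summarize")
        depth_passing = [r for r in records if r.passes_depth]
        summary = {
            "config": dataclasses.asdict(config),
            "counts": {
                "positions_called_parent_a": len(calls_a),
                "positions_called_parent_b": len(calls_b),
                "candidate_varietal_snps": len(scan.snps),
                "ihp_excluded": scan.n_ihp,
                "complex_excluded": len(scan.complex_sites),
                "density_removed": n_removed,
                "density_retained": len(retained),
                "bfr_evaluated": len(records),
                "depth_passing": len(depth_passing),
                "excluded_zero_denominator": sum(
                    r.excluded for r in depth_passing
                ),
                "threshold_passing": sum(r.passes_threshold for r in records),
            },
            "bfr_thresholds": bsa.threshold_summary(records),
        }
        tables.write_records(
            retained, os.path.join(config.out_dir, "snps.tsv"), VarietalSNP
        )
        tables.write_records(
            density_reports,
            os.path.join(config.out_dir, "density.tsv"),
            DensityReport,
        )
        tables.write_records(
            records, os.path.join(config.out_dir, "bfr.tsv"), BFRRecord
        )
        with open(os.path.join(config.out_dir, "summary.json"), "wt") as out:
            json.dump(summary, out, indent=2, sort_keys=True)
            out.write("\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("summarize", exc) from exc

    return PipelineResult(retained, density_reports, records, summary)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for the CLI exit message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
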