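import os

import pytest

from polybsa import RunConfig, SimConfig, run_pipeline, simulate_dataset, write_dataset
from polybsa.types import BASES, PileupColumn


def make_column(counts, ref_base="A", unigene="u1", pos=1, n_other=0):
    counts = {b: counts.get(b, 0) for b in BASES}
    depth = sum(counts.values()) + n_other
    return PileupColumn(unigene, pos, ref_base, depth, counts, n_other)


@pytest.fixture(scope="session")
def zero_error_config():
    # Noise-free study-scale dataset: uniform expression keeps every position
    # far from the depth cutoff, so allele recovery is effectively certain;
    # the relaxed allele fraction reflects the absence of sequencing error.
    return SimConfig(
        n_unigenes=50,
        mean_length_bp=2000,
        mean_depth=50.0,
        error_rate=0.0,
        expression_sigma=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def zero_error_dataset(zero_error_config):
    return simulate_dataset(zero_error_config)


@pytest.fixture(scope="session")
def zero_error_run(zero_error_dataset, tmp_path_factory):
    """Dataset written to disk and pushed through the whole pipeline."""
    d = tmp_path_factory.mktemp("sim_zero_error")
    write_dataset(zero_error_dataset, str(d))
    config = RunConfig(
        reference=str(d / "reference.fasta"),
        pileup_a=str(d / "parent_a.pileup"),
        pileup_b=str(d / "parent_b.pileup"),
        pileup_high=str(d / "high.pileup"),
        pileup_low=str(d / "low.pileup"),
        out_dir=str(d / "out"),
        min_allele_fraction=0.05,
    )
    result = run_pipeline(config)
    return zero_error_dataset, config, result
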