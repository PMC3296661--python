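"""Sequencing-depth design calculators.

Under random (Lander-Waterman) sampling, the number of reads covering a
position is Poisson with mean equal to the fold-coverage, so the chance of
sampling at least one read is ``1 - exp(-depth)``. For a heterozygous (or,
here, homoeologous) position, each of the two alleles receives an
independent Poisson share with mean ``depth/2``; the probability that both
alleles are seen at least ``r`` times is the squared upper tail of that
Poisson. These closed forms set expectations for the minimum-depth
thresholds used in SNP calling (8-, 12-, 16-fold).

Mapping-design arithmetic: ``n`` recombinant lines spread uniformly over an
interval of ``L`` cM resolve it to ``L/n`` cM on average, and ``m`` markers
over the same interval give one marker per ``L/m`` cM.
"""

from __future__ import annotations

import math

from scipy import stats


def prob_read_sampled(depth: float) -> float:
    """P(position covered by >=1 read) at mean fold-coverage ``depth``."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return 1.0 - math.exp(-depth)


def prob_both_alleles_sampled(depth: float, min_reads_per_allele: int = 1) -> float:
    """P(both alleles each sampled >= r times) at mean fold-coverage ``depth``.

    Per-allele coverage is modelled as independent Poisson with mean
    ``depth / 2`` (each allele takes half the reads at a heterozygous or
    homoeologous site).
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    r = min_reads_per_allele
    if not isinstance(r, int) or r < 1:
        raise ValueError("min_reads_per_allele must be an integer >= 1")
    p_one = float(stats.poisson.sf(r - 1, depth / 2.0))
    return p_one**2


def expected_resolution(interval_cM: float, n_recombinant_lines: int) -> float:
    """Expected mapping resolution (cM) from uniformly spread recombinants."""
    if interval_cM <= 0:
        raise ValueError("interval_cM must be positive")
    if n_recombinant_lines <= 0:
        raise ValueError("n_recombinant_lines must be positive")
    return interval_cM / n_recombinant_lines


def marker_density(interval_cM: float, n_markers: int) -> float:
    """Average spacing (cM per marker) of ``n_markers`` over an interval."""
    if interval_cM <= 0:
        raise ValueError("interval_cM must be positive")
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    return interval_cM / n_markers


def format_probability(p: float, decimals: int = 2) -> str:
    """Render a probability as a percentage string, e.g. ``'99.97%'``."""
    return f"{100.0 * p:.{decimals}f}%"


def format_cM(value: float, decimals: int = 2) -> str:
    """Render a genetic distance, e.g. ``'0.45 cM'``."""
    return f"{value:.{decimals}f} cM"
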