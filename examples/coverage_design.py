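"""Sequencing-depth and mapping-design arithmetic.

How deep must RNA-seq coverage be to see both alleles of a co-expressed
homoeologue pair, and what mapping resolution does a set of recombinant
lines buy across a genetic interval?
"""

from polybsa import (
    expected_resolution,
    format_cM,
    format_probability,
    marker_density,
    prob_both_alleles_sampled,
    prob_read_sampled,
)

print("Read sampling (Lander-Waterman, Poisson coverage):")
for depth in (8, 12, 16):
    print(f"  {depth:>2}-fold: P(>=1 read) = {format_probability(prob_read_sampled(depth))}")

print("\nBoth alleles of a heterozygous/homoeologous site (Poisson split):")
for depth in (8, 16):
    for r in (1, 2):
        p = prob_both_alleles_sampled(depth, r)
        print(f"  {depth:>2}-fold, >= {r} read(s) per allele: {format_probability(p)}")

print("\nMapping design for a 12.2 cM interval:")
print(f"  27 recombinant lines -> expected resolution {format_cM(expected_resolution(12.2, 27))}")
print(f"  39 markers           -> one marker per {format_cM(marker_density(12.2, 39))}")

# Interpretation: 8-fold coverage all but guarantees sampling *a* read, but
# seeing both homoeologous alleles twice needs ~16-fold - which is why the
# minimum-depth threshold matters so much for hemi-SNP calling.
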