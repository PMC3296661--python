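# Methods

This note documents the models, rules and numerical choices behind
`polybsa`, and what the simulator does and does not emulate.

## Pileup model

Input is samtools-mpileup text, 1-based positions. Only substitution
evidence enters allele counts: `.`/`,` resolve to the reference base,
letters to themselves (case folds strand), `^` consumes exactly one
mapping-quality character, `$` is consumed, and `+n`/`-n` indel blocks are
consumed without occupying a depth slot (they annotate the preceding read
base). Deletion placeholders (`*`), `N` calls and reference skips count in
`n_other`, preserving `sum(counts) + n_other == depth`. Base qualities, if
present, are ignored unless a minimum base quality is requested, in which
case sub-threshold bases move to `n_other`; quality handling otherwise
belongs to the upstream aligner, whose settings are the user's choice.

## Consensus genotyping

The caller is deliberately count-based and deterministic rather than
likelihood-based: a base is an allele when it has at least
`min_allele_reads` reads (default 2) **and** at least `min_allele_fraction`
of column depth (default 0.2, boundary inclusive); positions below
`min_depth` (default 8; 12 and 16 are the other standard operating points)
are no-calls. One or two qualifying bases give a call (singleton or IUPAC
pair); zero or three-plus give a no-call — three qualifying alleles in an
inbred tetraploid point to collapsed paralogues, and such positions never
reach SNP classification. Raising `min_depth` can only remove calls
(monotone). The defaults suit real error-bearing data; on synthetic
noise-free data the fraction threshold has nothing to reject and the
benchmark runs lower it to 0.05 so that exact-recovery comparisons measure
the classification logic rather than binomial sampling at the threshold.

The fraction denominator is total column depth (including `n_other`), with
an ACGT-only alternative exposed as a flag; the same convention is used for
bulk frequencies.

## Classification

Positions called in both parents with differing allele sets are classified
as IHP / hemi / simple / complex as described in the README; positions
called in only one parent are excluded (no cross-parent evidence — a
conservative choice), and complex patterns (pair vs pair, pair vs
non-member singleton) are reported separately but never emitted as varietal
SNPs. Agreement with the reference base plays no role: the unigene
reference is a consensus of co-assembled genomes, so only the parent-parent
contrast is meaningful. For simple SNPs both bases are informative, one per
parent; records store parent A's base with origin A by convention and the
BSA stage treats the orientation symmetrically.

The paralogue filter computes `n_snps × 1000 / length_bp` per unigene and
removes all SNPs of unigenes strictly above `max_density` (default 5
SNPs/kb; equality is retained). Unigenes are filtered independently.

## BFR screening

For each candidate SNP the informative-base frequency is measured in both
bulk pileups. Orientation follows the configured low-phenotype parent
label: origin = low parent ⇒ BFR = f_low / f_high, otherwise f_high /
f_low. A zero (or undefined, i.e. zero-depth) denominator yields an
excluded record — kept in the output with a flag, omitted from threshold
summaries' numerators and denominators. `passes_depth` requires
`min_depth` in both bulks; `passes_threshold` additionally requires a
non-excluded BFR ≥ the threshold (default 3.0, inclusive). In
one-SNP-per-unigene mode the SNP with the largest `min(depth_high,
depth_low)` is evaluated, ties to the smallest position — the selection
rule favours the best-measured site.

## Coverage design

Read sampling is Poisson: P(≥1 read) = 1 − e^(−depth). For two-allele
sites the per-allele coverages are modelled as independent Poisson with
mean depth/2, giving P(both ≥ r) = [P(Poisson(depth/2) ≥ r)]². This
Poisson-splitting model reproduces the standard r = 1 design values
exactly (99.93% at 16-fold, 96.37% at 8-fold); at r = 2 it gives 99.40%
and 82.52%, and these model values are what the package asserts.
Resolution and marker-spacing arithmetic are plain quotients
(interval/lines, interval/markers).

## Simulator

Defaults encode the target study design: 97% homoeologue identity (IHPs
i.i.d. per site at 3%), 2 varietal SNPs/kb in polymorphic unigenes, a
12.2 cM segregating interval with the target locus at its centre, bulks of
14 high- and 15 low-phenotype homozygous lines with the first two low
lines double-weighted (mirroring RNA double-loading used to balance
alleles), single-crossover lines with uniform breakpoints and orientation
forced to match the phenotype, 1:1 homoeologue expression (configurable
skew), lognormal per-unigene expression with σ = 1 (mean 1), mean depth
50, per-base error 0.005 (uniform to the other three bases), and 20% of
unigenes single-copy (these yield simple SNPs; duplicated unigenes yield
hemi-SNPs). Unigene classes: linked (map position inside the interval; by
default the first linked unigene sits exactly at the target locus, as the
causal gene's own transcript does), unlinked-polymorphic (per-line 50:50
independent segregation), and monomorphic. Per-position depth is
Poisson(mean depth × expression weight); bulk base mixtures weight each
line's haplotype by its RNA weight. All randomness flows from one seed via
spawned generator streams; a written dataset includes a manifest recording
the full configuration.

What the simulator does **not** emulate: read-level artefacts (quality
profiles, indels, mapping bias, paired-end structure), multi-crossover
lines, shared ancestry between two crosses contributing to one bulk,
normalization distortions, and reference incompleteness. Passing tests
therefore demonstrate the correctness of the calling/classification/BFR
logic under the stated sampling model, not robustness to alignment
pathology in real libraries.

## Benchmark conditions and problem sizes

* **Exact recovery** runs 50 unigenes × 2 kb at uniform 50-fold mean depth
  with zero error. Uniform expression (dispersion 0) is used here because
  exactness is only a property of positions safely above the depth cutoff:
  with dispersed expression some unigenes sit at the 8-fold margin where a
  true allele is unobserved with non-trivial probability, which measures
  binomial sampling, not the pipeline. The dispersed default remains in
  force everywhere else.
* **Enrichment** uses 20 simulated crosses, 24 unigenes × 1 kb each at
  120-fold, noise-free, with five linked unigenes within 0.5 cM of the
  target and five spread across the interval. A linked SNP counts as
  enriched at BFR ≥ 3 or complete depletion (zero denominator). Roughly
  1–2% of crosses genuinely fail the all-linked-SNPs condition because
  several of the 29 lines recombine between a 0.45 cM-distant marker and
  the target — a property of the bulk sizes, not of measurement noise.
  Unlinked BFRs are pooled across crosses before taking the median.
* **Hemi-SNP ceiling** uses 10 duplicated unigenes at 400-fold, zero
  error, and asserts the *mean* informative-base frequency within ±0.05 of
  0.5 (per-site binomial noise at depth 400 has sd ≈ 0.025 by itself).

## Known limitations

* The genotype caller has no quality model; it trusts the upstream
  aligner's filtering.
* BFR carries no significance statistic; the ≥ 3 cutoff is an operating
  point, and threshold summaries are provided so users can choose their
  own.
* Simple-SNP orientation assumes the parent-A convention throughout; with
  `low_parent="B"` configurations the origin labels must come from the
  same classification run.
* Floating-point quotients can land imperceptibly below an intended
  integer BFR (e.g. 0.3/0.1 < 3); thresholds compare raw floats.
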