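"""Synthetic tetraploid transcriptome data with full ground truth.

The generator emulates the study design this pipeline targets:

* **Homoeologue pairs.** Most unigenes exist as two co-expressed gene copies
  (the A- and B-genome homoeologues) at ~97% identity, co-mapped onto one
  consensus reference; their fixed differences are inter-homoeologue
  polymorphisms (IHPs), identical in both varieties. A configurable fraction
  of unigenes is single-copy.
* **Varietal SNPs.** Polymorphic unigenes carry variety-private alleles at
  ~2 SNPs/kb. In a duplicated unigene the private allele sits on one
  homoeologue of one parent, so that parent shows a two-base ambiguity and
  the other a single base (a hemi-SNP); in single-copy unigenes the parents
  show two plain different bases (a simple SNP).
* **A segregating interval with recombinant lines.** Each line is homozygous
  with a single crossover at a uniform position within the mapped interval;
  its phenotype is its genotype at the target locus. High-phenotype lines
  carry the donor (parent B) allele at the target, low-phenotype lines the
  recurrent (parent A) allele. Bulks mix lines with per-line RNA weights
  (supporting double-weighted lines). Unigenes may be linked (a map position
  inside the interval), unlinked-polymorphic (independent 50:50 segregation),
  or monomorphic.
* **Expression and noise.** Per-unigene expression weights are lognormal
  (mean 1); per-position depth is Poisson(mean depth x weight); each sampled
  base is mis-read with the per-base error rate, uniformly to the other
  three bases.

Everything is reproducible from the single seed, and every emitted pileup
column is reconstructible from the truth plus the seeded error process.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotype import iupac_code
from .types import BASES, PileupColumn

SAMPLES = ("parent_a", "parent_b", "high", "low")

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic dataset."""

    n_unigenes: int = 50
    mean_length_bp: int = 2000
    length_sigma: float = 0.3  # lognormal spread of unigene lengths
    min_length_bp: int = 300
    homoeologue_identity: float = 0.97
    single_copy_fraction: float = 0.2
    varietal_snp_rate_per_kb: float = 2.0
    linked_fraction: float = 0.5
    unlinked_polymorphic_fraction: float = 0.25
    interval_cM: float = 12.2
    target_locus_cM: float = 6.1
    linked_map_positions: Optional[Sequence[float]] = None
    n_lines_high: int = 14
    n_lines_low: int = 15
    weights_high: Optional[Sequence[float]] = None
    weights_low: Optional[Sequence[float]] = None  # default double-weights two lines
    homoeologue_ratio: float = 0.5  # expression share of the A-genome copy
    expression_sigma: float = 1.0  # lognormal sd of expression weights
    mean_depth: float = 50.0
    error_rate: float = 0.005
    read_length_bp: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.homoeologue_identity <= 1.0:
            raise ValueError("homoeologue_identity must be in (0, 1]")
        if self.varietal_snp_rate_per_kb < 0 or self.error_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_lines_high < 1 or self.n_lines_low < 1:
            raise ValueError("bulks must be non-empty")

    def resolved_weights(self) -> Tuple[np.ndarray, np.ndarray]:
        if self.weights_high is None:
            wh = np.ones(self.n_lines_high)
        else:
            wh = np.asarray(self.weights_high, dtype=float)
        if self.weights_low is None:
            wl = np.ones(self.n_lines_low)
            wl[: min(2, self.n_lines_low)] = 2.0
        else:
            wl = np.asarray(self.weights_low, dtype=float)
        if len(wh) != self.n_lines_high or len(wl) != self.n_lines_low:
            raise ValueError("per-line weights must match bulk sizes")
        return wh, wl


@dataclass(frozen=True)
class PlantedSNP:
    """Ground truth for one planted varietal SNP."""

    unigene_id: str
    pos: int  # 1-based
    snp_type: str  # "hemi" | "simple"
    informative_base: str
    origin: str  # parent whose allele set privately holds informative_base
    shared_base: Optional[str]
    genotype_a: str  # IUPAC code of parent A's true allele set
    genotype_b: str


@dataclass
class SimLine:
    name: str
    bulk: str  # "high" | "low"
    weight: float
    breakpoint_cM: float
    donor_left: bool  # donor (parent B) segment on [0, breakpoint)

    def genotype_at(self, map_cM: float) -> int:
        """1 = donor (parent B) allele, 0 = recurrent (parent A)."""
        return int((map_cM < self.breakpoint_cM) == self.donor_left)


@dataclass
class SimUnigene:
    unigene_id: str
    length_bp: int
    single_copy: bool
    map_cM: Optional[float]  # None => not linked to the interval
    unlinked_polymorphic: bool
    expression: float
    ref: np.ndarray  # consensus reference, ints 0..3
    ihp_positions: np.ndarray  # 0-based
    snps: List[PlantedSNP]
    # per-parent haplotype bases of the two homoeologue copies (ints 0..3);
    # copy-B arrays are None for single-copy unigenes
    base_a_parent_a: np.ndarray = field(repr=False, default=None)
    base_b_parent_a: Optional[np.ndarray] = field(repr=False, default=None)
    base_a_parent_b: np.ndarray = field(repr=False, default=None)
    base_b_parent_b: Optional[np.ndarray] = field(repr=False, default=None)


@dataclass
class SimTruth:
    config: SimConfig
    unigenes: List[SimUnigene]
    lines: List[SimLine]
    # per unlinked-polymorphic unigene: 0/1 donor-like genotype per line,
    # aligned with ``lines`` order
    unlinked_genotypes: Dict[str, np.ndarray]

    def donor_dosage(self, unigene: SimUnigene, bulk: str) -> float:
        """Weighted fraction of the bulk's RNA carrying parent B's allele."""
        idx = [i for i, l in enumerate(self.lines) if l.bulk == bulk]
        w = np.array([self.lines[i].weight for i in idx])
        if unigene.map_cM is not None:
            g = np.array(
                [self.lines[i].genotype_at(unigene.map_cM) for i in idx]
            )
        elif unigene.unlinked_polymorphic:
            g = self.unlinked_genotypes[unigene.unigene_id][idx]
        else:
            return 0.0
        return float(np.sum(w * g) / np.sum(w))

    def planted_snp_keys(self) -> set:
        """Planted SNPs as comparable tuples (classification oracle)."""
        return {
            (
                s.unigene_id,
                s.pos,
                s.snp_type,
                s.informative_base,
                s.origin,
                s.shared_base,
                s.genotype_a,
                s.genotype_b,
            )
            for u in self.unigenes
            for s in u.snps
        }


def simulate_homoeologue_pair(
    length: int, identity: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One ancestral sequence and its diverged homoeologue.

    Positions mutate independently with probability ``1 - identity``;
    substitutions are uniform over the three alternative bases. Returns
    (copy A, copy B, 0-based IHP positions).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    seq_a = rng.integers(0, 4, size=length)
    seq_b = seq_a.copy()
    mutate = rng.random(length) < (1.0 - identity)
    idx = np.nonzero(mutate)[0]
    if idx.size:
        seq_b[idx] = (seq_b[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return seq_a, seq_b, idx


def simulate_cross(config: SimConfig, rng: np.random.Generator) -> List[SimLine]:
    """Recombinant homozygous lines bulked by phenotype at the target locus.

    Single-crossover model: each line has one breakpoint uniform on the
    interval and is donor on one side; its bulk assignment is forced by the
    genotype at the target locus (high = donor, low = recurrent).
    """
    wh, wl = config.resolved_weights()
    lines: List[SimLine] = []
    specs = [("high", config.n_lines_high, wh, 1), ("low", config.n_lines_low, wl, 0)]
    for bulk, n, weights, target_genotype in specs:
        for i in range(n):
            bp = float(rng.uniform(0.0, config.interval_cM))
            donor_left = bool(rng.integers(0, 2))
            line = SimLine(f"{bulk[0].upper()}{i + 1}", bulk, float(weights[i]), bp, donor_left)
            if line.genotype_at(config.target_locus_cM) != target_genotype:
                line.donor_left = not donor_left
            lines.append(line)
    return lines


def _plant_snps(
    u: SimUnigene, rate_per_kb: float, rng: np.random.Generator
) -> None:
    """Plant varietal SNPs at non-IHP positions of a polymorphic unigene."""
    n = rng.poisson(rate_per_kb * u.length_bp / 1000.0)
    if n == 0:
        return
    candidates = np.setdiff1d(np.arange(u.length_bp), u.ihp_positions)
    n = min(n, candidates.size)
    positions = np.sort(rng.choice(candidates, size=n, replace=False))
    for p in positions:
        x = int(u.base_a_parent_a[p])
        y = (x + int(rng.integers(1, 4))) % 4  # derived base != x
        if u.single_copy:
            derived_parent = "A" if rng.integers(0, 2) else "B"
            if derived_parent == "A":
                u.base_a_parent_a[p] = y
                code_a, code_b = BASES[y], BASES[x]
            else:
                u.base_a_parent_b[p] = y
                code_a, code_b = BASES[x], BASES[y]
            # classifier convention: parent A's base is the informative one
            u.snps.append(
                PlantedSNP(
                    u.unigene_id, int(p) + 1, "simple",
                    informative_base=code_a, origin="A", shared_base=None,
                    genotype_a=code_a, genotype_b=code_b,
                )
            )
        else:
            origin = "A" if rng.integers(0, 2) else "B"
            on_copy_a = bool(rng.integers(0, 2))
            if origin == "A":
                target = u.base_a_parent_a if on_copy_a else u.base_b_parent_a
            else:
                target = u.base_a_parent_b if on_copy_a else u.base_b_parent_b
            target[p] = y
            pair = iupac_code({BASES[x], BASES[y]})
            code_a, code_b = (pair, BASES[x]) if origin == "A" else (BASES[x], pair)
            u.snps.append(
                PlantedSNP(
                    u.unigene_id, int(p) + 1, "hemi",
                    informative_base=BASES[y], origin=origin,
                    shared_base=BASES[x],
                    genotype_a=code_a, genotype_b=code_b,
                )
            )


def simulate_truth(config: SimConfig) -> SimTruth:
    """Build the full ground truth (sequences, SNPs, lines, expression)."""
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    n = config.n_unigenes
    n_linked = int(round(config.linked_fraction * n))
    n_unlinked = int(round(config.unlinked_polymorphic_fraction * n))
    n_linked = min(n_linked, n)
    n_unlinked = min(n_unlinked, n - n_linked)

    if config.linked_map_positions is not None:
        map_positions = [float(p) for p in config.linked_map_positions]
        n_linked = len(map_positions)
        if n_linked + n_unlinked > n:
            raise ValueError("more map positions than unigenes")
    else:
        # the target gene's own transcript is expressed and linked at 0 cM
        # from the target; remaining linked unigenes spread uniformly
        map_positions = [config.target_locus_cM] + [
            float(rng.uniform(0.0, config.interval_cM))
            for _ in range(max(0, n_linked - 1))
        ]

    lines = simulate_cross(config, rng)

    unigenes: List[SimUnigene] = []
    unlinked_genotypes: Dict[str, np.ndarray] = {}
    for i in range(n):
        uid = f"u{i + 1:04d}"
        length = int(
            rng.lognormal(
                math.log(config.mean_length_bp) - config.length_sigma**2 / 2,
                config.length_sigma,
            )
        )
        length = max(length, config.min_length_bp)
        single_copy = bool(rng.random() < config.single_copy_fraction)
        if single_copy:
            seq_a = rng.integers(0, 4, size=length)
            seq_b, ihp = None, np.empty(0, dtype=int)
        else:
            seq_a, seq_b, ihp = simulate_homoeologue_pair(
                length, config.homoeologue_identity, rng
            )
        expression = float(
            rng.lognormal(-config.expression_sigma**2 / 2, config.expression_sigma)
        )
        if i < n_linked:
            map_cM, unlinked_poly = map_positions[i], False
        elif i < n_linked + n_unlinked:
            map_cM, unlinked_poly = None, True
        else:
            map_cM, unlinked_poly = None, False
        u = SimUnigene(
            unigene_id=uid,
            length_bp=length,
            single_copy=single_copy,
            map_cM=map_cM,
            unlinked_polymorphic=unlinked_poly,
            expression=expression,
            ref=seq_a.copy(),
            ihp_positions=ihp,
            snps=[],
            base_a_parent_a=seq_a.copy(),
            base_b_parent_a=None if single_copy else seq_b.copy(),
            base_a_parent_b=seq_a.copy(),
            base_b_parent_b=None if single_copy else seq_b.copy(),
        )
        if map_cM is not None or unlinked_poly:
            _plant_snps(u, config.varietal_snp_rate_per_kb, rng)
        if unlinked_poly:
            unlinked_genotypes[uid] = rng.integers(0, 2, size=len(lines))
        unigenes.append(u)

    return SimTruth(config, unigenes, lines, unlinked_genotypes)


def _sample_channels(
    truth: SimTruth, u: SimUnigene, sample: str
) -> List[Tuple[np.ndarray, float]]:
    r = truth.config.homoeologue_ratio
    if sample == "parent_a":
        pa, pb = 1.0, 0.0
    elif sample == "parent_b":
        pa, pb = 0.0, 1.0
    elif sample in ("high", "low"):
        d = truth.donor_dosage(u, sample)
        pa, pb = 1.0 - d, d
    else:
        raise ValueError(f"unknown sample {sample!r}")
    if u.single_copy:
        channels = [(u.base_a_parent_a, pa), (u.base_a_parent_b, pb)]
    else:
        channels = [
            (u.base_a_parent_a, r * pa),
            (u.base_b_parent_a, (1.0 - r) * pa),
            (u.base_a_parent_b, r * pb),
            (u.base_b_parent_b, (1.0 - r) * pb),
        ]
    return [(arr, w) for arr, w in channels if w > 0.0]


def _apply_error(
    counts: np.ndarray, error_rate: float, rng: np.random.Generator
) -> None:
    """Mis-read each base with ``error_rate``, uniformly to the other three."""
    errors = rng.binomial(counts, error_rate)
    counts -= errors
    for b in range(4):
        e = errors[:, b]
        others = [x for x in range(4) if x != b]
        x1 = rng.binomial(e, 1.0 / 3.0)
        rem = e - x1
        x2 = rng.binomial(rem, 0.5)
        counts[:, others[0]] += x1
        counts[:, others[1]] += x2
        counts[:, others[2]] += rem - x2


def simulate_sample_counts(
    truth: SimTruth,
    sample: str,
    rng: np.random.Generator,
    mean_depth: Optional[float] = None,
    error_rate: Optional[float] = None,
) -> Dict[str, np.ndarray]:
    """Per-unigene (length x 4) base-count matrices for one sample."""
    cfg = truth.config
    mean_depth = cfg.mean_depth if mean_depth is None else mean_depth
    error_rate = cfg.error_rate if error_rate is None else error_rate
    out: Dict[str, np.ndarray] = {}
    for u in truth.unigenes:
        L = u.length_bp
        depth = rng.poisson(mean_depth * u.expression, size=L)
        channels = _sample_channels(truth, u, sample)
        bases = np.stack([arr for arr, _ in channels])
        weights = np.array([w for _, w in channels])
        weights = weights / weights.sum()
        counts = np.zeros((L, 4), dtype=np.int64)
        invariant = np.all(bases == bases[0], axis=0)
        inv_idx = np.nonzero(invariant)[0]
        counts[inv_idx, bases[0][inv_idx]] = depth[inv_idx]
        for p in np.nonzero(~invariant)[0]:
            probs = np.bincount(bases[:, p], weights=weights, minlength=4)
            counts[p] = rng.multinomial(depth[p], probs)
        if error_rate > 0.0:
            _apply_error(counts, error_rate, rng)
        out[u.unigene_id] = counts
    return out


def counts_to_columns(
    truth: SimTruth, counts: Dict[str, np.ndarray]
) -> Dict[Tuple[str, int], PileupColumn]:
    """Turn count matrices into a pileup index (zero-depth positions omitted)."""
    index: Dict[Tuple[str, int], PileupColumn] = {}
    for u in truth.unigenes:
        mat = counts[u.unigene_id]
        depths = mat.sum(axis=1)
        for p in np.nonzero(depths)[0]:
            index[(u.unigene_id, int(p) + 1)] = PileupColumn(
                unigene_id=u.unigene_id,
                pos=int(p) + 1,
                ref_base=BASES[int(u.ref[p])],
                depth=int(depths[p]),
                counts={b: int(mat[p, _BASE_IDX[b]]) for b in BASES},
            )
    return index


def simulate_mapped_read_counts(
    truth: SimTruth, rng: np.random.Generator, mean_depth: Optional[float] = None
) -> Dict[str, int]:
    """Per-unigene mapped-read counts consistent with the depth model."""
    cfg = truth.config
    mean_depth = cfg.mean_depth if mean_depth is None else mean_depth
    return {
        u.unigene_id: int(
            rng.poisson(u.expression * mean_depth * u.length_bp / cfg.read_length_bp)
        )
        for u in truth.unigenes
    }


@dataclass
class SimDataset:
    """A complete simulated experiment: truth plus per-sample pileups/counts."""

    truth: SimTruth
    pileups: Dict[str, Dict[Tuple[str, int], PileupColumn]]
    read_counts: Dict[str, Dict[str, int]]


def simulate_dataset(
    config: SimConfig,
    mean_depth: Optional[float] = None,
    error_rate: Optional[float] = None,
) -> SimDataset:
    """Simulate truth plus pileups and read counts for all four samples."""
    truth = simulate_truth(config)
    ss = np.random.SeedSequence(config.seed)
    # child 0 regenerates truth; children 1..4 drive the four samples
    children = ss.spawn(1 + len(SAMPLES))
    pileups = {}
    read_counts = {}
    for child, sample in zip(children[1:], SAMPLES):
        rng = np.random.default_rng(child)
        counts = simulate_sample_counts(
            truth, sample, rng, mean_depth=mean_depth, error_rate=error_rate
        )
        pileups[sample] = counts_to_columns(truth, counts)
        read_counts[sample] = simulate_mapped_read_counts(
            truth, rng, mean_depth=mean_depth
        )
    return SimDataset(truth, pileups, read_counts)


def write_dataset(dataset: SimDataset, out_dir: str) -> None:
    """Write reference FASTA, four mpileup files, counts files and truth."""
    from . import pileup as pileup_io

    os.makedirs(out_dir, exist_ok=True)
    truth = dataset.truth
    records = [
        SeqRecord(
            Seq("".join(BASES[int(b)] for b in u.ref)),
            id=u.unigene_id,
            description="",
        )
        for u in truth.unigenes
    ]
    SeqIO.write(records, os.path.join(out_dir, "reference.fasta"), "fasta")

    for sample in SAMPLES:
        index = dataset.pileups[sample]
        cols = (index[k] for k in sorted(index))
        pileup_io.write_mpileup(cols, os.path.join(out_dir, f"{sample}.pileup"))
        with open(os.path.join(out_dir, f"counts_{sample}.tsv"), "wt") as out:
            out.write("unigene_id\tmapped_reads\n")
            for uid in sorted(dataset.read_counts[sample]):
                out.write(f"{uid}\t{dataset.read_counts[sample][uid]}\n")

    with open(os.path.join(out_dir, "truth_snps.tsv"), "wt") as out:
        out.write(
            "unigene_id\tpos\tsnp_type\tinformative_base\torigin\t"
            "shared_base\tgenotype_a\tgenotype_b\tmap_cM\n"
        )
        for u in truth.unigenes:
            map_s = "" if u.map_cM is None else f"{u.map_cM:.6g}"
            for s in u.snps:
                out.write(
                    f"{s.unigene_id}\t{s.pos}\t{s.snp_type}\t"
                    f"{s.informative_base}\t{s.origin}\t"
                    f"{s.shared_base or ''}\t{s.genotype_a}\t{s.genotype_b}\t"
                    f"{map_s}\n"
                )

    with open(os.path.join(out_dir, "truth_lines.tsv"), "wt") as out:
        out.write("name\tbulk\tweight\tbreakpoint_cM\tdonor_left\n")
        for line in truth.lines:
            out.write(
                f"{line.name}\t{line.bulk}\t{line.weight:.6g}\t"
                f"{line.breakpoint_cM:.6g}\t{line.donor_left}\n"
            )

    manifest = {"config": dataclasses.asdict(truth.config)}
    if manifest["config"]["linked_map_positions"] is not None:
        manifest["config"]["linked_map_positions"] = list(
            manifest["config"]["linked_map_positions"]
        )
    if manifest["config"]["weights_high"] is not None:
        manifest["config"]["weights_high"] = list(manifest["config"]["weights_high"])
    if manifest["config"]["weights_low"] is not None:
        manifest["config"]["weights_low"] = list(manifest["config"]["weights_low"])
    with open(os.path.join(out_dir, "manifest.json"), "wt") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
        out.write("\n")
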