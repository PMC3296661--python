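import numpy as np
import pytest
from scipy import stats

from polybsa import (
    SimConfig,
    simulate_cross,
    simulate_dataset,
    simulate_homoeologue_pair,
    simulate_truth,
)
from polybsa.pileup import parse_pileup_line
from polybsa.simulate import counts_to_columns, simulate_sample_counts
from polybsa.types import BASES


class TestHomoeologuePair:
    def test_full_identity_means_no_ihps(self):
        rng = np.random.default_rng(0)
        a, b, ihp = simulate_homoeologue_pair(500, 1.0, rng)
        assert ihp.size == 0
        assert np.array_equal(a, b)

    def test_ihp_count_follows_binomial_model(self):
        rng = np.random.default_rng(1)
        _, _, ihp = simulate_homoeologue_pair(10_000, 0.97, rng)
        lo, hi = stats.binom.interval(0.999, 10_000, 0.03)
        assert lo <= ihp.size <= hi

    def test_substitutions_never_identity(self):
        rng = np.random.default_rng(2)
        a, b, ihp = simulate_homoeologue_pair(2000, 0.9, rng)
        assert np.all(a[ihp] != b[ihp])

    def test_seed_determinism(self):
        a1, b1, i1 = simulate_homoeologue_pair(1000, 0.97, np.random.default_rng(3))
        a2, b2, i2 = simulate_homoeologue_pair(1000, 0.97, np.random.default_rng(3))
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)
        assert np.array_equal(i1, i2)


class TestCross:
    config = SimConfig(seed=4)

    def test_bulks_are_pure_at_the_target_locus(self):
        lines = simulate_cross(self.config, np.random.default_rng(4))
        t = self.config.target_locus_cM
        for line in lines:
            assert line.genotype_at(t) == (1 if line.bulk == "high" else 0)

    def test_marker_at_target_shares_its_dosage(self):
        truth = simulate_truth(self.config)
        at_target = [u for u in truth.unigenes if u.map_cM == self.config.target_locus_cM]
        assert at_target, "the target gene's transcript is always simulated"
        for bulk, expected in (("high", 1.0), ("low", 0.0)):
            assert truth.donor_dosage(at_target[0], bulk) == pytest.approx(expected)

    def test_wrong_bulk_dosage_scales_linearly_with_distance(self):
        """Uniform single-breakpoint model: the chance a line's genotype at
        a marker differs from its target genotype equals distance/interval."""
        config = SimConfig(n_lines_high=4000, n_lines_low=4000, seed=5)
        lines = simulate_cross(config, np.random.default_rng(5))
        t, L = config.target_locus_cM, config.interval_cM
        for distance in (1.0, 3.0, 5.0):
            marker = t - distance
            flipped = np.mean(
                [l.genotype_at(marker) != l.genotype_at(t) for l in lines]
            )
            se = np.sqrt((distance / L) * (1 - distance / L) / len(lines))
            assert abs(flipped - distance / L) < 4 * se


class TestPileupGeneration:
    def test_zero_error_parent_shows_only_planted_bases(self):
        config = SimConfig(
            n_unigenes=6, mean_length_bp=800, error_rate=0.0,
            expression_sigma=0.0, mean_depth=60, seed=6,
        )
        truth = simulate_truth(config)
        rng = np.random.default_rng(60)
        counts = simulate_sample_counts(truth, "parent_a", rng)
        checked = 0
        for u in truth.unigenes:
            mat = counts[u.unigene_id]
            channels = [u.base_a_parent_a] + (
                [] if u.single_copy else [u.base_b_parent_a]
            )
            for s in u.snps:
                p = s.pos - 1
                # parent A's column may only contain parent A's true alleles
                allowed = {int(c[p]) for c in channels}
                observed = set(np.nonzero(mat[p])[0])
                assert observed <= allowed
                checked += 1
        assert checked > 0

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        from polybsa import write_dataset

        config = SimConfig(n_unigenes=4, mean_length_bp=500, seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate_dataset(config), str(d1))
        write_dataset(simulate_dataset(config), str(d2))
        for name in ("parent_a.pileup", "high.pileup", "reference.fasta",
                     "truth_snps.tsv", "counts_low.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_emitted_pileup_parses_with_exact_count_agreement(self):
        config = SimConfig(n_unigenes=3, mean_length_bp=400, seed=10)
        truth = simulate_truth(config)
        rng = np.random.default_rng(10)
        counts = simulate_sample_counts(truth, "high", rng)
        index = counts_to_columns(truth, counts)
        import io
        from polybsa.pileup import write_mpileup

        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "s.pileup")
            write_mpileup((index[k] for k in sorted(index)), path)
            with open(path) as handle:
                for i, line in enumerate(handle, start=1):
                    col = parse_pileup_line(line, line_number=i)
                    ref = index[(col.unigene_id, col.pos)]
                    assert dict(col.counts) == dict(ref.counts)
                    assert col.depth == ref.depth

    def test_error_process_perturbs_a_small_fraction(self):
        config = SimConfig(
            n_unigenes=4, mean_length_bp=1000, error_rate=0.01,
            expression_sigma=0.0, mean_depth=100, seed=11,
            single_copy_fraction=0.0, homoeologue_identity=1.0,
            linked_fraction=0.0, unlinked_polymorphic_fraction=0.0,
        )
        truth = simulate_truth(config)
        rng = np.random.default_rng(11)
        counts = simulate_sample_counts(truth, "parent_a", rng)
        mismatch = total = 0
        for u in truth.unigenes:
            mat = counts[u.unigene_id]
            true_base = u.base_a_parent_a
            total += mat.sum()
            mismatch += mat.sum() - mat[np.arange(u.length_bp), true_base].sum()
        rate = mismatch / total
        assert rate == pytest.approx(0.01, rel=0.25)


def test_collapsed_paralogue_unigene_is_density_filtered():
    """A unigene whose apparent varietal SNP density exceeds 5/kb (the
    signature of co-mapped paralogues) is dropped wholesale."""
    from polybsa import call_sample, snp_density_filter, varietal_snp_scan
    from polybsa.types import UnigeneRecord

    config = SimConfig(
        n_unigenes=2, mean_length_bp=1000, varietal_snp_rate_per_kb=12.0,
        error_rate=0.0, expression_sigma=0.0, mean_depth=60,
        linked_fraction=1.0, seed=12,
    )
    ds = simulate_dataset(config)
    calls_a = call_sample(ds.pileups["parent_a"].values(), min_allele_fraction=0.05)
    calls_b = call_sample(ds.pileups["parent_b"].values(), min_allele_fraction=0.05)
    scan = varietal_snp_scan(calls_a, calls_b)
    lengths = [UnigeneRecord(u.unigene_id, u.length_bp) for u in ds.truth.unigenes]
    retained, reports = snp_density_filter(scan.snps, lengths)
    dense = [r for r in reports if r.density > 5.0]
    assert dense, "planted 12 SNPs/kb must exceed the threshold"
    for r in dense:
        assert not r.retained
        assert all(s.unigene_id != r.unigene_id for s in retained)
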