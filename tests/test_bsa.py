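import math

import numpy as np
import pytest

from polybsa import (
    bsa_screen,
    bulk_frequency_ratio,
    informative_base_frequency,
    threshold_summary,
)
from polybsa.types import VarietalSNP

from conftest import make_column


def snp(unigene="u1", pos=10, snp_type="hemi", informative="G", origin="B"):
    return VarietalSNP(
        unigene, pos, snp_type, "C", "S", informative, origin,
        "C" if snp_type == "hemi" else None, 20, 20,
    )


class TestInformativeBaseFrequency:
    def test_fraction_of_total_depth(self):
        col = make_column({"C": 9, "G": 1})
        assert informative_base_frequency(col, "G") == pytest.approx(0.1)

    def test_absent_base_is_zero(self):
        assert informative_base_frequency(make_column({"C": 9, "G": 1}), "A") == 0.0

    def test_pure_column_is_one(self):
        assert informative_base_frequency(make_column({"T": 7}), "T") == 1.0

    def test_zero_depth_is_undefined(self):
        col = make_column({})
        assert math.isnan(informative_base_frequency(col, "A"))

    def test_denominator_choice(self):
        col = make_column({"G": 2, "C": 6}, n_other=2)
        assert informative_base_frequency(col, "G") == pytest.approx(0.2)
        assert informative_base_frequency(col, "G", acgt_only=True) == pytest.approx(
            0.25
        )


class TestBulkFrequencyRatio:
    def test_high_parent_origin_divides_high_by_low(self):
        # quotient of the stated bulk frequencies for a tightly linked
        # hemi-SNP from the high parent
        assert bulk_frequency_ratio(0.397, 0.017, "B") == pytest.approx(
            23.352941, abs=1e-6
        )

    def test_zero_denominator_is_excluded(self):
        # low-parent origin puts the high-bulk frequency in the denominator
        assert math.isnan(bulk_frequency_ratio(0.0, 0.4, "A"))
        assert math.isnan(bulk_frequency_ratio(0.0, 0.0, "A"))
        assert math.isnan(bulk_frequency_ratio(0.0, 0.0, "B"))

    def test_equal_frequencies_give_unity(self):
        assert bulk_frequency_ratio(0.25, 0.25, "A") == 1.0
        assert bulk_frequency_ratio(0.25, 0.25, "B") == 1.0

    def test_low_parent_declaration_flips_orientation(self):
        assert bulk_frequency_ratio(0.4, 0.1, "A", low_parent="B") == pytest.approx(4.0)
        assert bulk_frequency_ratio(0.4, 0.1, "A", low_parent="A") == pytest.approx(
            0.25
        )


class TestBsaScreen:
    def index(self, **cols):
        return {("u1", pos): col for pos, col in cols.items()}

    def test_missing_bulk_coverage_fails_depth(self):
        high = self.index()
        low = {("u1", 10): make_column({"G": 5, "C": 15}, pos=10)}
        (rec,) = bsa_screen([snp()], high, low)
        assert not rec.passes_depth
        assert rec.depth_high == 0
        assert rec.excluded

    def test_record_matches_hand_computation(self):
        high = {("u1", 10): make_column({"G": 8, "C": 12}, pos=10)}
        low = {("u1", 10): make_column({"G": 1, "C": 19}, pos=10)}
        (rec,) = bsa_screen([snp(origin="B")], high, low, threshold=3.0)
        assert rec.f_high == pytest.approx(0.4)
        assert rec.f_low == pytest.approx(0.05)
        assert rec.bfr == pytest.approx(8.0)
        assert rec.passes_depth and rec.passes_threshold and not rec.excluded

    def test_one_per_unigene_prefers_best_covered_then_smallest_pos(self):
        snps = [snp(pos=10), snp(pos=20), snp(pos=30)]
        high = {
            ("u1", 10): make_column({"G": 10}, pos=10),
            ("u1", 20): make_column({"G": 30}, pos=20),
            ("u1", 30): make_column({"G": 30}, pos=30),
        }
        low = {
            ("u1", 10): make_column({"G": 40}, pos=10),
            ("u1", 20): make_column({"G": 25}, pos=20),
            ("u1", 30): make_column({"G": 25}, pos=30),
        }
        records = bsa_screen(snps, high, low, one_per_unigene=True)
        assert [r.pos for r in records] == [20]  # min-depth 25 beats 10; tie -> pos 20

    def test_swapping_bulks_and_origin_preserves_bfr(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            fh, fl = rng.random(2)
            dh = make_column({"G": int(50 * fh), "C": 50 - int(50 * fh)}, pos=10)
            dl = make_column({"G": int(50 * fl), "C": 50 - int(50 * fl)}, pos=10)
            for origin, flipped in (("A", "B"), ("B", "A")):
                (r1,) = bsa_screen(
                    [snp(origin=origin)], {("u1", 10): dh}, {("u1", 10): dl}
                )
                (r2,) = bsa_screen(
                    [snp(origin=flipped)], {("u1", 10): dl}, {("u1", 10): dh}
                )
                if r1.excluded:
                    assert r2.excluded
                else:
                    assert r1.bfr == pytest.approx(r2.bfr)

    def test_raising_min_depth_only_shrinks_evaluated_set(self, zero_error_run):
        ds, config, result = zero_error_run
        from polybsa import load_pileup_index

        high = load_pileup_index(config.pileup_high)
        low = load_pileup_index(config.pileup_low)
        counts = []
        for depth in (8, 12, 16):
            records = bsa_screen(result.snps, high, low, min_depth=depth)
            counts.append(sum(r.passes_depth for r in records))
        assert counts[0] >= counts[1] >= counts[2]

    def test_unlinked_snp_bfr_concentrates_around_unity_at_high_depth(self):
        """Binomial sampling oracle: at depth 400 and balanced bulks the
        oriented ratio stays within [1/1.5, 1.5] in >=99% of draws."""
        rng = np.random.default_rng(11)
        depth, f = 400, 0.25
        fh = rng.binomial(depth, f, size=2000) / depth
        fl = rng.binomial(depth, f, size=2000) / depth
        ratio = fh / fl
        inside = np.mean((ratio >= 1 / 1.5) & (ratio <= 1.5))
        assert inside >= 0.99


class TestThresholdSummary:
    @staticmethod
    def record(pos, bfr):
        from polybsa.types import BFRRecord

        return BFRRecord(
            "u1", pos, "hemi", "B", "G", 0.4, 0.1, 50, 50,
            bfr, False, True, bfr >= 3.0,
        )

    def test_counts_and_percentages(self):
        recs = [self.record(i + 1, v) for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0])]
        rows = {r["cutoff"]: r for r in threshold_summary(recs, [2, 3])}
        assert rows[2.0]["count"] == 4 and rows[2.0]["percent"] == pytest.approx(80.0)
        assert rows[3.0]["count"] == 3 and rows[3.0]["percent"] == pytest.approx(60.0)

    def test_cutoff_is_inclusive(self):
        # 0.75 and 0.25 are exact binary fractions, so the ratio is exactly 3
        high = {("u1", 1): make_column({"G": 75, "C": 25}, pos=1)}
        low = {("u1", 1): make_column({"G": 25, "C": 75}, pos=1)}
        (rec,) = bsa_screen([snp(pos=1, origin="B")], high, low)
        assert rec.bfr == 3.0
        assert threshold_summary([rec], [3.0])[0]["count"] == 1

    def test_all_excluded_yields_zeros(self):
        high = {("u1", 1): make_column({"C": 20}, pos=1)}
        low = {("u1", 1): make_column({"C": 20}, pos=1)}
        (rec,) = bsa_screen([snp(pos=1, origin="B")], high, low)
        assert rec.excluded
        rows = threshold_summary([rec], [2, 3])
        assert all(r["count"] == 0 and r["percent"] == 0.0 for r in rows)

    def test_empty_records(self):
        rows = threshold_summary([], [2, 3])
        assert all(r["count"] == 0 and r["percent"] == 0.0 for r in rows)


def test_bfr_equals_brute_force_recount(zero_error_run):
    """Every screened BFR equals an independent recount straight from the
    mpileup text (character counting, no shared parsing code)."""
    ds, config, result = zero_error_run

    def recount(path):
        table = {}
        with open(path) as handle:
            for line in handle:
                uid, pos, ref, depth, bases = line.rstrip("\n").split("\t")[:5]
                counts = {b: bases.count(b) for b in "ACGT"}
                counts[ref] = counts.get(ref, 0) + bases.count(".") + bases.count(",")
                table[(uid, int(pos))] = (int(depth), counts)
        return table

    high = recount(config.pileup_high)
    low = recount(config.pileup_low)
    checked = 0
    for rec in result.bfr_records:
        key = (rec.unigene_id, rec.pos)
        for table, f_obs in ((high, rec.f_high), (low, rec.f_low)):
            if key in table:
                depth, counts = table[key]
                assert f_obs == pytest.approx(counts[rec.informative_base] / depth)
            else:
                assert math.isnan(f_obs)
        if not rec.excluded:
            dh, ch = high[key]
            dl, cl = low[key]
            fh, fl = ch[rec.informative_base] / dh, cl[rec.informative_base] / dl
            expected = fl / fh if rec.origin == "A" else fh / fl
            assert rec.bfr == pytest.approx(expected)
            checked += 1
    assert checked > 20
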