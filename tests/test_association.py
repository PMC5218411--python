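import numpy as np
import pytest
from scipy import stats

from isoarch.association import (
    LocalZProfile,
    classify_profile,
    local_z_profile,
    overlap_statistic,
    perm_test,
    randomize_regions,
)
from isoarch.regions import RegionSet

from conftest import random_region_set


def brute_force_overlap(a, b, mode):
    """Quadratic-scan oracle for the overlap statistic (bp via 1-bp mask)."""
    if mode == "count":
        total = 0
        for chrom, iv in a.intervals.items():
            bm = b.intervals.get(chrom, np.empty((0, 2), int))
            for s, e in iv:
                if any(bs < e and be > s for bs, be in bm):
                    total += 1
        return float(total)
    total = 0
    for chrom, L in a.genome.items():
        ma = np.zeros(L, dtype=bool)
        mb = np.zeros(L, dtype=bool)
        for s, e in a.intervals.get(chrom, []):
            ma[s:e] = True
        for s, e in b.intervals.get(chrom, []):
            mb[s:e] = True
        total += int(np.sum(ma & mb))
    return float(total)


class TestOverlapStatistic:
    def test_single_overlap_both_modes(self, toy_genome):
        a = RegionSet("a", toy_genome, {"chr1": np.array([[0, 100]])})
        b = RegionSet("b", toy_genome, {"chr1": np.array([[50, 150]])})
        assert overlap_statistic(a, b, "count") == 1
        assert overlap_statistic(a, b, "basepair") == 50

    def test_disjoint_sets_zero(self, toy_genome):
        a = RegionSet("a", toy_genome, {"chr1": np.array([[0, 100]])})
        b = RegionSet("b", toy_genome, {"chr1": np.array([[200, 300]])})
        assert overlap_statistic(a, b, "count") == 0
        assert overlap_statistic(a, b, "basepair") == 0

    def test_identity_saturates(self, toy_genome):
        iv = {"chr1": np.array([[0, 100], [300, 450]])}
        a = RegionSet("a", toy_genome, iv)
        assert overlap_statistic(a, a, "count") == 2
        assert overlap_statistic(a, a, "basepair") == 250

    def test_mismatched_genomes_rejected(self, toy_genome):
        a = RegionSet("a", toy_genome, {"chr1": np.array([[0, 100]])})
        b = RegionSet("b", {"chr1": 5000}, {"chr1": np.array([[0, 100]])})
        with pytest.raises(ValueError):
            overlap_statistic(a, b)

    @pytest.mark.parametrize("mode", ["count", "basepair"])
    def test_matches_quadratic_oracle_on_fuzzed_sets(self, toy_genome, mode):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = random_region_set(toy_genome, rng.integers(1, 12), rng)
            b = random_region_set(toy_genome, rng.integers(1, 12), rng)
            assert overlap_statistic(a, b, mode) == brute_force_overlap(a, b, mode)


class TestRandomization:
    def test_uniform_length_multiset_preserved(self, toy_genome):
        rng = np.random.default_rng(0)
        rs = random_region_set(toy_genome, 10, rng)
        rand = randomize_regions(rs, "uniform", seed=1)
        for chrom in rs.intervals:
            assert sorted(rand.lengths(chrom)) == sorted(rs.lengths(chrom))

    def test_circular_preserves_bp_and_splits_at_most_one(self, toy_genome):
        # wrap splits an end-crossing interval in two; bp content is exact
        rng = np.random.default_rng(0)
        rs = random_region_set(toy_genome, 10, rng)
        rand = randomize_regions(rs, "circular", seed=1)
        for chrom in rs.intervals:
            assert rand.lengths(chrom).sum() == rs.lengths(chrom).sum()
            assert len(rs.lengths(chrom)) <= len(rand.lengths(chrom)) <= len(
                rs.lengths(chrom)
            ) + 1

    def test_uniform_output_non_overlapping(self, toy_genome):
        rng = np.random.default_rng(0)
        rs = random_region_set(toy_genome, 10, rng)
        rand = randomize_regions(rs, "uniform", seed=2)
        for chrom, iv in rand.intervals.items():
            assert all(iv[i, 1] <= iv[i + 1, 0] for i in range(len(iv) - 1))

    def test_circular_zero_offset_is_identity(self, toy_genome):
        class ZeroRng(np.random.Generator):
            pass

        rng = np.random.default_rng(0)
        rs = random_region_set(toy_genome, 5, rng)

        class Degenerate:
            def integers(self, lo, hi=None):
                return 0

        out = randomize_regions(rs, "circular", rng=Degenerate())
        for chrom in rs.intervals:
            np.testing.assert_array_equal(
                out.intervals[chrom], rs.intervals[chrom]
            )

    def test_mask_forces_unique_feasible_slot(self):
        genome = {"chr1": 1000}
        rs = RegionSet(
            "a",
            genome,
            {"chr1": np.array([[0, 100]])},
            mask={"chr1": np.array([[0, 450], [550, 1000]])},
        )
        out = randomize_regions(rs, "uniform", seed=3)
        np.testing.assert_array_equal(out.intervals["chr1"], [[450, 550]])

    def test_infeasible_placement_raises_with_chromosome(self):
        genome = {"chr1": 1000}
        rs = RegionSet(
            "a",
            genome,
            {"chr1": np.array([[0, 100]])},
            mask={"chr1": np.array([[0, 1000]])},
        )
        with pytest.raises(RuntimeError, match="chr1"):
            randomize_regions(rs, "uniform", seed=3)


class TestPermTest:
    def test_identical_sets_reach_minimum_p(self):
        # B covers <5% of the genome and A = B: observed saturates
        genome = {"chr1": 10_000_000}
        starts = np.arange(20) * 450_000
        iv = {"chr1": np.stack([starts, starts + 20_000], axis=1)}
        a = RegionSet("a", genome, iv)
        res = perm_test(a, a, n_perm=999, mode="basepair", seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.z_score > 5

    def test_whole_genome_b_saturates_to_p_one(self, toy_genome):
        rng = np.random.default_rng(1)
        a = random_region_set(toy_genome, 5, rng)
        b = RegionSet(
            "b",
            toy_genome,
            {c: np.array([[0, L]]) for c, L in toy_genome.items()},
        )
        res = perm_test(a, b, n_perm=99, mode="count", seed=0)
        assert res.p_value == 1.0
        assert np.isnan(res.z_score)  # degenerate null flagged

    def test_seeded_reproducibility(self, toy_genome):
        rng = np.random.default_rng(2)
        a = random_region_set(toy_genome, 8, rng)
        b = random_region_set(toy_genome, 8, rng)
        r1 = perm_test(a, b, n_perm=50, mode="basepair", seed=7)
        r2 = perm_test(a, b, n_perm=50, mode="basepair", seed=7)
        np.testing.assert_array_equal(r1.null_values, r2.null_values)
        assert r1.p_value == r2.p_value

    def test_p_value_definition(self, toy_genome):
        rng = np.random.default_rng(3)
        a = random_region_set(toy_genome, 8, rng)
        b = random_region_set(toy_genome, 8, rng)
        res = perm_test(a, b, n_perm=99, mode="basepair", seed=5)
        expected = (1 + np.sum(res.null_values >= res.observed)) / 100
        assert res.p_value == pytest.approx(expected)

    def test_null_z_approximately_standard_normal(self):
        """KS distance of standardized null values from N(0,1) below 0.1."""
        genome = {"chr1": 2_000_000}
        rng = np.random.default_rng(4)
        starts = np.sort(
            rng.choice(np.arange(0, 1_900_000, 20_000), 40, replace=False)
        )
        a = RegionSet(
            "a", genome, {"chr1": np.stack([starts, starts + 15_000], axis=1)}
        )
        b = randomize_regions(a, "uniform", seed=9)
        res = perm_test(a, b, n_perm=1000, mode="basepair", seed=10)
        z = (res.null_values - res.null_mean) / res.null_sd
        d, _ = stats.kstest(z, "norm")
        assert d < 0.1


class TestLocalZ:
    def test_zero_shift_matches_perm_test(self, toy_genome):
        rng = np.random.default_rng(5)
        a = random_region_set(toy_genome, 8, rng)
        b = random_region_set(toy_genome, 8, rng)
        res = perm_test(a, b, n_perm=100, mode="basepair", seed=3)
        prof = local_z_profile(
            a, b, max_shift=1000, step=500, n_perm=100, mode="basepair", seed=3
        )
        assert 0 in prof.shifts
        assert prof.z_at_zero == pytest.approx(res.z_score)
        assert np.array_equal(prof.shifts, -prof.shifts[::-1])

    def test_step_must_divide_max_shift(self, toy_genome):
        rng = np.random.default_rng(6)
        a = random_region_set(toy_genome, 4, rng)
        with pytest.raises(ValueError):
            local_z_profile(a, a, max_shift=1000, step=300, n_perm=10, seed=0)

    def test_classify_constant_profile_flat(self):
        prof = LocalZProfile(
            shifts=np.array([-2, -1, 0, 1, 2]),
            z_values=np.array([5.0, 5.0, 5.0, 5.0, 5.0]),
            n_perm=10,
            seed=0,
        )
        assert classify_profile(prof) == "flat"

    def test_classify_peaked_profile_sharp(self):
        prof = LocalZProfile(
            shifts=np.array([-2, -1, 0, 1, 2]),
            z_values=np.array([5.0, 4.0, 30.0, 3.0, 5.0]),
            n_perm=10,
            seed=0,
        )
        assert prof.peak_sharpness == pytest.approx(6.0)
        assert classify_profile(prof) == "sharp"
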