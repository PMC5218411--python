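import numpy as np
import pandas as pd
import pytest

from isoarch.contacts import (
    BinAnnotation,
    ContactMatrix,
    annotate_bins,
    boundary_concordance,
    estimate_decay_exponent,
    interaction_class_fractions,
    lad_cf_by_family,
    make_bins,
    stratified_contact_profile,
    top_interactions,
)
from isoarch.isochores import Isochore
from isoarch.regions import RegionSet


def intra_matrix(values, chrom_len=1000, resolution=250):
    genome = {"chr1": chrom_len}
    bins = make_bins(genome, resolution)
    return ContactMatrix(resolution, bins, values, kind="intra")


def inter_matrix(values, n1=3, n2=4, resolution=250):
    genome = {"chr1": n1 * resolution, "chr2": n2 * resolution}
    bins = make_bins(genome, resolution)
    return ContactMatrix(resolution, bins, values, kind="inter")


class TestContactMatrix:
    def test_asymmetric_rejected(self):
        v = np.zeros((4, 4))
        v[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            intra_matrix(v)

    def test_negative_rejected(self):
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            intra_matrix(v)

    def test_bad_tiling_rejected(self):
        bins = pd.DataFrame(
            {
                "bin_id": [0, 1],
                "chrom": ["chr1", "chr1"],
                "start": [0, 300],
                "end": [250, 550],
            }
        )
        with pytest.raises(ValueError, match="tile"):
            ContactMatrix(250, bins, np.zeros((2, 2)))

    def test_triplet_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        v = rng.poisson(3, (4, 4)).astype(float)
        v = v + v.T
        m = intra_matrix(v)
        m.to_files(tmp_path / "bins.tsv", tmp_path / "trip.tsv")
        back = ContactMatrix.from_files(
            tmp_path / "bins.tsv", tmp_path / "trip.tsv", 250, "intra"
        )
        np.testing.assert_array_equal(m.values, back.values)


class TestAnnotateBins:
    ISOS = [
        Isochore("chr1", 0, 600, 35.0, "L1"),
        Isochore("chr1", 600, 1000, 50.0, "H2"),
    ]

    def test_majority_rule(self):
        m = intra_matrix(np.zeros((4, 4)))
        ann = annotate_bins(m, self.ISOS)
        # bin [500,750): 100 bp L1 vs 150 bp H2 -> H2
        assert list(ann.family) == ["L1", "L1", "H2", "H2"]
        assert list(ann.klass) == ["GC-poor", "GC-poor", "GC-rich", "GC-rich"]

    def test_tie_broken_by_midpoint(self):
        isos = [
            Isochore("chr1", 0, 125, 35.0, "L1"),
            Isochore("chr1", 125, 1000, 50.0, "H2"),
        ]
        m = intra_matrix(np.zeros((4, 4)))
        ann = annotate_bins(m, isos)
        # bin [0,250): 125/125 tie; midpoint 125 lies in H2
        assert ann.family[0] == "H2"

    def test_uncovered_bin_unassigned(self):
        isos = [Isochore("chr1", 0, 100, 35.0, "L1")]
        m = intra_matrix(np.zeros((4, 4)))
        ann = annotate_bins(m, isos)
        assert ann.family[0] is None and ann.klass[0] is None


class TestStratifiedProfile:
    def test_constant_matrix_every_cell_constant(self):
        v = np.full((4, 4), 7.0)
        m = intra_matrix(v)
        ann = annotate_bins(m, TestAnnotateBins.ISOS)
        tab = stratified_contact_profile(m, ann, [500])
        assert (tab["mean_value"] == 7.0).all()

    def test_class_pair_order_symmetric(self):
        rng = np.random.default_rng(1)
        v = rng.poisson(5, (4, 4)).astype(float)
        v = v + v.T
        m = intra_matrix(v)
        ann = annotate_bins(m, TestAnnotateBins.ISOS)
        tab = stratified_contact_profile(m, ann, [500])
        # classes stored canonically sorted: no (rich, poor) duplicate rows
        keys = set(zip(tab["class_i"], tab["class_j"]))
        assert ("GC-rich", "GC-poor") not in keys

    def test_every_annotated_pair_counted_once(self):
        v = np.zeros((4, 4))
        m = intra_matrix(v)
        ann = annotate_bins(m, TestAnnotateBins.ISOS)
        tab = stratified_contact_profile(m, ann, [10_000])
        assert tab["n_pairs"].sum() == 6  # C(4,2)

    def test_intra_required(self):
        m = inter_matrix(np.zeros((7, 7)))
        ann = BinAnnotation(family=np.array(["L1"] * 7, dtype=object))
        with pytest.raises(ValueError):
            stratified_contact_profile(m, ann, [500])


class TestTopInteractions:
    def test_two_largest_in_order(self):
        v = np.zeros((7, 7))
        v[0, 3], v[3, 0] = 9.0, 9.0
        v[1, 4], v[4, 1] = 5.0, 5.0
        v[2, 5], v[5, 2] = 7.0, 7.0
        m = inter_matrix(v)
        top = top_interactions(m, 2)
        assert list(top["value"]) == [9.0, 7.0]

    def test_ties_broken_lexicographically(self):
        v = np.zeros((7, 7))
        for i in range(3):
            for j in range(3, 7):
                v[i, j] = v[j, i] = 2.0
        m = inter_matrix(v)
        top = top_interactions(m, 2)
        assert list(zip(top["bin_i"], top["bin_j"])) == [(0, 3), (0, 4)]

    def test_saturation_returns_all_nonzero_with_warning(self):
        v = np.zeros((7, 7))
        v[0, 3] = v[3, 0] = 1.0
        m = inter_matrix(v)
        with pytest.warns(UserWarning):
            top = top_interactions(m, 5)
        assert len(top) == 1

    def test_intra_matrix_rejected(self):
        m = intra_matrix(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            top_interactions(m, 1)

    def test_stable_under_input_permutation(self, tmp_path):
        rng = np.random.default_rng(2)
        v = np.zeros((7, 7))
        iu, ju = np.triu_indices(7, 1)
        vals = rng.poisson(4, len(iu)).astype(float)
        v[iu, ju] = vals
        v[ju, iu] = vals
        # zero out intra blocks to make it a clean inter matrix
        v[:3, :3] = 0
        v[3:, 3:] = 0
        m = inter_matrix(v)
        m.to_files(tmp_path / "b.tsv", tmp_path / "t.tsv")
        trip = pd.read_csv(tmp_path / "t.tsv", sep="\t", header=None)
        trip.sample(frac=1, random_state=3).to_csv(
            tmp_path / "t2.tsv", sep="\t", header=False, index=False
        )
        m2 = ContactMatrix.from_files(tmp_path / "b.tsv", tmp_path / "t2.tsv", 250, "inter")
        pd.testing.assert_frame_equal(top_interactions(m, 5), top_interactions(m2, 5))


class TestClassFractions:
    def test_all_rich_bins(self):
        ann = BinAnnotation(family=np.array(["H1"] * 7, dtype=object))
        top = pd.DataFrame({"bin_i": [0, 1], "bin_j": [3, 4], "value": [2.0, 1.0]})
        out = interaction_class_fractions([top], ann)
        assert out["fraction_gc_rich"] == 1.0
        assert out["fraction_gc_poor"] == 0.0

    def test_fractions_sum_to_one_and_distinct_counting(self):
        fam = np.array(["H1", "L1", "H2", "L2", "H3", "L1", "H1"], dtype=object)
        ann = BinAnnotation(family=fam)
        top = pd.DataFrame(
            {"bin_i": [0, 0, 1], "bin_j": [3, 3, 4], "value": [3.0, 2.0, 1.0]}
        )
        out = interaction_class_fractions([top], ann)
        # distinct bins: {0,1,3,4} -> rich {0,4}, poor {1,3}
        assert out["n_bins"] == 4
        assert out["fraction_gc_rich"] + out["fraction_gc_poor"] == 1.0
        assert out["fraction_gc_rich"] == 0.5


class TestBoundaryConcordance:
    def test_identical_boundaries_full_match(self, toy_genome):
        isos = [
            Isochore("chr1", 0, 5000, 35.0, "L1"),
            Isochore("chr1", 5000, 10_000, 50.0, "H2"),
        ]
        doms = RegionSet(
            "d", toy_genome, {"chr1": np.array([[0, 5000], [5000, 10_000]])}
        )
        out = boundary_concordance(doms, isos, tolerance=0)
        assert out["fraction_matched"] == 1.0

    def test_no_isochores_on_chromosome(self, toy_genome):
        isos = [Isochore("chr2", 0, 8000, 35.0, "L1")]
        doms = RegionSet("d", toy_genome, {"chr1": np.array([[100, 900]])})
        out = boundary_concordance(doms, isos, tolerance=50)
        assert out["fraction_matched"] == 0.0

    def test_tolerance_window(self, toy_genome):
        isos = [Isochore("chr1", 0, 5000, 35.0, "L1")]
        doms = RegionSet("d", toy_genome, {"chr1": np.array([[80, 5100]])})
        assert boundary_concordance(doms, isos, 100)["fraction_matched"] == 1.0
        assert boundary_concordance(doms, isos, 50)["fraction_matched"] == 0.0


class TestLadCf:
    def test_all_high_cf_in_l1(self, toy_genome):
        isos = [
            Isochore("chr1", 0, 5000, 35.0, "L1"),
            Isochore("chr1", 5000, 10_000, 50.0, "H2"),
        ]
        lads = RegionSet(
            "lads",
            toy_genome,
            {"chr1": np.array([[0, 2000], [2500, 4500]])},
            scores={"chr1": np.array([1.0, 1.0])},
        )
        tab = lad_cf_by_family(lads, isos).set_index("family")
        assert tab.loc["L1", "n_lads"] == 2
        assert tab.loc["L1", "mean_cf"] == 1.0
        assert tab.loc["L1", "fraction_high_cf"] == 1.0
        assert "H2" not in tab.index

    def test_no_lads_empty_table(self, toy_genome):
        isos = [Isochore("chr1", 0, 5000, 35.0, "L1")]
        lads = RegionSet("lads", toy_genome, {})
        assert lad_cf_by_family(lads, isos).empty


def test_decay_exponent_on_exact_power_law():
    n = 60
    genome = {"chr1": n * 250}
    bins = make_bins(genome, 250)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d = np.abs(ii - jj).astype(float)
    with np.errstate(divide="ignore"):
        v = np.where(d > 0, 1000.0 * d**-1.2, 1000.0)
    m = ContactMatrix(250, bins, v, kind="intra")
    est = estimate_decay_exponent(m, max_distance_bins=30)
    assert est == pytest.approx(1.2, abs=0.01)
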