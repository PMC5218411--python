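import numpy as np
import pytest

from isoarch.config import FAMILIES, SimulationConfig
from isoarch.contacts import annotate_bins, top_interactions
from isoarch.isochores import GC_POOR, compute_gc_profile
from isoarch.simulate import (
    concordant_tads,
    simulate_contact_matrix,
    simulate_ctcf_sites,
    simulate_domains,
    simulate_isochore_genome,
    simulate_isochore_structure,
    simulate_orthologs,
)


class TestStructure:
    def test_same_seed_identical_output(self, small_config):
        g1, t1 = simulate_isochore_genome(small_config)
        g2, t2 = simulate_isochore_genome(small_config)
        assert g1 == g2  # byte-identical sequences
        assert [
            (i.chrom, i.start, i.end, i.family) for i in t1.isochores
        ] == [(i.chrom, i.start, i.end, i.family) for i in t2.isochores]

    def test_isochores_tile_each_chromosome(self, small_truth):
        for chrom, L in small_truth.genome.items():
            isos = small_truth.isochores_on(chrom)
            assert isos[0].start == 0 and isos[-1].end == L
            for a, b in zip(isos, isos[1:]):
                assert a.end == b.start
                assert a.family != b.family

    def test_chromosome_shorter_than_min_isochore_rejected(self):
        with pytest.raises(ValueError, match="minimal isochore"):
            SimulationConfig(chromosome_length=100_000)

    def test_family_composition_follows_stationary_distribution(self):
        """Aggregate family counts over seeds match the succession chain's
        stationary distribution within multinomial error."""
        counts = np.zeros(5)
        cfg0 = SimulationConfig(seed=0)
        for seed in range(50):
            cfg = SimulationConfig(seed=seed, n_chromosomes=1)
            truth = simulate_isochore_structure(cfg)
            for iso in truth.isochores:
                counts[FAMILIES.index(iso.family)] += 1
        pi = cfg0.stationary_families()
        n = counts.sum()
        from scipy.stats import chisquare

        _, p = chisquare(counts, pi * n)
        assert p > 0.001

    def test_single_family_sequence_matches_target_gc(self):
        cfg = SimulationConfig(
            seed=3,
            n_chromosomes=1,
            chromosome_length=2_000_000,
            window_noise_sd=0.0,
            family_gc_targets={
                "L1": 10.0, "L2": 20.0, "H1": 30.0, "H2": 40.0, "H3": 55.0
            },
            family_transition=np.eye(5)[:, [1, 2, 3, 4, 0]],  # unused: one iso
            family_length_params={
                f: (np.log(5_000_000), 0.01) for f in FAMILIES
            },
        )
        genome, truth = simulate_isochore_genome(cfg)
        assert len(truth.isochores) == 1
        target = truth.isochores[0].mean_gc
        prof = compute_gc_profile(genome["chr1"], 100_000, chrom="chr1")
        # every window within binomial sampling error of the target
        se = 100 * np.sqrt((target / 100) * (1 - target / 100) / 100_000)
        assert np.all(np.abs(prof.values - target) < 6 * se)

    def test_per_family_gc_within_one_percent(self, small_config):
        genome, truth = simulate_isochore_genome(small_config)
        for iso in truth.isochores:
            if iso.length < 500_000:
                continue
            seq = genome[iso.chrom][iso.start : iso.end]
            gc = 100 * (seq.count("G") + seq.count("C")) / len(seq)
            assert abs(gc - iso.mean_gc) < 1.0


class TestDomains:
    def test_zero_jitter_tads_equal_isochores(self, small_truth, small_config):
        cfg = SimulationConfig(
            seed=small_config.seed,
            n_chromosomes=small_config.n_chromosomes,
            chromosome_length=small_config.chromosome_length,
            tad_jitter_sd=0.0,
            discordant_tad_fraction=0.0,
        )
        truth = simulate_isochore_structure(cfg)
        tads, _ = simulate_domains(truth, cfg)
        for chrom in truth.genome:
            expected = np.array(
                [(i.start, i.end) for i in truth.isochores_on(chrom)]
            )
            np.testing.assert_array_equal(tads.intervals[chrom], expected)
        assert all(src != "discordant" for src in truth.true_tad_map)

    def test_full_discordance_labels_every_tad(self, small_config):
        cfg = SimulationConfig(
            seed=1,
            n_chromosomes=1,
            chromosome_length=10_000_000,
            discordant_tad_fraction=1.0,
        )
        truth = simulate_isochore_structure(cfg)
        simulate_domains(truth, cfg)
        assert all(src == "discordant" for src in truth.true_tad_map)

    def test_lads_are_gc_poor_isochores_with_cf(self, small_config):
        truth = simulate_isochore_structure(small_config)
        _, lads = simulate_domains(truth, small_config)
        n_poor = sum(1 for i in truth.isochores if i.family in GC_POOR)
        assert lads.n_intervals() == n_poor
        for chrom, sc in lads.scores.items():
            assert np.all((sc >= 0) & (sc <= 1))

    def test_l1_cf_stochastically_dominates_l2(self):
        """Mean CF over L1 LADs exceeds L2 in nearly all seeds under the
        default Beta parameters."""
        from isoarch.contacts import lad_cf_by_family

        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed)
            truth = simulate_isochore_structure(cfg)
            _, lads = simulate_domains(truth, cfg)
            tab = lad_cf_by_family(lads, truth.isochores).set_index("family")
            if "L1" in tab.index and "L2" in tab.index:
                wins += tab.loc["L1", "mean_cf"] > tab.loc["L2", "mean_cf"]
            else:
                wins += 1
        assert wins >= 0.95 * n_seeds

    def test_concordant_tads_subset(self, small_config):
        truth = simulate_isochore_structure(small_config)
        tads, _ = simulate_domains(truth, small_config)
        poor = concordant_tads(truth, GC_POOR)
        assert poor.n_intervals() <= tads.n_intervals()
        assert poor.n_intervals() == sum(
            1
            for src in truth.true_tad_map
            if src != "discordant" and truth.isochores[src].family in GC_POOR
        )


class TestContactsSim:
    def test_matrix_symmetric_and_seeded(self, small_truth, small_config):
        m1 = simulate_contact_matrix(small_truth, small_config, "intra")
        m2 = simulate_contact_matrix(small_truth, small_config, "intra")
        np.testing.assert_array_equal(m1.values, m2.values)
        np.testing.assert_array_equal(m1.values, m1.values.T)

    def test_inter_needs_two_chromosomes(self):
        cfg = SimulationConfig(seed=0, n_chromosomes=1)
        truth = simulate_isochore_structure(cfg)
        with pytest.raises(ValueError):
            simulate_contact_matrix(truth, cfg, "inter")

    def test_distance_decay_halves_at_double_distance(self):
        """decay_exponent=1, boosts off: mean contact at 2 bins is half the
        mean at 1 bin, within Poisson error over >=1000 pairs."""
        cfg = SimulationConfig(
            seed=2,
            n_chromosomes=1,
            chromosome_length=20_000_000,
            contact_resolution=50_000,  # 400 bins -> ~400 pairs per offset
            decay_exponent=1.0,
            domain_boost=1.0,
            gcpoor_longrange_boost=1.0,
            contact_base=50.0,
        )
        truth = simulate_isochore_structure(cfg)
        m = simulate_contact_matrix(truth, cfg, "intra")
        d1 = np.diagonal(m.values, 1)
        d2 = np.diagonal(m.values, 2)
        ratio = d1.mean() / d2.mean()
        se = ratio * np.sqrt(1 / d1.sum() + 1 / d2.sum())
        assert abs(ratio - 2.0) < 4 * se

    def test_gcpoor_boost_ratio_recovered(self):
        from isoarch.contacts import longrange_class_ratio

        cfg = SimulationConfig(seed=4, n_chromosomes=1)
        truth = simulate_isochore_structure(cfg)
        m = simulate_contact_matrix(truth, cfg, "intra")
        ann = annotate_bins(m, truth.isochores)
        out = longrange_class_ratio(m, ann)
        assert out["ratio"] == pytest.approx(
            cfg.gcpoor_longrange_boost, abs=max(4 * out["se"], 0.4)
        )

    def test_top_interactions_hit_planted_hub_fraction(self, small_config):
        truth = simulate_isochore_structure(small_config)
        m = simulate_contact_matrix(truth, small_config, "inter")
        ann = annotate_bins(m, truth.isochores)
        top = top_interactions(m, 100)
        from isoarch.contacts import interaction_class_fractions

        out = interaction_class_fractions([top], ann)
        assert out["fraction_gc_rich"] == pytest.approx(0.75, abs=0.07)


class TestOrthologs:
    def test_identity_layout_is_collinear(self, small_truth, small_config):
        pairs, gc, _ = simulate_orthologs(
            small_truth, small_config, shuffle_blocks=False
        )
        for _, sub in pairs.groupby("chrom_a"):
            assert sub["start_b"].is_monotonic_increasing
            assert (sub["strand_b"] == "+").all()

    def test_zero_noise_gc_equal(self, small_truth, small_config):
        _, gc, _ = simulate_orthologs(small_truth, small_config, gc_noise_sd=0.0)
        np.testing.assert_array_equal(gc["gc_a"], gc["gc_b"])

    def test_blocks_recorded_and_detectable(self, small_config):
        from isoarch.synteny import build_synteny_blocks

        truth = simulate_isochore_structure(small_config)
        pairs, _, truth_b = simulate_orthologs(truth, small_config)
        blocks = build_synteny_blocks(pairs, min_genes=3)
        planted = {b["genes"]: b["orientation"] for b in truth_b.blocks}
        assert len(blocks) == len(planted)
        for b in blocks:
            assert planted[b.genes_a] == b.orientation

    def test_too_small_blocks_rejected(self):
        with pytest.raises(ValueError, match="genes_per_block"):
            SimulationConfig(genes_per_block=2)


class TestCtcf:
    def test_zero_density_no_sites(self, small_truth):
        sites = simulate_ctcf_sites(
            small_truth, densities={f: 0.0 for f in FAMILIES}, seed=0
        )
        assert all(len(v) == 0 for v in sites.values())

    def test_poisson_count_in_single_isochore(self):
        cfg = SimulationConfig(
            seed=0,
            n_chromosomes=1,
            chromosome_length=1_000_000,
            family_length_params={
                f: (np.log(5_000_000), 0.01) for f in FAMILIES
            },
        )
        counts = []
        for seed in range(200):
            truth = simulate_isochore_structure(
                SimulationConfig(
                    seed=seed,
                    n_chromosomes=1,
                    chromosome_length=1_000_000,
                    family_length_params=cfg.family_length_params,
                )
            )
            fam = truth.isochores[0].family
            sites = simulate_ctcf_sites(truth, densities={fam: 10.0}, seed=seed)
            counts.append(len(sites["chr1"]))
        counts = np.asarray(counts)
        # Poisson(10): mean 10, var 10
        assert counts.mean() == pytest.approx(10.0, abs=0.7)
        assert counts.var() == pytest.approx(10.0, rel=0.35)

    def test_negative_density_rejected(self, small_truth):
        with pytest.raises(ValueError):
            simulate_ctcf_sites(small_truth, densities={"L1": -1.0}, seed=0)
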