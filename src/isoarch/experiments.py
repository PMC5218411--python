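"""Planted-parameter recovery studies.

Each function runs one closed-loop experiment: simulate data with a known
planted structure, run the corresponding analysis stage, and measure how
well the planted value is recovered.  All randomness derives from a single
base seed through named streams, so every study is reproducible and the
studies are mutually independent.

Problem sizes (20 Mb chromosomes, hundreds of permutations, tens to a
hundred replicate seeds) are chosen so each study carries enough Monte
Carlo resolution for its tolerance while remaining desk-scale.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    classify_profile,
    local_z_profile,
    perm_test,
    randomize_regions,
)
from .config import SimulationConfig, stream_key
from .contacts import (
    aggregate_class_fractions,
    annotate_bins,
    boundary_concordance,
    estimate_decay_exponent,
    longrange_class_ratio,
    top_interactions,
)
from .isochores import (
    FAMILIES,
    FamilyBoundaries,
    GC_POOR,
    compute_gc_profile,
    ctcf_density_by_family,
    segment_isochores,
)
from .pipeline import evaluate_segmentation
from .regions import RegionSet
from .simulate import (
    calibrate_ortholog_noise,
    concordant_tads,
    regional_control_regions,
    simulate_contact_matrix,
    simulate_ctcf_sites,
    simulate_domains,
    simulate_isochore_genome,
    simulate_isochore_structure,
    simulate_orthologs,
)
from .synteny import build_synteny_blocks, gc_correlation


def _rep_seeds(base_seed: int, study: str, n: int) -> List[int]:
    ss = np.random.SeedSequence(
        entropy=base_seed, spawn_key=(stream_key(study),)
    )
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ----------------------------------------------------------------------
# 1. isochore recovery


def segmentation_recovery(
    seed: int = 0, n_seeds: int = 10, window: int = 100_000,
    min_size: int = 200_000,
) -> dict:
    """Segment 20 Mb five-family genomes and score recovery vs truth."""
    recalls, accs = [], []
    for s in _rep_seeds(seed, "segmentation", n_seeds):
        cfg = SimulationConfig(seed=s, n_chromosomes=1,
                               chromosome_length=20_000_000)
        genome, truth = simulate_isochore_genome(cfg)
        called = []
        for chrom, seq in genome.items():
            prof = compute_gc_profile(seq, window, chrom=chrom)
            called.extend(
                segment_isochores(prof, FamilyBoundaries(), min_size=min_size)
            )
        r = evaluate_segmentation(truth, called, window)
        recalls.append(r.boundary_recall)
        accs.append(r.bp_accuracy)
    return {
        "boundary_recall_mean": float(np.mean(recalls)),
        "boundary_recall_min": float(np.min(recalls)),
        "bp_accuracy_mean": float(np.mean(accs)),
        "bp_accuracy_min": float(np.min(accs)),
        "n_seeds": n_seeds,
    }


# ----------------------------------------------------------------------
# 2. concordant association


def tad_association(
    seed: int = 0, n_seeds: int = 10, n_perm: int = 999
) -> dict:
    """Jittered GC-poor TADs vs GC-poor isochores: p and z per seed."""
    ps, zs = [], []
    for s in _rep_seeds(seed, "tad-association", n_seeds):
        cfg = SimulationConfig(seed=s, tad_jitter_sd=50_000.0,
                               discordant_tad_fraction=0.0)
        truth = simulate_isochore_structure(cfg)
        simulate_domains(truth, cfg)
        b = truth.as_region_set(families=GC_POOR)
        a = concordant_tads(truth, GC_POOR)
        res = perm_test(a, b, n_perm=n_perm, mode="basepair",
                        scheme="uniform", seed=s)
        ps.append(res.p_value)
        zs.append(res.z_score)
    return {
        "p_max": float(np.max(ps)),
        "p_min_attainable": 1.0 / (n_perm + 1),
        "z_min": float(np.min(zs)),
        "all_at_min_p": bool(all(p == 1.0 / (n_perm + 1) for p in ps)),
        "n_seeds": n_seeds,
    }


# ----------------------------------------------------------------------
# 3. calibration under independence


def association_calibration(
    seed: int = 0, n_reps: int = 500, n_perm: int = 199, alpha: float = 0.05
) -> dict:
    """Type-I error of the permutation test on independent region sets."""
    genome = {"chr1": 20_000_000}
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream_key("calib"),))
    )
    starts = np.arange(25) * 750_000
    lengths = rng.integers(100_000, 600_000, 25)
    template = RegionSet(
        "template", genome, {"chr1": np.stack([starts, starts + lengths], 1)}
    )
    rejections = 0
    for _ in range(n_reps):
        a = randomize_regions(template, "uniform", rng=rng)
        b = randomize_regions(template, "uniform", rng=rng)
        res = perm_test(a, b, n_perm=n_perm, mode="basepair",
                        scheme="uniform", seed=int(rng.integers(2**31)))
        rejections += res.p_value <= alpha
    return {
        "rejection_rate": rejections / n_reps,
        "alpha": alpha,
        "n_reps": n_reps,
        "n_perm": n_perm,
    }


# ----------------------------------------------------------------------
# 4. local z mechanism


def localz_classification(
    seed: int = 0, n_seeds: int = 100, n_perm: int = 100
) -> dict:
    """Sharp/flat discrimination of boundary-concordant vs regional sets.

    The shift range scales with the tested set: max_shift = 5x the mean
    interval length, so the half-range probes well past the boundary
    scale of a concordant set while staying inside the territory scale of
    a regional one.
    """
    correct_sharp = correct_flat = 0
    drop_ok = 0
    for s in _rep_seeds(seed, "localz", n_seeds):
        cfg = SimulationConfig(seed=s, tad_jitter_sd=50_000.0,
                               discordant_tad_fraction=0.0)
        truth = simulate_isochore_structure(cfg)
        simulate_domains(truth, cfg)
        b = truth.as_region_set(families=GC_POOR)
        a = concordant_tads(truth, GC_POOR)
        step = int(round(a.mean_length()))
        prof = local_z_profile(a, b, max_shift=5 * step, step=step,
                               n_perm=n_perm, mode="basepair", seed=s)
        correct_sharp += classify_profile(prof) == "sharp"
        far = np.abs(prof.shifts) >= 5 * step
        if prof.z_at_zero > 0 and np.all(
            prof.z_values[far] <= 0.5 * prof.z_at_zero
        ):
            drop_ok += 1

        a2 = regional_control_regions(b, n_per_chrom=40, length=50_000, seed=s)
        step2 = 50_000
        prof2 = local_z_profile(a2, b, max_shift=5 * step2, step=step2,
                                n_perm=n_perm, mode="basepair", seed=s)
        correct_flat += classify_profile(prof2) == "flat"
    return {
        "classification_accuracy": (correct_sharp + correct_flat)
        / (2 * n_seeds),
        "sharp_accuracy": correct_sharp / n_seeds,
        "flat_accuracy": correct_flat / n_seeds,
        "z_drop_fraction": drop_ok / n_seeds,
        "n_seeds": n_seeds,
    }


# ----------------------------------------------------------------------
# 5. synteny oracle + planted recovery


def _oracle_blocks(pairs: pd.DataFrame, min_genes: int = 3) -> list:
    """Brute-force longest-valid-prefix enumeration (reference method)."""

    def window_valid(sub: pd.DataFrame) -> bool:
        if sub["chrom_b"].nunique() != 1:
            return False
        b = list(sub["start_b"])
        if len(b) == 1:
            return True
        return all(x < y for x, y in zip(b, b[1:])) or all(
            x > y for x, y in zip(b, b[1:])
        )

    out = []
    df = pairs.sort_values(["chrom_a", "start_a"], kind="mergesort")
    for _, sub in df.groupby("chrom_a", sort=False):
        sub = sub.reset_index(drop=True)
        start = 0
        while start < len(sub):
            end = start
            while end + 1 < len(sub) and window_valid(
                sub.iloc[start : end + 2]
            ):
                end += 1
            if end - start + 1 >= min_genes:
                w = sub.iloc[start : end + 1]
                b = list(w["start_b"])
                out.append(
                    (
                        tuple(w["gene_a"]),
                        "inverted" if b[0] > b[-1] else "direct",
                    )
                )
            start = end + 1
    return out


def _fuzz_table(rng: np.random.Generator) -> pd.DataFrame:
    n = int(rng.integers(3, 13))
    chrom_b = rng.choice(["chrB", "chrC"], n, p=[0.8, 0.2])
    b_pos = rng.permutation(n) * 10
    if rng.random() < 0.5:
        k = int(rng.integers(2, n + 1))
        b_pos[:k] = np.sort(b_pos[:k])
    return pd.DataFrame(
        {
            "gene_a": [f"a{i}" for i in range(n)],
            "chrom_a": "chrA",
            "start_a": np.arange(n) * 1000,
            "end_a": np.arange(n) * 1000 + 100,
            "gene_b": [f"b{i}" for i in range(n)],
            "chrom_b": chrom_b,
            "start_b": b_pos,
            "end_b": b_pos + 5,
            "strand_b": "+",
        }
    )


def synteny_recovery(seed: int = 0, n_tables: int = 100) -> dict:
    """Oracle agreement on fuzzed tables + exact recovery of 50 planted
    blocks (count, membership, orientation) without GC noise."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream_key("fuzz"),))
    )
    agree = 0
    for _ in range(n_tables):
        t = _fuzz_table(rng)
        ours = [
            (b.genes_a, b.orientation)
            for b in build_synteny_blocks(t, min_genes=3)
        ]
        agree += ours == _oracle_blocks(t, 3)

    cfg = SimulationConfig(
        seed=_rep_seeds(seed, "synteny-planted", 1)[0],
        n_chromosomes=1,
        orthologs_per_chrom=250,
        genes_per_block=5,
    )
    truth = simulate_isochore_structure(cfg)
    pairs, _, truth_b = simulate_orthologs(truth, cfg, gc_noise_sd=0.0)
    blocks = build_synteny_blocks(pairs, min_genes=3)
    planted = {b["genes"]: b["orientation"] for b in truth_b.blocks}
    exact = len(blocks) == len(planted) == 50 and all(
        b.genes_a in planted and planted[b.genes_a] == b.orientation
        for b in blocks
    )
    return {
        "oracle_agreement": agree / n_tables,
        "n_tables": n_tables,
        "planted_blocks": len(planted),
        "recovered_blocks": len(blocks),
        "planted_recovered_exactly": bool(exact),
    }


# ----------------------------------------------------------------------
# 6. GC correlation recovery


def gc_correlation_recovery(
    seed: int = 0, n_seeds: int = 100, target_r: float = 0.9, n_genes: int = 300
) -> dict:
    """Plant a cross-species GC correlation and re-estimate it."""
    rs = []
    for s in _rep_seeds(seed, "gc-correlation", n_seeds):
        cfg = SimulationConfig(seed=s, n_chromosomes=1,
                               orthologs_per_chrom=n_genes)
        truth = simulate_isochore_structure(cfg)
        sd = calibrate_ortholog_noise(truth, cfg, target_r)
        _, gc_tab, _ = simulate_orthologs(truth, cfg, gc_noise_sd=sd)
        rs.append(gc_correlation(gc_tab["gc_a"], gc_tab["gc_b"])["pearson_r"])
    rs = np.asarray(rs)
    return {
        "target_r": target_r,
        "r_mean": float(rs.mean()),
        "fraction_within_0.05": float(np.mean(np.abs(rs - target_r) <= 0.05)),
        "n_seeds": n_seeds,
        "n_genes": n_genes,
    }


# ----------------------------------------------------------------------
# 7. inter-chromosomal class fractions


def interchrom_fraction_recovery(
    seed: int = 0, n_seeds: int = 20, n_chromosomes: int = 7, top_n: int = 100
) -> dict:
    """Recover the planted GC-rich involvement fraction from top
    interactions over all chromosome pairs (C(7,2)=21 pairs)."""
    fracs = []
    for s in _rep_seeds(seed, "interchrom", n_seeds):
        cfg = SimulationConfig(seed=s, n_chromosomes=n_chromosomes)
        truth = simulate_isochore_structure(cfg)
        items = []
        for ca, cb in combinations(list(truth.genome), 2):
            m = simulate_contact_matrix(truth, cfg, "inter", [ca, cb])
            ann = annotate_bins(m, truth.isochores)
            items.append((m, top_interactions(m, n=top_n), ann))
        fracs.append(aggregate_class_fractions(items)["fraction_gc_rich"])
    fracs = np.asarray(fracs)
    return {
        "planted_preference": 0.75,
        "fraction_mean": float(fracs.mean()),
        "max_abs_deviation": float(np.max(np.abs(fracs - 0.75))),
        "n_seeds": n_seeds,
        "n_chromosome_pairs": n_chromosomes * (n_chromosomes - 1) // 2,
    }


# ----------------------------------------------------------------------
# 8. stratified contacts


def contact_recovery(seed: int = 0) -> dict:
    """Recover the decay exponent (boosts off) and the 3x GC-poor
    long-range boost (planted) from simulated intra matrices."""
    s1, s2 = _rep_seeds(seed, "contacts", 2)
    cfg_plain = SimulationConfig(
        seed=s1, n_chromosomes=2, domain_boost=1.0, gcpoor_longrange_boost=1.0
    )
    truth = simulate_isochore_structure(cfg_plain)
    decays = []
    for chrom in truth.genome:
        m = simulate_contact_matrix(truth, cfg_plain, "intra", [chrom])
        decays.append(estimate_decay_exponent(m, max_distance_bins=40))
    cfg_boost = SimulationConfig(seed=s2, n_chromosomes=2,
                                 gcpoor_longrange_boost=3.0)
    truth_b = simulate_isochore_structure(cfg_boost)
    logs, ses = [], []
    for chrom in truth_b.genome:
        m = simulate_contact_matrix(truth_b, cfg_boost, "intra", [chrom])
        ann = annotate_bins(m, truth_b.isochores)
        out = longrange_class_ratio(m, ann)
        if np.isfinite(out["ratio"]):
            logs.append(np.log(out["ratio"]))
            ses.append(out["se"] / out["ratio"])
    w = 1.0 / np.asarray(ses) ** 2
    ratio = float(np.exp(np.sum(np.asarray(logs) * w) / np.sum(w)))
    ratio_se = ratio * float(1.0 / np.sqrt(np.sum(w)))
    return {
        "planted_decay_exponent": cfg_plain.decay_exponent,
        "decay_exponent_estimate": float(np.mean(decays)),
        "planted_boost": 3.0,
        "boost_ratio_estimate": ratio,
        "boost_ratio_se": ratio_se,
    }


# ----------------------------------------------------------------------
# 9. boundary concordance closed form


def concordance_recovery(
    seed: int = 0, n_seeds: int = 5, jitter_sd: float = 50_000.0,
    tolerance: int = 100_000,
) -> dict:
    """Matched-boundary fraction vs the Gaussian closed form
    P(|N(0, sd)| <= tol) = 2*Phi(tol/sd) - 1."""
    expected = float(2 * stats.norm.cdf(tolerance / jitter_sd) - 1)
    matched = total = 0
    for s in _rep_seeds(seed, "concordance", n_seeds):
        cfg = SimulationConfig(seed=s, n_chromosomes=3,
                               tad_jitter_sd=jitter_sd,
                               discordant_tad_fraction=0.0)
        truth = simulate_isochore_structure(cfg)
        tads, _ = simulate_domains(truth, cfg)
        out = boundary_concordance(tads, truth.isochores, tolerance=tolerance)
        matched += out["matched"]
        total += out["total"]
    frac = matched / total
    half_ci = 1.959964 * float(np.sqrt(expected * (1 - expected) / total))
    return {
        "fraction_matched": frac,
        "expected_gaussian": expected,
        "binomial_ci_halfwidth": half_ci,
        "within_ci": bool(abs(frac - expected) <= half_ci),
        "n_boundaries": total,
    }


# ----------------------------------------------------------------------
# 10. CTCF gradient


def ctcf_gradient_recovery(seed: int = 0, n_seeds: int = 100) -> dict:
    """Recover the strictly increasing L1<L2<H1<H2<H3 density ordering."""
    ok = 0
    for s in _rep_seeds(seed, "ctcf", n_seeds):
        cfg = SimulationConfig(seed=s, n_chromosomes=5)
        truth = simulate_isochore_structure(cfg)
        sites = simulate_ctcf_sites(truth, config=cfg)
        tab = ctcf_density_by_family(sites, truth.isochores).set_index("family")
        dens = [float(tab.loc[f, "density_per_mb"]) for f in FAMILIES]
        ok += all(a < b for a, b in zip(dens, dens[1:]))
    return {
        "ordering_recovery_rate": ok / n_seeds,
        "n_seeds": n_seeds,
        "planted_densities": dict(SimulationConfig().ctcf_densities),
    }
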