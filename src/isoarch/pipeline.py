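"""End-to-end orchestration: simulate → segment → associate → synteny →
contacts → report, under one global seed.

Stage seeds derive from the global seed and a CRC-32 stage-name hash, so
adding a stage never perturbs another stage's random stream.  The report
is a pydantic model whose JSON schema ships with the package
(``report.schema.json``); a report regenerates bit-identically from the
same configuration (no timestamps are written).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel

from ._version import __version__ as _pkg_version
from .association import classify_profile, local_z_profile, perm_test
from .config import PipelineConfig
from .contacts import (
    ContactMatrix,
    annotate_bins,
    boundary_concordance,
    estimate_decay_exponent,
    interaction_class_fractions,
    lad_cf_by_family,
    longrange_class_ratio,
    stratified_contact_profile,
    top_interactions,
)
from .isochores import (
    FamilyBoundaries,
    GC_POOR,
    Isochore,
    compute_gc_profile,
    ctcf_density_by_family,
    isochores_to_bed,
    isochores_to_dataframe,
    segment_isochores,
    write_fasta,
)
from .regions import RegionSet, write_genome_tsv
from .simulate import (
    GroundTruth,
    concordant_tads,
    simulate_contact_matrix,
    simulate_ctcf_sites,
    simulate_domains,
    simulate_isochore_genome,
    simulate_orthologs,
)
from .synteny import (
    block_stats,
    blocks_to_dataframe,
    build_synteny_blocks,
    gc_correlation,
    orthologous_isochores,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


# ----------------------------------------------------------------------
# report model


class AssociationSummary(BaseModel):
    observed: float
    null_mean: float
    null_sd: float
    z_score: Optional[float]
    p_value: float
    n_perm: int
    mode: str
    scheme: str


class LocalZSummary(BaseModel):
    z_at_zero: float
    peak_sharpness: float
    classification: str
    max_shift: int
    step: int


class SegmentationSummary(BaseModel):
    n_isochores: int
    boundary_recall: float
    bp_accuracy: float


class SyntenySummary(BaseModel):
    n_blocks: int
    mean_span: Optional[float]
    min_span: Optional[float]
    max_span: Optional[float]
    n_true_blocks: int
    pearson_r: Optional[float]
    spearman_rho: Optional[float]
    n_pairs: int


class ContactsSummary(BaseModel):
    decay_exponent_estimate: float
    longrange_poor_rich_ratio: float
    fraction_gc_rich: float
    fraction_gc_poor: float
    n_top_bins: int


class AnalysisReport(BaseModel):
    version: str
    seed: int
    config: dict
    outputs: Dict[str, str]
    segmentation: SegmentationSummary
    tad_association: AssociationSummary
    lad_association: AssociationSummary
    tad_localz: LocalZSummary
    synteny: SyntenySummary
    contacts: ContactsSummary
    concordance: dict
    lad_cf: List[dict]
    ctcf_density: List[dict]


# ----------------------------------------------------------------------
# recovery metrics


def evaluate_segmentation(
    truth: GroundTruth, called: Sequence[Isochore], window: int
) -> SegmentationSummary:
    """Boundary recall (within ±window) and family bp accuracy vs truth."""
    by_chrom_true: Dict[str, List[Isochore]] = {}
    for iso in truth.isochores:
        by_chrom_true.setdefault(iso.chrom, []).append(iso)
    by_chrom_called: Dict[str, List[Isochore]] = {}
    for iso in called:
        by_chrom_called.setdefault(iso.chrom, []).append(iso)

    n_bound = n_hit = 0
    correct_bp = total_bp = 0
    for chrom, tr in by_chrom_true.items():
        tr = sorted(tr, key=lambda x: x.start)
        ca = sorted(by_chrom_called.get(chrom, []), key=lambda x: x.start)
        true_bounds = np.unique([x.start for x in tr] + [x.end for x in tr])
        called_bounds = (
            np.unique([x.start for x in ca] + [x.end for x in ca])
            if ca
            else np.empty(0)
        )
        n_bound += len(true_bounds)
        if len(called_bounds):
            idx = np.searchsorted(called_bounds, true_bounds)
            lo = np.abs(
                true_bounds - called_bounds[np.clip(idx - 1, 0, None)]
            )
            hi = np.abs(
                called_bounds[np.clip(idx, 0, len(called_bounds) - 1)]
                - true_bounds
            )
            n_hit += int(np.sum(np.minimum(lo, hi) <= window))
        # piecewise-exact family agreement
        cuts = np.unique(
            np.concatenate(
                [
                    true_bounds,
                    called_bounds if len(called_bounds) else np.empty(0),
                ]
            )
        ).astype(np.int64)
        t_starts = np.array([x.start for x in tr])
        c_starts = np.array([x.start for x in ca]) if ca else None
        for s, e in zip(cuts[:-1], cuts[1:]):
            total_bp += int(e - s)
            ti = int(np.searchsorted(t_starts, s, side="right")) - 1
            fam_true = tr[ti].family if 0 <= ti < len(tr) else None
            fam_called = None
            if c_starts is not None:
                ci = int(np.searchsorted(c_starts, s, side="right")) - 1
                if 0 <= ci < len(ca) and ca[ci].end > s:
                    fam_called = ca[ci].family
            if fam_true is not None and fam_true == fam_called:
                correct_bp += int(e - s)
    return SegmentationSummary(
        n_isochores=len(called),
        boundary_recall=n_hit / n_bound if n_bound else 0.0,
        bp_accuracy=correct_bp / total_bp if total_bp else 0.0,
    )


# ----------------------------------------------------------------------
# validation


def validate_inputs(
    beds: Sequence = (),
    genome: Optional[Dict[str, int]] = None,
    fasta: Optional[Dict[str, str]] = None,
    matrix: Optional[ContactMatrix] = None,
    orthologs: Optional[pd.DataFrame] = None,
) -> dict:
    """Validate pipeline inputs; returns {'errors': [...], 'warnings': [...]}.

    Checks BED sortedness (warning, with auto-sort being the consumer's
    default), interval bounds vs the genome (fatal), FASTA/genome length
    agreement (fatal), contact-matrix symmetry and tiling (fatal, done at
    construction), and ortholog one-to-one-ness (fatal).
    """
    errors: List[str] = []
    warnings_: List[str] = []
    for k, df in enumerate(beds):
        if isinstance(df, (str, Path)):
            from .regions import read_bed

            df = read_bed(df)
        for chrom, grp in df.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(ends <= starts):
                line = int(grp.index[np.nonzero(ends <= starts)[0][0]]) + 1
                errors.append(
                    f"bed[{k}] {chrom} line {line}: empty or negative interval"
                )
            if genome is not None:
                if chrom not in genome:
                    errors.append(f"bed[{k}]: unknown chromosome {chrom}")
                elif np.any(ends > genome[chrom]):
                    line = int(grp.index[np.nonzero(ends > genome[chrom])[0][0]]) + 1
                    errors.append(
                        f"bed[{k}] {chrom} line {line}: interval beyond "
                        f"chromosome length {genome[chrom]}"
                    )
            if np.any(np.diff(starts) < 0):
                warnings_.append(f"bed[{k}] {chrom}: unsorted, will auto-sort")
    if fasta is not None and genome is not None:
        for chrom, L in genome.items():
            if chrom not in fasta:
                errors.append(f"fasta: missing chromosome {chrom}")
            elif len(fasta[chrom]) != L:
                errors.append(
                    f"fasta {chrom}: length {len(fasta[chrom])} != genome {L}"
                )
    if matrix is not None:
        asym = np.argwhere(~np.isclose(matrix.values, matrix.values.T))
        if len(asym):
            i, j = asym[0]
            errors.append(f"matrix asymmetric at ({i}, {j})")
    if orthologs is not None:
        for col in ("gene_a", "gene_b"):
            dup = orthologs[col][orthologs[col].duplicated()]
            if len(dup):
                errors.append(f"orthologs: duplicate {col} {sorted(set(dup))[:5]}")
    return {"errors": errors, "warnings": warnings_}


# ----------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig, out_dir) -> AnalysisReport:
    """Run the full synthetic analysis and write all declared outputs.

    Any stage error aborts with the stage name; partial outputs are
    retained and MANIFEST.json records per-stage completion.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, str] = {}
    outputs: Dict[str, str] = {}

    def done(stage: str, *files: str) -> None:
        manifest[stage] = "done"
        for f in files:
            outputs[f] = f
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    def run_stage(stage, fn):
        manifest[stage] = "running"
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - report stage and abort
            manifest[stage] = f"failed: {exc}"
            (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(stage, str(exc)) from exc
        return result

    sim = config.simulation

    def stage_simulate():
        genome_seq, truth = simulate_isochore_genome(sim)
        write_fasta(genome_seq, out / "genome.fa")
        write_genome_tsv(truth.genome, out / "genome.tsv")
        isochores_to_bed(truth.isochores, out / "true_isochores.bed")
        return genome_seq, truth

    genome_seq, truth = run_stage("simulate", stage_simulate)
    done("simulate", "genome.fa", "genome.tsv", "true_isochores.bed")

    boundaries = FamilyBoundaries.preset(config.boundaries_mode)

    def stage_segment():
        profiles = {
            chrom: compute_gc_profile(
                seq, config.window, config.step, chrom=chrom
            )
            for chrom, seq in genome_seq.items()
        }
        pd.concat([p.to_dataframe() for p in profiles.values()]).to_csv(
            out / "gc_profile.tsv", sep="\t", index=False
        )
        called: List[Isochore] = []
        for chrom, prof in profiles.items():
            called.extend(
                segment_isochores(prof, boundaries, min_size=config.min_size)
            )
        isochores_to_bed(called, out / "isochores.bed")
        return called

    called = run_stage("segment", stage_segment)
    done("segment", "gc_profile.tsv", "isochores.bed")
    seg_summary = evaluate_segmentation(truth, called, config.window)

    def stage_domains():
        tads, lads = simulate_domains(truth, sim)
        tads.to_bed(out / "tads.bed")
        lads.to_dataframe().assign(
            score=lambda d: (d["score"] * 100).round().astype(int)
        ).to_csv(out / "lads.bed", sep="\t", header=False, index=False)
        return tads, lads

    tads, lads = run_stage("domains", stage_domains)
    done("domains", "tads.bed", "lads.bed")

    def stage_assoc():
        poor_iso = truth.as_region_set(families=GC_POOR, name="isochores[L1+L2]")
        poor_tads = concordant_tads(truth, GC_POOR)
        seed_a = _seed(config.seed, "assoc:tad")
        res_tad = perm_test(
            poor_tads, poor_iso,
            n_perm=config.n_perm, mode=config.association_mode,
            scheme=config.randomization, seed=seed_a,
        )
        res_lad = perm_test(
            lads, poor_iso,
            n_perm=config.n_perm, mode=config.association_mode,
            scheme=config.randomization, seed=_seed(config.seed, "assoc:lad"),
        )
        profile = local_z_profile(
            poor_tads, poor_iso,
            max_shift=config.max_shift, step=config.shift_step,
            n_perm=config.n_perm, mode=config.association_mode,
            scheme=config.randomization, seed=_seed(config.seed, "localz"),
        )
        pd.DataFrame(
            {"shift": profile.shifts, "z": profile.z_values}
        ).to_csv(out / "local_z_profile.tsv", sep="\t", index=False)
        with open(out / "association.json", "w") as fh:
            json.dump(
                {"tad": res_tad.to_dict(), "lad": res_lad.to_dict()},
                fh, indent=2, sort_keys=True,
            )
        return res_tad, res_lad, profile

    res_tad, res_lad, zprofile = run_stage("association", stage_assoc)
    done("association", "association.json", "local_z_profile.tsv")

    def stage_synteny():
        pairs, gc_tab, truth_b = simulate_orthologs(truth, sim)
        pairs.to_csv(out / "orthologs.tsv", sep="\t", index=False)
        blocks = build_synteny_blocks(pairs, min_genes=config.min_genes)
        blocks_to_dataframe(blocks).to_csv(
            out / "synteny_blocks.tsv", sep="\t", index=False
        )
        iso_pairs, _ = orthologous_isochores(blocks, truth.isochores, gc_tab)
        cor = gc_correlation(iso_pairs) if len(iso_pairs) >= 3 else {
            "pearson_r": None, "spearman_rho": None, "n": len(iso_pairs),
            "ci95": None,
        }
        with open(out / "gc_correlation.json", "w") as fh:
            json.dump(cor, fh, indent=2, sort_keys=True)
        return blocks, cor, truth_b

    blocks, cor, truth_b = run_stage("synteny", stage_synteny)
    done("synteny", "orthologs.tsv", "synteny_blocks.tsv", "gc_correlation.json")
    bstats = block_stats(blocks)

    def stage_contacts():
        chroms = list(truth.genome)
        intra = simulate_contact_matrix(truth, sim, "intra", chroms[:1])
        intra.to_files(out / "intra_bins.tsv", out / "intra_triplets.tsv")
        ann_intra = annotate_bins(intra, truth.isochores)
        strat = stratified_contact_profile(
            intra, ann_intra, list(config.distance_breaks)
        )
        strat.to_csv(out / "stratified_contacts.tsv", sep="\t", index=False)
        # measure decay on GC-rich pairs beyond the domain scale: they carry
        # neither the long-range GC-poor boost nor same-domain enrichment
        decay = estimate_decay_exponent(
            intra, max_distance_bins=60, min_distance_bins=8,
            annotation=ann_intra, klass="GC-rich",
        )
        ratio = longrange_class_ratio(intra, ann_intra)
        tops = []
        ann_by_matrix = []
        if len(chroms) >= 2:
            inter = simulate_contact_matrix(truth, sim, "inter", chroms[:2])
            inter.to_files(out / "inter_bins.tsv", out / "inter_triplets.tsv")
            ann_inter = annotate_bins(inter, truth.isochores)
            top = top_interactions(inter, n=config.top_n)
            top.to_csv(out / "top_interactions.tsv", sep="\t", index=False)
            tops.append(top)
            ann_by_matrix.append(ann_inter)
        if tops:
            fractions = interaction_class_fractions(tops, ann_by_matrix[0])
        else:
            fractions = {
                "fraction_gc_rich": float("nan"),
                "fraction_gc_poor": float("nan"),
                "n_bins": 0,
            }
        with open(out / "class_fractions.json", "w") as fh:
            json.dump(fractions, fh, indent=2, sort_keys=True)
        return decay, ratio, fractions

    decay, ratio, fractions = run_stage("contacts", stage_contacts)
    done(
        "contacts",
        "intra_bins.tsv", "intra_triplets.tsv", "stratified_contacts.tsv",
        "inter_bins.tsv", "inter_triplets.tsv", "top_interactions.tsv",
        "class_fractions.json",
    )

    def stage_concordance():
        conc = boundary_concordance(
            tads, called, tolerance=config.boundary_tolerance
        )
        with open(out / "concordance.json", "w") as fh:
            json.dump(conc, fh, indent=2, sort_keys=True)
        cf = lad_cf_by_family(
            lads, truth.isochores, cf_threshold=config.lad_cf_threshold
        )
        cf.to_csv(out / "lad_cf_by_family.tsv", sep="\t", index=False)
        sites = simulate_ctcf_sites(truth, config=sim)
        dens = ctcf_density_by_family(sites, truth.isochores)
        dens.to_csv(out / "ctcf_density.tsv", sep="\t", index=False)
        return conc, cf, dens

    conc, cf_table, dens_table = run_stage("concordance", stage_concordance)
    done(
        "concordance",
        "concordance.json", "lad_cf_by_family.tsv", "ctcf_density.tsv",
    )

    report = AnalysisReport(
        version=_pkg_version,
        seed=config.seed,
        config=config.to_dict(),
        outputs=outputs,
        segmentation=seg_summary,
        tad_association=_assoc_summary(res_tad),
        lad_association=_assoc_summary(res_lad),
        tad_localz=LocalZSummary(
            z_at_zero=zprofile.z_at_zero,
            peak_sharpness=float(min(zprofile.peak_sharpness, 1e12)),
            classification=classify_profile(
                zprofile, config.sharpness_threshold
            ),
            max_shift=config.max_shift,
            step=config.shift_step,
        ),
        synteny=SyntenySummary(
            n_blocks=bstats["count"],
            mean_span=bstats["mean_span"],
            min_span=bstats["min_span"],
            max_span=bstats["max_span"],
            n_true_blocks=len(truth.true_block_partition),
            pearson_r=cor["pearson_r"],
            spearman_rho=cor["spearman_rho"],
            n_pairs=cor["n"],
        ),
        contacts=ContactsSummary(
            decay_exponent_estimate=decay,
            longrange_poor_rich_ratio=ratio["ratio"],
            fraction_gc_rich=fractions["fraction_gc_rich"],
            fraction_gc_poor=fractions["fraction_gc_poor"],
            n_top_bins=int(fractions["n_bins"]),
        ),
        concordance=conc,
        lad_cf=cf_table.to_dict(orient="records"),
        ctcf_density=dens_table.to_dict(orient="records"),
    )
    (out / "report.json").write_text(
        json.dumps(report.model_dump(), indent=2, sort_keys=True)
    )
    manifest["report"] = "done"
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    return report


def _assoc_summary(res) -> AssociationSummary:
    d = res.to_dict()
    return AssociationSummary(
        observed=d["observed"],
        null_mean=d["null_mean"],
        null_sd=d["null_sd"],
        z_score=d["z_score"],
        p_value=d["p_value"],
        n_perm=d["n_perm"],
        mode=d["mode"],
        scheme=d["scheme"],
    )


def _seed(global_seed: int, stage: str) -> int:
    from .config import derive_seed

    return derive_seed(global_seed, stage)
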