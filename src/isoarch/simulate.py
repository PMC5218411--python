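"""Seeded synthetic genomes with planted compositional architecture.

The generator emulates, with recorded ground truth, the structures the
analysis modules are meant to recover: a mosaic genome of isochores in
five GC families (Markov family succession, lognormal lengths, Gaussian
window-GC noise), TADs coinciding with isochores up to boundary jitter,
LADs on the GC-poor families carrying Beta-distributed nuclear-lamina
contact frequencies, cross-species ortholog tables with conserved blocks
and correlated GC, contact matrices with power-law distance decay, domain
blocks, boosted GC-poor long-range interactions and GC-rich-biased
inter-chromosomal hubs, and CTCF sites at family-graded Poisson densities.

Every operation is deterministic given the config seed: named substreams
are derived with :meth:`SimulationConfig.rng`, so identical configs give
bit-identical output and adding one simulation product never perturbs the
others.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import FAMILIES, SimulationConfig
from .contacts import ContactMatrix, make_bins
from .isochores import GC_POOR, Isochore
from .regions import RegionSet

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ATGC", dtype=np.uint8)


@dataclass
class GroundTruth:
    """Planted structure of one synthetic species-A genome."""

    genome: Dict[str, int]
    isochores: List[Isochore]
    #: per-TAD source: isochore index into ``isochores`` or "discordant"
    #: (filled by :func:`simulate_domains`).
    true_tad_map: List = field(default_factory=list)
    #: TAD intervals aligned with ``true_tad_map`` (chrom, start, end).
    true_tad_intervals: List[Tuple[str, int, int]] = field(default_factory=list)
    #: filled by :func:`simulate_orthologs`.
    true_block_partition: List[dict] = field(default_factory=list)
    planted_interchrom_preference: Optional[float] = None

    def __post_init__(self) -> None:
        # isochores must tile every chromosome without gaps or overlaps
        by_chrom: Dict[str, List[Isochore]] = {}
        for iso in self.isochores:
            by_chrom.setdefault(iso.chrom, []).append(iso)
        for chrom, isos in by_chrom.items():
            isos = sorted(isos, key=lambda x: x.start)
            if isos[0].start != 0 or isos[-1].end != self.genome[chrom]:
                raise ValueError(f"true isochores do not tile {chrom}")
            for a, b in zip(isos, isos[1:]):
                if a.end != b.start:
                    raise ValueError(f"gap/overlap in true isochores on {chrom}")
                if a.family == b.family:
                    raise ValueError(
                        f"adjacent true isochores share family on {chrom}"
                    )

    def isochores_on(self, chrom: str) -> List[Isochore]:
        return sorted(
            (i for i in self.isochores if i.chrom == chrom), key=lambda x: x.start
        )

    def family_at(self, chrom: str, pos: int) -> Optional[str]:
        for iso in self.isochores_on(chrom):
            if iso.start <= pos < iso.end:
                return iso.family
        return None

    def as_region_set(
        self, families: Optional[Sequence[str]] = None, name: str = "isochores"
    ) -> RegionSet:
        intervals: Dict[str, list] = {c: [] for c in self.genome}
        for iso in self.isochores:
            if families is None or iso.family in families:
                intervals[iso.chrom].append((iso.start, iso.end))
        return RegionSet(
            name=name,
            genome=dict(self.genome),
            intervals={
                c: np.asarray(v, dtype=np.int64).reshape(-1, 2)
                for c, v in intervals.items()
            },
        )


# ----------------------------------------------------------------------
# genome structure and sequence


def simulate_isochore_structure(config: SimulationConfig) -> GroundTruth:
    """Draw the planted isochore mosaic (no sequence synthesis).

    Per chromosome, families follow the succession matrix (first one from
    its stationary distribution) and lengths are lognormal per family,
    truncated below at ``min_isochore_length`` and above to fit the
    chromosome; a terminal remainder too short to stand alone is given to
    the last isochore.
    """
    rng = config.rng("structure")
    stationary = config.stationary_families()
    genome = {
        f"chr{k + 1}": config.chromosome_length
        for k in range(config.n_chromosomes)
    }
    isochores: List[Isochore] = []
    for chrom in genome:
        L = genome[chrom]
        pos = 0
        fam_idx = int(rng.choice(len(FAMILIES), p=stationary))
        while pos < L:
            mu, sd = config.family_length_params[FAMILIES[fam_idx]]
            length = int(rng.lognormal(mu, sd))
            length = max(length, config.min_isochore_length)
            if L - (pos + length) < config.min_isochore_length:
                length = L - pos  # absorb the remainder
            isochores.append(
                Isochore(
                    chrom=chrom,
                    start=pos,
                    end=pos + length,
                    mean_gc=config.family_gc_targets[FAMILIES[fam_idx]],
                    family=FAMILIES[fam_idx],
                )
            )
            pos += length
            if pos < L:
                row = config.family_transition[fam_idx].copy()
                row[fam_idx] = 0.0  # adjacent isochores get distinct families
                row /= row.sum()
                fam_idx = int(rng.choice(len(FAMILIES), p=row))
    return GroundTruth(genome=genome, isochores=isochores)


def _synthesize_isochore(
    iso: Isochore, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. A/C/G/T bases with per-tile GC = family target + noise."""
    n = iso.length
    w = config.noise_window
    out = np.empty(n, dtype=np.uint8)
    for off in range(0, n, w):
        m = min(w, n - off)
        gc = iso.mean_gc
        if config.window_noise_sd > 0:
            gc = gc + rng.normal(0.0, config.window_noise_sd)
        gc = float(np.clip(gc, 0.0, 100.0))
        is_gc = rng.random(m) < gc / 100.0
        which = rng.integers(0, 2, m)
        out[off : off + m] = _BASES[which + 2 * is_gc]
    return out


def simulate_isochore_genome(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], GroundTruth]:
    """Generate sequences and ground truth for a mosaic isochore genome."""
    truth = simulate_isochore_structure(config)
    rng = config.rng("sequence")
    genome_seq: Dict[str, str] = {}
    for chrom in truth.genome:
        parts = [
            _synthesize_isochore(iso, config, rng)
            for iso in truth.isochores_on(chrom)
        ]
        genome_seq[chrom] = np.concatenate(parts).tobytes().decode("ascii")
    return genome_seq, truth


# ----------------------------------------------------------------------
# domains


def simulate_domains(
    truth: GroundTruth, config: SimulationConfig
) -> Tuple[RegionSet, RegionSet]:
    """TADs (jittered isochores, some discordant) and LADs with CF values.

    Concordant TADs take a true isochore's endpoints perturbed by
    N(0, tad_jitter_sd), clipped to the chromosome and redrawn if the
    interval would collapse; a ``discordant_tad_fraction`` of TADs are
    placed uniformly at random.  LADs are the true L1/L2 isochores with
    contact frequencies drawn from the family's Beta law.  Fills
    ``truth.true_tad_map``.
    """
    rng = config.rng("domains")
    tad_intervals: Dict[str, list] = {c: [] for c in truth.genome}
    tad_map: List = []
    tad_flat: List[Tuple[str, int, int]] = []
    for k, iso in enumerate(truth.isochores):
        L = truth.genome[iso.chrom]
        if rng.random() < config.discordant_tad_fraction:
            length = min(iso.length, L)
            s = int(rng.integers(0, L - length + 1))
            tad_intervals[iso.chrom].append((s, s + length))
            tad_map.append("discordant")
            tad_flat.append((iso.chrom, s, s + length))
            continue
        for _ in range(100):
            s = iso.start + int(round(rng.normal(0, config.tad_jitter_sd)))
            e = iso.end + int(round(rng.normal(0, config.tad_jitter_sd)))
            s, e = max(0, min(s, L)), max(0, min(e, L))
            if e > s:
                break
            logger.warning(
                "jitter collapsed TAD on %s [%d, %d); redrawing",
                iso.chrom, iso.start, iso.end,
            )
        else:  # pragma: no cover - requires pathological jitter
            s, e = iso.start, iso.end
        tad_intervals[iso.chrom].append((s, e))
        tad_map.append(k)
        tad_flat.append((iso.chrom, s, e))
    truth.true_tad_map = tad_map
    truth.true_tad_intervals = tad_flat

    lad_intervals: Dict[str, list] = {c: [] for c in truth.genome}
    lad_scores: Dict[str, list] = {c: [] for c in truth.genome}
    for iso in truth.isochores:
        if iso.family in config.lad_cf_params:
            a, b = config.lad_cf_params[iso.family]
            lad_intervals[iso.chrom].append((iso.start, iso.end))
            lad_scores[iso.chrom].append(float(rng.beta(a, b)))

    tads = RegionSet(
        name="TADs",
        genome=dict(truth.genome),
        intervals={
            c: np.asarray(v, dtype=np.int64).reshape(-1, 2)
            for c, v in tad_intervals.items()
        },
    )
    lads = RegionSet(
        name="LADs",
        genome=dict(truth.genome),
        intervals={
            c: np.asarray(v, dtype=np.int64).reshape(-1, 2)
            for c, v in lad_intervals.items()
        },
        scores={c: np.asarray(v, dtype=float) for c, v in lad_scores.items()},
    )
    return tads, lads


def concordant_tads(
    truth: GroundTruth, families: Sequence[str]
) -> RegionSet:
    """Subset of TADs whose source isochore belongs to the given families.

    The class-restricted TAD set is what the association stage tests
    against the same families' isochores: the full isochore set tiles the
    genome, which would saturate any coverage statistic.  Requires
    :func:`simulate_domains` to have filled ``truth.true_tad_map``.
    """
    intervals: Dict[str, list] = {c: [] for c in truth.genome}
    for src, (chrom, s, e) in zip(truth.true_tad_map, truth.true_tad_intervals):
        if src == "discordant":
            continue
        if truth.isochores[src].family in families:
            intervals[chrom].append((s, e))
    return RegionSet(
        name=f"TADs[{'+'.join(families)}]",
        genome=dict(truth.genome),
        intervals={
            c: np.asarray(v, dtype=np.int64).reshape(-1, 2)
            for c, v in intervals.items()
        },
    )


def regional_control_regions(
    territory: RegionSet,
    n_per_chrom: int = 40,
    length: int = 50_000,
    seed: Optional[int] = None,
) -> RegionSet:
    """Small intervals placed uniformly inside a region set's territory.

    The regional-association control: such a set co-locates with the
    territory without sharing boundaries, so its local z profile is flat
    while a boundary-concordant set's profile peaks at shift zero.
    """
    rng = np.random.default_rng(seed)
    intervals: Dict[str, list] = {}
    for chrom in territory.intervals:
        m = territory.merged(chrom)
        if len(m) == 0:
            continue
        w = (m[:, 1] - m[:, 0]).astype(float)
        w /= w.sum()
        out = []
        for _ in range(n_per_chrom):
            k = int(rng.choice(len(m), p=w))
            hi = max(m[k, 0] + 1, m[k, 1] - length)
            s = int(rng.integers(m[k, 0], hi))
            out.append((s, min(s + length, int(m[k, 1]))))
        intervals[chrom] = np.asarray(out, dtype=np.int64)
    return RegionSet(
        name="regional-control", genome=dict(territory.genome),
        intervals=intervals,
    )


# ----------------------------------------------------------------------
# contact matrices


def _bin_annotation_from_truth(
    bins: pd.DataFrame, truth: GroundTruth
) -> Tuple[np.ndarray, np.ndarray]:
    """(isochore index, GC-poor flag) per bin, by bin midpoint."""
    iso_idx = np.full(len(bins), -1, dtype=int)
    poor = np.zeros(len(bins), dtype=bool)
    index_of = {id(iso): k for k, iso in enumerate(truth.isochores)}
    by_chrom: Dict[str, List[Isochore]] = {}
    for iso in truth.isochores:
        by_chrom.setdefault(iso.chrom, []).append(iso)
    for k, row in enumerate(bins.itertuples(index=False)):
        mid = (int(row.start) + int(row.end)) // 2
        for iso in by_chrom.get(row.chrom, []):
            if iso.start <= mid < iso.end:
                iso_idx[k] = index_of[id(iso)]
                poor[k] = iso.family in GC_POOR
                break
    return iso_idx, poor


def simulate_contact_matrix(
    truth: GroundTruth,
    config: SimulationConfig,
    kind: str = "intra",
    chroms: Optional[Sequence[str]] = None,
) -> ContactMatrix:
    """Poisson contact matrix around the planted expectation law.

    intra: E[i, j] = base · |i−j|^(−decay_exponent), times ``domain_boost``
    when both bins sit in the same true isochore and
    ``gcpoor_longrange_boost`` when both bins are GC-poor.

    inter: a set of interaction-hub bins per chromosome, of which a
    fraction ``interchrom_gcrich_preference`` are GC-rich, exchanges high
    Poisson intensity (all hub×hub cross-chromosome pairs); everything
    else is uniform background.  The preference is thus the planted
    GC-rich fraction of involved bins, the quantity
    :func:`~isoarch.contacts.interaction_class_fractions` recovers.
    """
    if kind not in ("intra", "inter"):
        raise ValueError("kind must be 'intra' or 'inter'")
    if kind == "inter" and len(truth.genome) < 2:
        raise ValueError("inter-chromosomal matrix needs >= 2 chromosomes")
    if chroms is None:
        chroms = (
            [next(iter(truth.genome))]
            if kind == "intra"
            else list(truth.genome)[:2]
        )
    if kind == "inter" and len(chroms) != 2:
        raise ValueError("inter matrix takes exactly two chromosomes")
    rng = config.rng(f"contacts:{kind}:{','.join(chroms)}")
    bins = make_bins(truth.genome, config.contact_resolution, chroms)
    iso_idx, poor = _bin_annotation_from_truth(bins, truth)
    n = len(bins)
    chrom_arr = bins["chrom"].to_numpy()

    lam = np.zeros((n, n))
    if kind == "intra":
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        same_chrom = chrom_arr[ii] == chrom_arr[jj]
        d = np.abs(ii - jj).astype(float)
        with np.errstate(divide="ignore"):
            lam = config.contact_base * np.where(
                d > 0, d ** (-config.decay_exponent), 1.0
            )
        lam *= np.where(iso_idx[ii] == iso_idx[jj], config.domain_boost, 1.0)
        lam *= np.where(poor[ii] & poor[jj], config.gcpoor_longrange_boost, 1.0)
        lam = np.where(same_chrom, lam, 0.0)
    else:
        lam[:] = 0.0
        cross = chrom_arr[:, None] != chrom_arr[None, :]
        lam[cross] = config.interchrom_background
        hubs = _draw_hubs(bins, poor, chroms, config)
        hub_mask = np.zeros(n, dtype=bool)
        hub_mask[hubs] = True
        strong = hub_mask[:, None] & hub_mask[None, :] & cross
        lam[strong] = config.interchrom_hub_intensity

    iu, ju = np.triu_indices(n, k=1)
    vals = np.zeros((n, n))
    draws = rng.poisson(lam[iu, ju]).astype(float)
    vals[iu, ju] = draws
    vals[ju, iu] = draws
    if kind == "intra":
        diag = rng.poisson(
            np.full(n, config.contact_base * config.domain_boost)
        ).astype(float)
        vals[np.arange(n), np.arange(n)] = diag
    return ContactMatrix(
        resolution=config.contact_resolution,
        bins=bins,
        values=vals,
        kind=kind,
        normalization_tag="synthetic-poisson",
    )


def _draw_hubs(
    bins: pd.DataFrame,
    poor: np.ndarray,
    chroms: Sequence[str],
    config: SimulationConfig,
) -> np.ndarray:
    """Hub bin ids: per chromosome, exactly round(p·k) GC-rich hubs.

    Hubs are a property of the chromosome, not of a matrix: each
    chromosome's hubs come from a chromosome-keyed stream, so every
    chromosome pair involving it sees the same hub loci.
    """
    hubs: List[int] = []
    chrom_arr = bins["chrom"].to_numpy()
    k = config.interchrom_hubs_per_chrom
    n_rich_target = int(round(config.interchrom_gcrich_preference * k))
    for chrom in chroms:
        rng = config.rng(f"hubs:{chrom}")
        ids = np.nonzero(chrom_arr == chrom)[0]
        rich_ids = ids[~poor[ids]]
        poor_ids = ids[poor[ids]]
        n_rich = min(n_rich_target, len(rich_ids))
        n_poor = min(k - n_rich_target, len(poor_ids))
        if n_rich < n_rich_target or n_poor < k - n_rich_target:
            warnings.warn(
                f"chromosome {chrom}: only {n_rich} GC-rich / {n_poor} GC-poor "
                "hub candidates available", stacklevel=2,
            )
        hubs.extend(rng.choice(rich_ids, n_rich, replace=False).tolist())
        hubs.extend(rng.choice(poor_ids, n_poor, replace=False).tolist())
    return np.asarray(hubs, dtype=int)


# ----------------------------------------------------------------------
# orthologs


@dataclass
class SpeciesBTruth:
    """Planted species-B gene order: block permutation and orientations."""

    genome_b: Dict[str, int]
    blocks: List[dict]  # chrom_a, genes, orientation, slot


def _assign_slots(
    n_blocks: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Slot permutation + orientations with every A-junction breaking
    monotonicity, so each planted block is detectable by the chaining rule.

    A junction merges chains iff a direct block is followed (in A order)
    by a block placed later in B, or an inverted one by a block placed
    earlier.  Drawing a uniform slot permutation and *forcing* each
    block's orientation from its successor's side (direct iff the next
    block sits earlier in B) guarantees every junction breaks; the
    orientation sequence is then the descent pattern of a uniform
    permutation — a near-fair, weakly dependent coin.  The last block's
    orientation is a free coin flip.
    """
    slots = rng.permutation(n_blocks)
    orient = np.empty(n_blocks, dtype=int)  # 1 = inverted
    for t in range(n_blocks - 1):
        orient[t] = 0 if slots[t + 1] < slots[t] else 1
    orient[n_blocks - 1] = int(rng.integers(0, 2))
    return slots, orient


def simulate_orthologs(
    truth_a: GroundTruth,
    config: SimulationConfig,
    gc_noise_sd: Optional[float] = None,
    shuffle_blocks: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame, SpeciesBTruth]:
    """Ortholog pair table with planted synteny blocks and correlated GC.

    Genes are laid out evenly along each species-A chromosome, grouped
    into consecutive blocks of ``genes_per_block``; blocks are permuted
    and inverted onto the species-B chromosome under a detectability
    constraint (see :func:`_assign_slots`).  Per-gene species-B GC is the
    species-A value plus N(0, ortholog_gc_noise_sd), clipped to [0, 100].

    Returns (ortholog table, per-gene GC table, species-B truth); the GC
    table doubles as the ``gc_b`` source for
    :func:`~isoarch.synteny.orthologous_isochores`.
    """
    rng = config.rng("orthologs")
    sd = config.ortholog_gc_noise_sd if gc_noise_sd is None else gc_noise_sd
    gene_len = 10_000
    rows = []
    gc_rows = []
    genome_b: Dict[str, int] = {}
    blocks_truth: List[dict] = []
    gpb = config.genes_per_block
    for chrom in truth_a.genome:
        L = truth_a.genome[chrom]
        n_genes = config.orthologs_per_chrom
        spacing = L // n_genes
        if spacing <= gene_len:
            raise ValueError("too many orthologs for chromosome length")
        n_blocks = n_genes // gpb
        if n_blocks < 1:
            raise ValueError("not enough genes for a single block")
        if shuffle_blocks:
            slots, orient = _assign_slots(n_blocks, rng)
        else:  # identity permutation, all direct (collinear genomes)
            slots = np.arange(n_blocks)
            orient = np.zeros(n_blocks, dtype=int)
        chrom_b = chrom.replace("chr", "chrB")
        genome_b[chrom_b] = L
        isos = truth_a.isochores_on(chrom)
        iso_starts = np.array([i.start for i in isos])
        for t in range(n_blocks):
            slot = int(slots[t])
            inverted = bool(orient[t])
            gene_ids = []
            for k in range(gpb):
                g = t * gpb + k
                start_a = g * spacing + (spacing - gene_len) // 2
                mid = start_a + gene_len // 2
                iso = isos[
                    int(np.searchsorted(iso_starts, mid, side="right")) - 1
                ]
                gc_a = iso.mean_gc
                gc_b = float(np.clip(gc_a + rng.normal(0.0, sd), 0.0, 100.0))
                pos_in_slot = (gpb - 1 - k) if inverted else k
                start_b = (slot * gpb + pos_in_slot) * spacing + (
                    spacing - gene_len
                ) // 2
                gene_a = f"{chrom}:g{g}"
                gene_b = f"{chrom_b}:g{g}"
                rows.append(
                    {
                        "gene_a": gene_a,
                        "chrom_a": chrom,
                        "start_a": start_a,
                        "end_a": start_a + gene_len,
                        "gene_b": gene_b,
                        "chrom_b": chrom_b,
                        "start_b": start_b,
                        "end_b": start_b + gene_len,
                        "strand_b": "-" if inverted else "+",
                    }
                )
                gc_rows.append(
                    {
                        "gene_b": gene_b,
                        "chrom_b": chrom_b,
                        "start_b": start_b,
                        "end_b": start_b + gene_len,
                        "gc_a": gc_a,
                        "gc_b": gc_b,
                    }
                )
                gene_ids.append(gene_a)
            blocks_truth.append(
                {
                    "chrom_a": chrom,
                    "genes": tuple(gene_ids),
                    "orientation": "inverted" if inverted else "direct",
                    "slot": slot,
                }
            )
    truth_a.true_block_partition = blocks_truth
    return (
        pd.DataFrame(rows),
        pd.DataFrame(gc_rows),
        SpeciesBTruth(genome_b=genome_b, blocks=blocks_truth),
    )


def calibrate_ortholog_noise(
    truth_a: GroundTruth, config: SimulationConfig, target_r: float
) -> float:
    """Noise sd giving an expected cross-species GC correlation ``target_r``.

    With gc_b = gc_a + ε, ε ~ N(0, σ²): r = sd(gc_a)/sqrt(sd(gc_a)² + σ²),
    so σ = sd(gc_a)·sqrt(1/r² − 1).  sd(gc_a) is computed over the same
    gene layout :func:`simulate_orthologs` uses.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    gene_len = 10_000
    gcs = []
    for chrom in truth_a.genome:
        L = truth_a.genome[chrom]
        spacing = L // config.orthologs_per_chrom
        isos = truth_a.isochores_on(chrom)
        iso_starts = np.array([i.start for i in isos])
        n_blocks = config.orthologs_per_chrom // config.genes_per_block
        for g in range(n_blocks * config.genes_per_block):
            mid = g * spacing + (spacing - gene_len) // 2 + gene_len // 2
            iso = isos[int(np.searchsorted(iso_starts, mid, side="right")) - 1]
            gcs.append(iso.mean_gc)
    sd_a = float(np.std(gcs))
    return sd_a * float(np.sqrt(1.0 / target_r**2 - 1.0))


# ----------------------------------------------------------------------
# CTCF sites


def simulate_ctcf_sites(
    truth: GroundTruth,
    densities: Optional[Dict[str, float]] = None,
    seed: Optional[int] = None,
    config: Optional[SimulationConfig] = None,
) -> Dict[str, np.ndarray]:
    """CTCF site positions: homogeneous Poisson per isochore at the
    family's rate (sites per Mb)."""
    if config is not None and densities is None:
        densities = config.ctcf_densities
    if densities is None:
        raise ValueError("provide densities or a config")
    if any(v < 0 for v in densities.values()):
        raise ValueError("densities must be >= 0")
    if config is not None and seed is None:
        rng = config.rng("ctcf")
    else:
        rng = np.random.default_rng(seed)
    sites: Dict[str, List[int]] = {c: [] for c in truth.genome}
    for iso in truth.isochores:
        rate = densities.get(iso.family, 0.0)
        n = int(rng.poisson(rate * iso.length / 1e6))
        if n:
            sites[iso.chrom].extend(
                int(x) for x in rng.integers(iso.start, iso.end, n)
            )
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in sites.items()}
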