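"""Class-stratified statistics of binned chromatin contact matrices.

Bins of a fixed-resolution contact matrix are annotated with the isochore
family of majority overlap and collapsed into the two compositional
classes, GC-poor (L1+L2) and GC-rich (H1+H2+H3).  On that annotation the
module computes distance-stratified mean contacts per class pair, the
top-N inter-chromosomal interactions and the class fractions of their
involved bins, TAD/LAD-to-isochore boundary concordance, and per-family
summaries of lamina contact frequencies.  Matrices are consumed
pre-normalized; balancing happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .isochores import FAMILIES, GC_POOR, GC_RICH, Isochore
from .regions import RegionSet


@dataclass
class ContactMatrix:
    """Symmetric binned contact values at fixed resolution.

    ``bins`` has columns (bin_id, chrom, start, end) tiling the involved
    chromosomes (the last bin of a chromosome may be short); ``values`` is
    a dense symmetric array indexed by bin_id.  ``kind`` is ``intra`` or
    ``inter``; for inter matrices only cross-chromosome entries are
    meaningful.
    """

    resolution: int
    bins: pd.DataFrame
    values: np.ndarray
    kind: str = "intra"
    normalization_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.bins)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match bin table")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("negative contact values")
        self._check_tiling()

    def _check_tiling(self) -> None:
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not np.array_equal(starts[1:], ends[:-1]) or starts[0] != 0:
                raise ValueError(f"bins do not tile chromosome {chrom}")
            widths = ends - starts
            if np.any(widths[:-1] != self.resolution) or widths[-1] > self.resolution:
                raise ValueError(
                    f"bin tiling inconsistent with resolution on {chrom}"
                )

    # -- io --------------------------------------------------------------
    def to_files(self, bins_path, triplets_path) -> None:
        self.bins.to_csv(bins_path, sep="\t", index=False, header=False)
        i, j = np.nonzero(np.triu(self.values))
        pd.DataFrame(
            {"bin_i": i, "bin_j": j, "value": self.values[i, j]}
        ).to_csv(triplets_path, sep="\t", index=False, header=False)

    @classmethod
    def from_files(
        cls, bins_path, triplets_path, resolution: int, kind: str = "intra",
        normalization_tag: str = "raw",
    ) -> "ContactMatrix":
        bins = pd.read_csv(
            bins_path, sep="\t", header=None,
            names=["bin_id", "chrom", "start", "end"],
        )
        trip = pd.read_csv(
            triplets_path, sep="\t", header=None, names=["bin_i", "bin_j", "value"]
        )
        n = len(bins)
        values = np.zeros((n, n))
        values[trip["bin_i"], trip["bin_j"]] = trip["value"]
        values[trip["bin_j"], trip["bin_i"]] = trip["value"]
        return cls(resolution, bins, values, kind, normalization_tag)


def make_bins(
    genome: Dict[str, int], resolution: int, chroms: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Bin table tiling the given chromosomes at ``resolution``."""
    rows = []
    bid = 0
    for chrom in chroms if chroms is not None else genome:
        L = genome[chrom]
        for s in range(0, L, resolution):
            rows.append(
                {"bin_id": bid, "chrom": chrom, "start": s, "end": min(s + resolution, L)}
            )
            bid += 1
    return pd.DataFrame(rows)


@dataclass
class BinAnnotation:
    """Per-bin isochore family and compositional class labels."""

    family: np.ndarray  # object array, family label or None
    klass: np.ndarray = field(init=False)  # 'GC-rich' | 'GC-poor' | None

    def __post_init__(self) -> None:
        self.family = np.asarray(self.family, dtype=object)
        kl = np.empty(len(self.family), dtype=object)
        for i, f in enumerate(self.family):
            if f in GC_POOR:
                kl[i] = "GC-poor"
            elif f in GC_RICH:
                kl[i] = "GC-rich"
            else:
                kl[i] = None
        self.klass = kl


def _majority_family(
    chrom: str, start: int, end: int, isos: List[Isochore]
) -> Optional[str]:
    """Family of majority bp overlap; exact tie broken by the isochore
    containing the midpoint; None if >50% of the span is uncovered."""
    cover: Dict[str, int] = {}
    covered = 0
    for iso in isos:
        lo, hi = max(start, iso.start), min(end, iso.end)
        if hi > lo:
            cover[iso.family] = cover.get(iso.family, 0) + (hi - lo)
            covered += hi - lo
    span = end - start
    if covered * 2 < span or not cover:
        return None
    best = max(cover.values())
    winners = [f for f, v in cover.items() if v == best]
    if len(winners) == 1:
        return winners[0]
    mid = (start + end) // 2
    for iso in isos:
        if iso.start <= mid < iso.end and iso.family in winners:
            return iso.family
    return sorted(winners)[0]


def annotate_bins(
    matrix: ContactMatrix, isochores: Sequence[Isochore]
) -> BinAnnotation:
    """Label each matrix bin with the isochore family of majority overlap."""
    by_chrom: Dict[str, List[Isochore]] = {}
    for iso in isochores:
        by_chrom.setdefault(iso.chrom, []).append(iso)
    fam = np.empty(len(matrix.bins), dtype=object)
    for k, row in enumerate(matrix.bins.itertuples(index=False)):
        isos = by_chrom.get(row.chrom, [])
        fam[k] = _majority_family(row.chrom, int(row.start), int(row.end), isos)
    return BinAnnotation(family=fam)


def stratified_contact_profile(
    matrix: ContactMatrix,
    annotation: BinAnnotation,
    distance_breaks: Sequence[int],
) -> pd.DataFrame:
    """Mean contact per (class_i, class_j, distance stratum).

    Every unordered annotated intra-chromosomal bin pair contributes once;
    unassigned bins are excluded; absent sparse entries count as zeros
    (they are zeros in the dense representation).
    """
    if matrix.kind != "intra":
        raise ValueError("stratified profile is defined for intra matrices")
    breaks = list(distance_breaks)
    if breaks != sorted(breaks):
        raise ValueError("distance_breaks must be increasing")
    edges = [0] + breaks + [np.inf]
    labels = [
        f"[{int(edges[k])},{'inf' if np.isinf(edges[k+1]) else int(edges[k+1])})"
        for k in range(len(edges) - 1)
    ]
    acc: Dict[Tuple[str, str, str], List[float]] = {}
    bins = matrix.bins
    chrom = bins["chrom"].to_numpy()
    mids = ((bins["start"] + bins["end"]) // 2).to_numpy()
    n = len(bins)
    for i in range(n):
        if annotation.klass[i] is None:
            continue
        for j in range(i + 1, n):
            if chrom[j] != chrom[i] or annotation.klass[j] is None:
                continue
            d = abs(int(mids[j]) - int(mids[i]))
            s = int(np.searchsorted(edges, d, side="right")) - 1
            ci, cj = sorted((annotation.klass[i], annotation.klass[j]))
            acc.setdefault((ci, cj, labels[s]), []).append(matrix.values[i, j])
    rows = [
        {
            "class_i": k[0],
            "class_j": k[1],
            "stratum": k[2],
            "mean_value": float(np.mean(v)),
            "n_pairs": len(v),
            "sum_value": float(np.sum(v)),
        }
        for k, v in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows, columns=["class_i", "class_j", "stratum", "mean_value", "n_pairs",
                       "sum_value"]
    )


def top_interactions(matrix: ContactMatrix, n: int = 100) -> pd.DataFrame:
    """The n largest inter-chromosomal entries, sorted descending.

    Ties are broken by ascending (bin_i, bin_j).  Fewer than n nonzero
    entries returns them all with a warning.
    """
    if matrix.kind != "inter":
        raise ValueError("top_interactions requires an inter matrix")
    if n < 1:
        raise ValueError("n must be >= 1")
    chrom = matrix.bins["chrom"].to_numpy()
    iu, ju = np.triu_indices(len(matrix.bins), k=1)
    cross = chrom[iu] != chrom[ju]
    iu, ju = iu[cross], ju[cross]
    vals = matrix.values[iu, ju]
    nz = vals > 0
    iu, ju, vals = iu[nz], ju[nz], vals[nz]
    if len(vals) < n:
        import warnings

        warnings.warn(
            f"only {len(vals)} nonzero inter entries (< n={n})", stacklevel=2
        )
        n = len(vals)
    order = np.lexsort((ju, iu, -vals))[:n]
    return pd.DataFrame(
        {"bin_i": iu[order], "bin_j": ju[order], "value": vals[order]}
    )


def interaction_class_fractions(
    tops: Sequence[pd.DataFrame], annotation: BinAnnotation
) -> dict:
    """Class fractions of the distinct bins involved in top interactions.

    A bin appearing in many top pairs counts once; fractions are over
    assigned bins and sum to 1.  ``per_pair`` weighting (every interaction
    endpoint counted) is available via :func:`interaction_class_fractions_weighted`.
    """
    bins: set = set()
    for t in tops:
        bins.update(int(b) for b in t["bin_i"])
        bins.update(int(b) for b in t["bin_j"])
    rich = poor = unassigned = 0
    for b in bins:
        k = annotation.klass[b]
        if k == "GC-rich":
            rich += 1
        elif k == "GC-poor":
            poor += 1
        else:
            unassigned += 1
    assigned = rich + poor
    return {
        "fraction_gc_rich": rich / assigned if assigned else float("nan"),
        "fraction_gc_poor": poor / assigned if assigned else float("nan"),
        "n_bins": assigned,
        "n_unassigned": unassigned,
    }


def aggregate_class_fractions(
    items: Sequence[Tuple[ContactMatrix, pd.DataFrame, BinAnnotation]]
) -> dict:
    """Class fractions of distinct bins over several matrices' top lists.

    Bin ids are matrix-local, so distinct bins are keyed by genomic locus
    (chrom, start) when aggregating across chromosome pairs.
    """
    rich: set = set()
    poor: set = set()
    unassigned = 0
    for matrix, top, ann in items:
        for col in ("bin_i", "bin_j"):
            for b in top[col]:
                b = int(b)
                row = matrix.bins.iloc[b]
                key = (row["chrom"], int(row["start"]))
                k = ann.klass[b]
                if k == "GC-rich":
                    rich.add(key)
                elif k == "GC-poor":
                    poor.add(key)
                else:
                    unassigned += 1
    assigned = len(rich) + len(poor)
    return {
        "fraction_gc_rich": len(rich) / assigned if assigned else float("nan"),
        "fraction_gc_poor": len(poor) / assigned if assigned else float("nan"),
        "n_bins": assigned,
        "n_unassigned": unassigned,
    }


def interaction_class_fractions_weighted(
    tops: Sequence[pd.DataFrame], annotation: BinAnnotation
) -> dict:
    """Endpoint-weighted alternative to :func:`interaction_class_fractions`."""
    rich = poor = 0
    for t in tops:
        for col in ("bin_i", "bin_j"):
            for b in t[col]:
                k = annotation.klass[int(b)]
                if k == "GC-rich":
                    rich += 1
                elif k == "GC-poor":
                    poor += 1
    assigned = rich + poor
    return {
        "fraction_gc_rich": rich / assigned if assigned else float("nan"),
        "fraction_gc_poor": poor / assigned if assigned else float("nan"),
        "n_bins": assigned,
    }


def boundary_concordance(
    domains: RegionSet, isochores: Sequence[Isochore], tolerance: int = 100_000
) -> dict:
    """Fraction of domain boundaries within ``tolerance`` bp of an isochore
    boundary on the same chromosome."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    bounds: Dict[str, np.ndarray] = {}
    for iso in isochores:
        bounds.setdefault(iso.chrom, [])
    tmp: Dict[str, List[int]] = {c: [] for c in bounds}
    for iso in isochores:
        tmp[iso.chrom].extend((iso.start, iso.end))
    bounds = {c: np.unique(np.asarray(v)) for c, v in tmp.items()}
    matched = total = 0
    for chrom, iv in domains.intervals.items():
        pts = np.concatenate([iv[:, 0], iv[:, 1]]) if len(iv) else np.empty(0)
        total += len(pts)
        ib = bounds.get(chrom)
        if ib is None or len(ib) == 0:
            continue
        idx = np.searchsorted(ib, pts)
        left = np.abs(pts - ib[np.clip(idx - 1, 0, len(ib) - 1)])
        right = np.abs(ib[np.clip(idx, 0, len(ib) - 1)] - pts)
        matched += int(np.sum(np.minimum(left, right) <= tolerance))
    return {
        "fraction_matched": matched / total if total else 0.0,
        "matched": matched,
        "total": total,
        "tolerance": tolerance,
    }


def lad_cf_by_family(
    lads: RegionSet, isochores: Sequence[Isochore], cf_threshold: float = 0.8
) -> pd.DataFrame:
    """Per-family lamina contact-frequency summaries.

    Each LAD is assigned to the family of majority bp overlap (same rule as
    bin annotation); CF values are read from the region set's scores (on
    [0, 1]).  Reports n, mean CF and the fraction with CF above the
    threshold (default the printed 80% level of "stable" contacts).
    """
    by_chrom: Dict[str, List[Isochore]] = {}
    for iso in isochores:
        by_chrom.setdefault(iso.chrom, []).append(iso)
    acc: Dict[str, List[float]] = {f: [] for f in FAMILIES}
    for chrom, iv in lads.intervals.items():
        scores = (
            lads.scores.get(chrom)
            if lads.scores is not None
            else np.full(len(iv), np.nan)
        )
        isos = by_chrom.get(chrom, [])
        for (s, e), cf in zip(iv, scores):
            fam = _majority_family(chrom, int(s), int(e), isos)
            if fam is not None:
                acc[fam].append(float(cf))
    rows = []
    for f in FAMILIES:
        v = np.asarray(acc[f])
        if len(v) == 0:
            continue
        rows.append(
            {
                "family": f,
                "n_lads": len(v),
                "mean_cf": float(np.nanmean(v)),
                "fraction_high_cf": float(np.mean(v > cf_threshold)),
            }
        )
    return pd.DataFrame(
        rows, columns=["family", "n_lads", "mean_cf", "fraction_high_cf"]
    )


def estimate_decay_exponent(
    matrix: ContactMatrix,
    max_distance_bins: Optional[int] = None,
    min_distance_bins: int = 1,
    annotation: Optional[BinAnnotation] = None,
    klass: Optional[str] = None,
) -> float:
    """Distance-decay exponent by log-log regression of mean contact vs
    bin separation over an intra-chromosomal matrix.

    ``min_distance_bins`` excludes short separations where same-domain
    enrichment sits on top of the power law and would bias the slope;
    passing ``annotation`` and ``klass`` restricts to bin pairs of one
    compositional class (e.g. GC-rich, which carries no long-range boost).
    """
    if matrix.kind != "intra":
        raise ValueError("decay estimation requires an intra matrix")
    if (annotation is None) != (klass is None):
        raise ValueError("annotation and klass go together")
    chrom = matrix.bins["chrom"].to_numpy()
    n = len(matrix.bins)
    means = {}
    for c in pd.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        if annotation is not None:
            idx = idx[[annotation.klass[i] == klass for i in idx]]
        k = len(idx)
        dmax = max_distance_bins or (k - 1)
        for a_i, i in enumerate(idx):
            for j in idx[a_i + 1 :]:
                d = int(j - i)
                if d < max(1, min_distance_bins) or d > dmax:
                    continue
                means.setdefault(d, []).append(matrix.values[i, j])
    ds = np.array(sorted(means))
    mu = np.array([np.mean(means[d]) for d in ds])
    keep = mu > 0
    slope, _, _, _, _ = stats.linregress(np.log(ds[keep]), np.log(mu[keep]))
    return float(-slope)


def longrange_class_ratio(
    matrix: ContactMatrix,
    annotation: BinAnnotation,
    min_separation: int = 5_000_000,
) -> dict:
    """Distance-matched GC-poor/GC-poor over GC-rich/GC-rich contact ratio
    beyond ``min_separation`` bp, with a Poisson-delta standard error.

    For each exact bin separation the class sums are accumulated; the
    ratio is inverse-variance weighted on the log scale across distances
    so compositional differences in within-stratum distance mixtures do
    not bias it.
    """
    chrom = matrix.bins["chrom"].to_numpy()
    mids = ((matrix.bins["start"] + matrix.bins["end"]) // 2).to_numpy()
    n = len(matrix.bins)
    per_d: Dict[int, Dict[str, List[float]]] = {}
    for i in range(n):
        ki = annotation.klass[i]
        if ki is None:
            continue
        for j in range(i + 1, n):
            if chrom[j] != chrom[i]:
                continue
            kj = annotation.klass[j]
            if kj is None or ki != kj:
                continue
            d = abs(int(mids[j]) - int(mids[i]))
            if d <= min_separation:
                continue
            per_d.setdefault(d, {"GC-poor": [], "GC-rich": []})[ki].append(
                matrix.values[i, j]
            )
    logs, weights = [], []
    for d, v in per_d.items():
        sp, sr = np.sum(v["GC-poor"]), np.sum(v["GC-rich"])
        np_, nr = len(v["GC-poor"]), len(v["GC-rich"])
        if np_ == 0 or nr == 0 or sp <= 0 or sr <= 0:
            continue
        logs.append(np.log((sp / np_) / (sr / nr)))
        weights.append(1.0 / (1.0 / sp + 1.0 / sr))
    if not logs:
        return {"ratio": float("nan"), "se": float("nan"), "n_distances": 0}
    logs = np.asarray(logs)
    weights = np.asarray(weights)
    log_ratio = float(np.sum(logs * weights) / np.sum(weights))
    se_log = float(1.0 / np.sqrt(np.sum(weights)))
    ratio = float(np.exp(log_ratio))
    return {
        "ratio": ratio,
        "se": ratio * se_log,
        "n_distances": len(logs),
    }
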