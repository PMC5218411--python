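"""Isochore calling: windowed GC profiles, family thresholds, segmentation.

An isochore is a long (≳200 kb) genomic segment of fairly homogeneous GC,
classified into the five Bernardi families L1, L2 (GC-poor) and H1, H2, H3
(GC-rich) by increasing GC level.  Calling is threshold classification of
windowed GC followed by a smoothing merge that absorbs sub-minimum
segments into the compositionally nearer neighbour — no HMM, no
likelihood model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

FAMILIES = ("L1", "L2", "H1", "H2", "H3")
FAMILY_INDEX = {f: i for i, f in enumerate(FAMILIES)}
GC_POOR = ("L1", "L2")
GC_RICH = ("H1", "H2", "H3")

#: GC% cutpoints separating L1|L2|H1|H2|H3.  The 46 value is the H1 upper
#: threshold; "extended" ranges lift it to 47 to tolerate minimal
#: trespassings of 46 by H1 isochores.
FIXED_CUTPOINTS = (37.0, 41.0, 46.0, 53.0)
EXTENDED_CUTPOINTS = (37.0, 41.0, 47.0, 53.0)


@dataclass(frozen=True)
class FamilyBoundaries:
    """Family classification thresholds on the GC% axis.

    Assignment is half-open: family f covers [low_f, high_f), so a GC of
    exactly 46 falls in H2 under the fixed boundaries.
    """

    mode: str = "fixed"
    cutpoints: Tuple[float, float, float, float] = FIXED_CUTPOINTS

    def __post_init__(self) -> None:
        c = self.cutpoints
        if len(c) != 4 or not all(a < b for a, b in zip(c, c[1:])):
            raise ValueError("cutpoints must be four strictly increasing GC% values")

    @classmethod
    def preset(cls, mode: str) -> "FamilyBoundaries":
        if mode == "fixed":
            return cls("fixed", FIXED_CUTPOINTS)
        if mode == "extended":
            return cls("extended", EXTENDED_CUTPOINTS)
        raise ValueError(f"unknown boundaries mode {mode!r}")


def assign_family(gc, boundaries: FamilyBoundaries = FamilyBoundaries()):
    """Family whose half-open GC range [low, high) contains ``gc``.

    Vectorized: accepts a scalar or array; returns a label or object array.
    """
    cuts = np.asarray(boundaries.cutpoints)
    idx = np.searchsorted(cuts, np.asarray(gc, dtype=float), side="right")
    labels = np.asarray(FAMILIES, dtype=object)[idx]
    if np.isscalar(gc) or np.ndim(gc) == 0:
        return str(labels)
    return labels


@dataclass
class GCProfile:
    """Windowed GC profile of one chromosome.

    ``values`` holds GC% per window with NaN for masked windows (non-ACGT
    fraction above the masking policy).  ``weights`` holds the number of
    ACGT bases actually counted in each window.
    """

    chrom: str
    window: int
    step: int
    window_starts: np.ndarray
    window_ends: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    partial_last: bool = False

    def __len__(self) -> int:
        return len(self.values)

    @property
    def masked(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.window_starts,
                "end": self.window_ends,
                "gc": self.values,
            }
        )


_GC_BYTES = frozenset(b"GCgc")
_ACGT_BYTES = frozenset(b"ACGTacgt")


def _seq_masks(sequence) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(sequence, str):
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    elif isinstance(sequence, (bytes, bytearray)):
        arr = np.frombuffer(bytes(sequence), dtype=np.uint8)
    else:
        arr = np.asarray(sequence, dtype=np.uint8)
    upper = np.where((arr >= 97) & (arr <= 122), arr - 32, arr)
    gc = (upper == ord("G")) | (upper == ord("C"))
    acgt = gc | (upper == ord("A")) | (upper == ord("T"))
    return gc, acgt


def compute_gc_profile(
    sequence,
    window: int,
    step: Optional[int] = None,
    n_policy: float = 0.5,
    chrom: str = "chr",
    strict: bool = False,
) -> GCProfile:
    """Sliding-window GC% profile of a nucleotide sequence.

    GC% is 100·(G+C)/(A+C+G+T) over the window; bases outside ACGT are
    excluded from both numerator and denominator.  A window whose non-ACGT
    fraction exceeds ``n_policy`` is masked (NaN).  A trailing partial
    window is kept iff it spans at least half the window length.

    Parameters
    ----------
    window, step : bp; ``step`` defaults to ``window`` (non-overlapping
        tiling, the segmentation default — overlapping windows would
        double-count sequence).
    strict : raise if the sequence is shorter than one window instead of
        returning a single partial window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = window if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    gc_mask, acgt_mask = _seq_masks(sequence)
    n = len(gc_mask)
    if n == 0:
        raise ValueError("empty sequence")
    if n < window and strict:
        raise ValueError(f"sequence ({n} bp) shorter than window ({window} bp)")

    gc_cum = np.concatenate(([0], np.cumsum(gc_mask, dtype=np.int64)))
    acgt_cum = np.concatenate(([0], np.cumsum(acgt_mask, dtype=np.int64)))

    starts = np.arange(0, max(n - window, 0) + 1, step, dtype=np.int64)
    if len(starts) == 0:
        starts = np.array([0], dtype=np.int64)
    partial_last = False
    last_end = int(starts[-1]) + window
    if last_end < n:
        # trailing partial window, kept iff >= half a window long
        tail_start = int(starts[-1]) + step
        if n - tail_start >= (window + 1) // 2:
            starts = np.append(starts, tail_start)
            partial_last = True
    ends = np.minimum(starts + window, n)
    if ends[-1] - starts[-1] < window:
        partial_last = True

    gc_counts = gc_cum[ends] - gc_cum[starts]
    acgt_counts = acgt_cum[ends] - acgt_cum[starts]
    spans = ends - starts
    with np.errstate(invalid="ignore", divide="ignore"):
        values = 100.0 * gc_counts / acgt_counts
    non_acgt_frac = 1.0 - acgt_counts / spans
    values = np.where(non_acgt_frac > n_policy, np.nan, values)
    return GCProfile(
        chrom=chrom,
        window=window,
        step=step,
        window_starts=starts,
        window_ends=ends,
        values=values,
        weights=acgt_counts,
        partial_last=partial_last,
    )


@dataclass
class Isochore:
    """A genomic segment with mean GC and Bernardi family label."""

    chrom: str
    start: int
    end: int
    mean_gc: float
    family: str
    #: True when the segment was produced by absorbing sub-minimum
    #: segments, so individual windows may disagree with the label.
    merged: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def segment_isochores(
    profile: GCProfile,
    boundaries: FamilyBoundaries = FamilyBoundaries(),
    min_size: int = 200_000,
) -> List[Isochore]:
    """Segment a windowed GC profile into isochores.

    Consecutive windows with equal family labels are merged; segments
    shorter than ``min_size`` are then absorbed, smallest first, into the
    flanking neighbour whose mean GC is nearer (left neighbour on an exact
    tie), iterating until stable.  Mean GC is recomputed over the final
    segment (ACGT-base weighted) and the family label reassigned from the
    pooled mean.  Masked windows break segments; absorption never crosses
    a masked gap.
    """
    if profile.step != profile.window:
        raise ValueError(
            "segmentation requires a non-overlapping profile (step == window)"
        )
    values = profile.values
    if np.all(np.isnan(values)):
        warnings.warn("fully masked profile: no isochores", stacklevel=2)
        return []

    out: List[Isochore] = []
    # split into contiguous unmasked stretches
    good = ~np.isnan(values)
    idx = np.arange(len(values))
    breaks = np.where(np.diff(good.astype(int)) != 0)[0] + 1
    for block in np.split(idx, breaks):
        if len(block) == 0 or not good[block[0]]:
            continue
        out.extend(_segment_block(profile, block, boundaries, min_size))
    return out


def _segment_block(
    profile: GCProfile,
    block: np.ndarray,
    boundaries: FamilyBoundaries,
    min_size: int,
) -> List[Isochore]:
    gc = profile.values[block]
    w = profile.weights[block].astype(float)
    w = np.where(w > 0, w, 1.0)
    starts = profile.window_starts[block]
    ends = profile.window_ends[block]
    fams = np.searchsorted(np.asarray(boundaries.cutpoints), gc, side="right")

    # initial runs of equal family
    segs: List[dict] = []
    run_start = 0
    for k in range(1, len(block) + 1):
        if k == len(block) or fams[k] != fams[run_start]:
            sl = slice(run_start, k)
            segs.append(
                {
                    "start": int(starts[run_start]),
                    "end": int(ends[k - 1]),
                    "gc_sum": float(np.sum(gc[sl] * w[sl])),
                    "w_sum": float(np.sum(w[sl])),
                    "merged": False,
                }
            )
            run_start = k
    for s in segs:
        s["mean"] = s["gc_sum"] / s["w_sum"]
        s["fam"] = int(
            np.searchsorted(np.asarray(boundaries.cutpoints), s["mean"], side="right")
        )

    # absorb sub-minimum segments, smallest first, until stable
    changed = True
    while changed:
        changed = False
        small = [
            (s["end"] - s["start"], i)
            for i, s in enumerate(segs)
            if s["end"] - s["start"] < min_size and len(segs) > 1
        ]
        if not small:
            break
        _, i = min(small)
        s = segs[i]
        left = segs[i - 1] if i > 0 else None
        right = segs[i + 1] if i + 1 < len(segs) else None
        if left is None and right is None:
            break
        if left is None:
            target, j = right, i + 1
        elif right is None:
            target, j = left, i - 1
        else:
            dl = abs(left["mean"] - s["mean"])
            dr = abs(right["mean"] - s["mean"])
            target, j = (left, i - 1) if dl <= dr else (right, i + 1)
        lo, hi = (j, i) if j < i else (i, j)
        merged = {
            "start": segs[lo]["start"],
            "end": segs[hi]["end"],
            "gc_sum": segs[lo]["gc_sum"] + segs[hi]["gc_sum"],
            "w_sum": segs[lo]["w_sum"] + segs[hi]["w_sum"],
            "merged": True,
        }
        merged["mean"] = merged["gc_sum"] / merged["w_sum"]
        merged["fam"] = int(
            np.searchsorted(
                np.asarray(boundaries.cutpoints), merged["mean"], side="right"
            )
        )
        segs[lo : hi + 1] = [merged]
        segs = _coalesce_equal(segs, boundaries)
        changed = True

    return [
        Isochore(
            chrom=profile.chrom,
            start=s["start"],
            end=s["end"],
            mean_gc=s["mean"],
            family=FAMILIES[s["fam"]],
            merged=s["merged"],
        )
        for s in segs
    ]


def _coalesce_equal(segs: List[dict], boundaries: FamilyBoundaries) -> List[dict]:
    """Merge adjacent segments whose (re)assigned families are equal."""
    out = [segs[0]]
    for s in segs[1:]:
        if s["fam"] == out[-1]["fam"]:
            prev = out[-1]
            prev["end"] = s["end"]
            prev["gc_sum"] += s["gc_sum"]
            prev["w_sum"] += s["w_sum"]
            prev["mean"] = prev["gc_sum"] / prev["w_sum"]
            prev["fam"] = int(
                np.searchsorted(
                    np.asarray(boundaries.cutpoints), prev["mean"], side="right"
                )
            )
            prev["merged"] = True
        else:
            out.append(s)
    return out


def ctcf_density_by_family(
    sites: Dict[str, np.ndarray] | pd.DataFrame,
    isochores: Sequence[Isochore],
) -> pd.DataFrame:
    """Per-family CTCF site density (sites per Mb of family territory).

    Each site is assigned to the unique isochore containing it (half-open
    intervals); sites falling in no isochore are reported on an
    ``unassigned`` row with NaN density.
    """
    if isinstance(sites, pd.DataFrame):
        by_chrom = {
            c: np.sort(grp["pos"].to_numpy(dtype=np.int64))
            for c, grp in sites.groupby("chrom")
        }
    else:
        by_chrom = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in sites.items()}

    counts = {f: 0 for f in FAMILIES}
    bp = {f: 0 for f in FAMILIES}
    unassigned = 0
    iso_by_chrom: Dict[str, List[Isochore]] = {}
    for iso in isochores:
        iso_by_chrom.setdefault(iso.chrom, []).append(iso)
        bp[iso.family] += iso.length
    for chrom, isos in iso_by_chrom.items():
        isos = sorted(isos, key=lambda x: x.start)
        starts = np.array([i.start for i in isos])
        ends = np.array([i.end for i in isos])
        pos = by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        for k in np.nonzero(inside)[0]:
            counts[isos[idx[k]].family] += 1
        unassigned += int((~inside).sum())
    for chrom, pos in by_chrom.items():
        if chrom not in iso_by_chrom:
            unassigned += len(pos)

    rows = []
    for f in FAMILIES:
        mb = bp[f] / 1e6
        rows.append(
            {
                "family": f,
                "n_sites": counts[f],
                "mb_covered": mb,
                "density_per_mb": counts[f] / mb if mb > 0 else 0.0,
            }
        )
    rows.append(
        {
            "family": "unassigned",
            "n_sites": unassigned,
            "mb_covered": float("nan"),
            "density_per_mb": float("nan"),
        }
    )
    return pd.DataFrame(rows)


# -- FASTA / BED io ------------------------------------------------------

def write_fasta(genome: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    genome: Dict[str, List[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                genome[name] = []
            else:
                genome[name].append(line)
    return {k: "".join(v) for k, v in genome.items()}


def isochores_to_bed(isochores: Iterable[Isochore], path) -> None:
    """Write isochores as BED5: name=family, score=round(10·mean GC)."""
    with open(path, "w") as fh:
        for iso in isochores:
            fh.write(
                f"{iso.chrom}\t{iso.start}\t{iso.end}\t{iso.family}\t"
                f"{round(10 * iso.mean_gc)}\n"
            )


def isochores_from_bed(path) -> List[Isochore]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, fam, score = line.split()[:5]
            out.append(
                Isochore(chrom, int(start), int(end), float(score) / 10.0, fam)
            )
    return out


def isochores_to_dataframe(isochores: Iterable[Isochore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": i.chrom,
                "start": i.start,
                "end": i.end,
                "mean_gc": i.mean_gc,
                "family": i.family,
                "merged": i.merged,
            }
            for i in isochores
        ]
    )
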