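"""Synteny blocks from ortholog pair tables and cross-species GC conservation.

A synteny block is a maximal run of at least ``min_genes`` (default 3)
orthologs with conserved gene order on one chromosome (arm, when a
centromere table is supplied) in each species.  Descending order in the
second species counts as conserved (an inverted block); ``direct_only``
restores the strict reading.  Blocks are grown greedily over pairs sorted
by position in species A: a violation of single-chromosome/monotonic-order
closes the chain and opens a new one at the violating pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .isochores import Isochore

ORTHOLOG_COLUMNS = [
    "gene_a", "chrom_a", "start_a", "end_a",
    "gene_b", "chrom_b", "start_b", "end_b", "strand_b",
]


@dataclass
class SyntenyBlock:
    members: pd.DataFrame  # rows of the ortholog table, A-order
    chrom_a: str
    chrom_b: str
    orientation: str  # direct | inverted
    arm_b: str = "unknown"

    @property
    def n_genes(self) -> int:
        return len(self.members)

    @property
    def span_a(self) -> Tuple[int, int]:
        return int(self.members["start_a"].min()), int(self.members["end_a"].max())

    @property
    def span_b(self) -> Tuple[int, int]:
        return int(self.members["start_b"].min()), int(self.members["end_b"].max())

    @property
    def genes_a(self) -> Tuple[str, ...]:
        return tuple(self.members["gene_a"])


def _arm_of(pos: int, centromere: Optional[int]) -> str:
    if centromere is None:
        return "unknown"
    return "p" if pos < centromere else "q"


def build_synteny_blocks(
    pairs: pd.DataFrame,
    min_genes: int = 3,
    arms_b: Optional[Dict[str, int]] = None,
    direct_only: bool = False,
    max_gap: Optional[int] = None,
) -> List[SyntenyBlock]:
    """Chain an ortholog table into synteny blocks.

    Parameters
    ----------
    pairs : ortholog table with columns ``gene_a, chrom_a, start_a, end_a,
        gene_b, chrom_b, start_b, end_b, strand_b``; gene ids must be
        one-to-one.
    min_genes : minimum chain length emitted as a block (>= 2; the
        standard rule is at least 3 orthologs).
    arms_b : optional chromosome-B centromere positions; when given, a
        chain additionally may not cross an arm boundary in B.
    max_gap : optional maximum bp gap between consecutive members in B.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    for col in ("gene_a", "gene_b"):
        dup = pairs[col][pairs[col].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate {col} ids: {sorted(set(dup))}")

    blocks: List[SyntenyBlock] = []
    df = pairs.sort_values(["chrom_a", "start_a"], kind="mergesort").reset_index(
        drop=True
    )
    for _, sub in df.groupby("chrom_a", sort=False):
        blocks.extend(
            _chain_chromosome(
                sub.reset_index(drop=True), min_genes, arms_b, direct_only, max_gap
            )
        )
    return blocks


def _chain_chromosome(
    sub: pd.DataFrame,
    min_genes: int,
    arms_b: Optional[Dict[str, int]],
    direct_only: bool,
    max_gap: Optional[int],
) -> List[SyntenyBlock]:
    blocks: List[SyntenyBlock] = []
    chain: List[int] = []
    orientation = 0  # 0 undetermined, +1 direct, -1 inverted

    def flush() -> None:
        nonlocal chain, orientation
        if len(chain) >= min_genes:
            members = sub.iloc[chain].reset_index(drop=True)
            cen = arms_b.get(members["chrom_b"].iloc[0]) if arms_b else None
            blocks.append(
                SyntenyBlock(
                    members=members,
                    chrom_a=str(members["chrom_a"].iloc[0]),
                    chrom_b=str(members["chrom_b"].iloc[0]),
                    orientation="inverted" if orientation == -1 else "direct",
                    arm_b=_arm_of(int(members["start_b"].iloc[0]), cen),
                )
            )
        chain = []
        orientation = 0

    for i in range(len(sub)):
        row = sub.iloc[i]
        if not chain:
            chain = [i]
            continue
        prev = sub.iloc[chain[-1]]
        ok = row["chrom_b"] == prev["chrom_b"]
        if ok and arms_b is not None:
            cen = arms_b.get(row["chrom_b"])
            ok = _arm_of(int(row["start_b"]), cen) == _arm_of(
                int(prev["start_b"]), cen
            )
        if ok:
            step = int(row["start_b"]) - int(prev["start_b"])
            if step == 0:
                ok = False  # tied B positions break strict monotonicity
            elif orientation == 0:
                orientation = 1 if step > 0 else -1
                ok = not (direct_only and orientation == -1)
            else:
                ok = (step > 0) == (orientation == 1)
        if ok and max_gap is not None:
            gap = abs(int(row["start_b"]) - int(prev["end_b"])) if int(
                row["start_b"]
            ) >= int(prev["end_b"]) else abs(int(prev["start_b"]) - int(row["end_b"]))
            ok = gap <= max_gap
        if ok:
            chain.append(i)
        else:
            flush()
            chain = [i]
    flush()
    return blocks


def block_stats(blocks: Sequence[SyntenyBlock]) -> dict:
    """Count and span statistics (species A) of a block list."""
    if not blocks:
        return {"count": 0, "mean_span": None, "min_span": None, "max_span": None}
    spans = np.array([b.span_a[1] - b.span_a[0] for b in blocks], dtype=float)
    return {
        "count": len(blocks),
        "mean_span": float(spans.mean()),
        "min_span": float(spans.min()),
        "max_span": float(spans.max()),
    }


def blocks_to_dataframe(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    rows = []
    for k, b in enumerate(blocks):
        sa, sb = b.span_a, b.span_b
        rows.append(
            {
                "block_id": k,
                "chrom_a": b.chrom_a,
                "start_a": sa[0],
                "end_a": sa[1],
                "chrom_b": b.chrom_b,
                "start_b": sb[0],
                "end_b": sb[1],
                "orientation": b.orientation,
                "n_genes": b.n_genes,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b",
            "end_b", "orientation", "n_genes",
        ],
    )


@dataclass
class OrthologousIsochorePair:
    """A species-A isochore and its projection into species B."""

    isochore: Isochore
    chrom_b: str
    start_b: int
    end_b: int
    gc_a: float
    gc_b: float


def _project(
    a_lo: int, a_hi: int, span_a: Tuple[int, int], span_b: Tuple[int, int],
    inverted: bool,
) -> Tuple[int, int]:
    """Linear proportional mapping of an A-interval onto span_b.

    Relative position is preserved, mirrored for inverted blocks.
    """
    a0, a1 = span_a
    b0, b1 = span_b
    if a1 == a0:
        return b0, b1
    f_lo = (a_lo - a0) / (a1 - a0)
    f_hi = (a_hi - a0) / (a1 - a0)
    if inverted:
        f_lo, f_hi = 1.0 - f_hi, 1.0 - f_lo
    s = b0 + f_lo * (b1 - b0)
    e = b0 + f_hi * (b1 - b0)
    return int(round(s)), max(int(round(e)), int(round(s)) + 1)


def orthologous_isochores(
    blocks: Sequence[SyntenyBlock],
    isochores_a: Sequence[Isochore],
    gc_b: pd.DataFrame,
    min_overlap_fraction: float = 0.5,
) -> Tuple[List[OrthologousIsochorePair], int]:
    """Intersect isochores with synteny blocks and project into species B.

    Each isochore overlapping a block's A-span by at least
    ``min_overlap_fraction`` of the isochore yields one pair; the B region
    is the linear proportional image of the intersected interval (mirrored
    for inverted blocks).  ``gc_b`` maps species-B regions to GC: columns
    ``chrom_b, start_b, end_b, gc_b`` (e.g. per-gene GC from an ortholog
    simulation); the pair's gc_b is the mean over entries overlapping the
    projected region.  Returns (pairs, number of isochores excluded for
    insufficient block overlap).
    """
    pairs: List[OrthologousIsochorePair] = []
    excluded = 0
    by_chrom: Dict[str, List[SyntenyBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom_a, []).append(b)
    gc_by_chrom = {c: g.sort_values("start_b") for c, g in gc_b.groupby("chrom_b")}
    for iso in isochores_a:
        emitted = False
        for b in by_chrom.get(iso.chrom, []):
            sa = b.span_a
            lo, hi = max(iso.start, sa[0]), min(iso.end, sa[1])
            if hi - lo < min_overlap_fraction * iso.length:
                continue
            s_b, e_b = _project(lo, hi, sa, b.span_b, b.orientation == "inverted")
            g = gc_by_chrom.get(b.chrom_b)
            if g is None:
                continue
            hit = g[(g["start_b"] < e_b) & (g["end_b"] > s_b)]
            if len(hit) == 0:
                continue
            pairs.append(
                OrthologousIsochorePair(
                    isochore=iso,
                    chrom_b=b.chrom_b,
                    start_b=s_b,
                    end_b=e_b,
                    gc_a=iso.mean_gc,
                    gc_b=float(hit["gc_b"].mean()),
                )
            )
            emitted = True
        if not emitted:
            excluded += 1
    return pairs, excluded


def gc_correlation(gc_a, gc_b=None) -> dict:
    """Pearson and Spearman correlation of GC across species, with a
    Fisher-z 95% CI for Pearson's r.

    Accepts either two arrays or a list of OrthologousIsochorePair.
    """
    if gc_b is None:
        pairs = gc_a
        gc_a = np.array([p.gc_a for p in pairs], dtype=float)
        gc_b = np.array([p.gc_b for p in pairs], dtype=float)
    gc_a = np.asarray(gc_a, dtype=float)
    gc_b = np.asarray(gc_b, dtype=float)
    n = len(gc_a)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(gc_a) == 0 or np.std(gc_b) == 0:
        import warnings

        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return {"pearson_r": None, "spearman_rho": None, "n": n, "ci95": None}
    r, _ = stats.pearsonr(gc_a, gc_b)
    rho, _ = stats.spearmanr(gc_a, gc_b)
    if abs(r) < 1.0 and n > 3:
        zf = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(zf - 1.959964 * se)), float(np.tanh(zf + 1.959964 * se)))
    else:
        ci = (float(r), float(r))
    return {
        "pearson_r": float(r),
        "spearman_rho": float(rho),
        "n": int(n),
        "ci95": ci,
    }
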