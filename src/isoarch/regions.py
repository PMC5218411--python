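"""Genomic interval sets on 0-based half-open coordinates.

A :class:`RegionSet` is the unit the permutation machinery randomizes and
evaluates: a named collection of intervals on a genome with known
per-chromosome lengths, plus an optional mask of excluded territory.
Interval arithmetic is done on sorted numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Optional, Tuple

import numpy as np
import pandas as pd


def merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Union of a (n, 2) interval array: sorted, disjoint."""
    if len(iv) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def intersect_bp(a: np.ndarray, b: np.ndarray) -> int:
    """Total bp of intersection between two merged interval arrays."""
    if len(a) == 0 or len(b) == 0:
        return 0
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if e > s:
            total += int(e - s)
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return total


@dataclass
class RegionSet:
    """Named set of half-open intervals on a genome."""

    name: str
    genome: Dict[str, int]
    intervals: Dict[str, np.ndarray] = field(default_factory=dict)
    mask: Optional[Dict[str, np.ndarray]] = None
    #: optional per-interval scores aligned with sorted intervals (e.g. LAD
    #: contact frequencies); dict chrom -> float array.
    scores: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        clean = {}
        for chrom, iv in self.intervals.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            if len(iv):
                order = np.lexsort((iv[:, 1], iv[:, 0]))
                iv = iv[order]
                if self.scores is not None and chrom in self.scores:
                    self.scores[chrom] = np.asarray(self.scores[chrom])[order]
            clean[chrom] = iv
        self.intervals = clean
        self.validate()

    def validate(self) -> None:
        for chrom, iv in self.intervals.items():
            if chrom not in self.genome:
                raise ValueError(f"interval chromosome {chrom!r} not in genome")
            if len(iv) == 0:
                continue
            if np.any(iv[:, 0] < 0) or np.any(iv[:, 1] > self.genome[chrom]):
                raise ValueError(f"interval out of bounds on {chrom}")
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError(f"empty or inverted interval on {chrom}")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        genome: Dict[str, int],
        name: str = "regions",
        score_col: Optional[str] = None,
    ) -> "RegionSet":
        intervals: Dict[str, np.ndarray] = {}
        scores: Dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            intervals[chrom] = grp[["start", "end"]].to_numpy(dtype=np.int64)
            if score_col is not None:
                scores[chrom] = grp[score_col].to_numpy(dtype=float)
        return cls(
            name=name,
            genome=dict(genome),
            intervals=intervals,
            scores=scores if score_col is not None else None,
        )

    @classmethod
    def from_bed(
        cls, path, genome: Dict[str, int], name: Optional[str] = None
    ) -> "RegionSet":
        df = read_bed(path)
        score_col = "score" if "score" in df.columns else None
        return cls.from_dataframe(
            df, genome, name=name or str(path), score_col=score_col
        )

    # -- views ----------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom in self.intervals:
            iv = self.intervals[chrom]
            sc = self.scores.get(chrom) if self.scores else None
            for k, (s, e) in enumerate(iv):
                row = {"chrom": chrom, "start": int(s), "end": int(e)}
                if sc is not None:
                    row["score"] = float(sc[k])
                rows.append(row)
        cols = ["chrom", "start", "end"] + (["score"] if self.scores else [])
        return pd.DataFrame(rows, columns=cols)

    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for chrom, iv in self.intervals.items():
            for s, e in iv:
                yield chrom, int(s), int(e)

    def n_intervals(self) -> int:
        return sum(len(iv) for iv in self.intervals.values())

    def total_bp(self) -> int:
        """Total bp covered by the union of the set's intervals."""
        total = 0
        for iv in self.intervals.values():
            m = merge_intervals(iv)
            if len(m):
                total += int((m[:, 1] - m[:, 0]).sum())
        return total

    def merged(self, chrom: str) -> np.ndarray:
        return merge_intervals(self.intervals.get(chrom, np.empty((0, 2), np.int64)))

    def lengths(self, chrom: str) -> np.ndarray:
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return np.empty(0, dtype=np.int64)
        return iv[:, 1] - iv[:, 0]

    def mean_length(self) -> float:
        lens = np.concatenate(
            [self.lengths(c) for c in self.intervals] or [np.empty(0, np.int64)]
        )
        return float(lens.mean()) if len(lens) else float("nan")

    # -- io --------------------------------------------------------------
    def to_bed(self, path, name_col: Optional[Iterable[str]] = None) -> None:
        df = self.to_dataframe()
        out = df[["chrom", "start", "end"]].copy()
        out["name"] = list(name_col) if name_col is not None else self.name
        if "score" in df.columns:
            out["score"] = df["score"]
        out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3/4/5 file into a DataFrame (chrom, start, end[, name, score])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def read_genome_tsv(path) -> Dict[str, int]:
    """Read a two-column (chrom, length) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_genome_tsv(genome: Dict[str, int], path) -> None:
    pd.DataFrame(
        {"chrom": list(genome), "length": list(genome.values())}
    ).to_csv(path, sep="\t", header=False, index=False)
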