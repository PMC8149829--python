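"""Genomic interval primitives.

All coordinates are 0-based half-open (BED convention) throughout the
package; 1-based formats (GTF) are converted on read.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

VALID_STRANDS = frozenset({"+", "-", "unknown"})


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval: 0-based, half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


def validate_interval_frame(df: pd.DataFrame, name: str = "table") -> None:
    """Validate that a DataFrame with chrom/start/end columns holds legal intervals."""
    if df.empty:
        return
    bad = df.index[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        i = bad[0]
        raise ValueError(
            f"{name}: invalid interval at row {i}: "
            f"{df.loc[i, 'chrom']}:{df.loc[i, 'start']}-{df.loc[i, 'end']}"
        )


class IntervalIndex:
    """Per-chromosome interval trees over the rows of an interval DataFrame."""

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            tree = IntervalTree()
            for i, row in zip(sub.index, sub.itertuples(index=False)):
                tree.addi(int(row.start), int(row.end), i)
            self._trees[chrom] = tree

    def query(self, chrom: str, start: int, end: int) -> list[int]:
        """Row indices of intervals overlapping [start, end) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(start, end))

    def query_point(self, chrom: str, pos: int) -> list[int]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.at(pos))


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome.

    Touching intervals ([a,b) and [b,c)) are merged, matching bedtools
    merge default.
    """
    if df.empty:
        return df[["chrom", "start", "end"]].copy()
    out = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def brute_force_overlaps(
    a: pd.DataFrame, b: pd.DataFrame
) -> list[tuple[int, int]]:
    """O(n*m) overlap scan; the oracle the IntervalIndex is tested against."""
    pairs = []
    for i, ra in enumerate(a.itertuples(index=False)):
        for j, rb in enumerate(b.itertuples(index=False)):
            if ra.chrom == rb.chrom and ra.start < rb.end and rb.start < ra.end:
                pairs.append((i, j))
    return pairs
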