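"""Genomic interval primitives shared across the pipeline.

All coordinates are 0-based half-open internally (the BED dialect). GFF3
(1-based closed) is converted on read. Intervals are plain frozen dataclasses;
collections are thin wrappers around sorted lists so that results are
reproducible independent of input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    id: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


class IntervalSet:
    """A sorted collection of :class:`GenomicInterval` with a source label.

    May contain overlapping members unless an operation's contract says
    otherwise.
    """

    def __init__(
        self, intervals: Iterable[GenomicInterval] = (), source_label: str = ""
    ) -> None:
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.id)
        )
        self.source_label = source_label

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, source={self.source_label!r})"

    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def ids(self) -> list[str]:
        return [iv.id for iv in self.intervals]


def read_bed(path, source_label: str = "") -> IntervalSet:
    """Read a BED3+ file; column 4 (name), if present, becomes the id."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str}
        )
    except pd.errors.EmptyDataError:
        return IntervalSet([], source_label or str(path))
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >= 3 columns")
    ivs = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if df.shape[1] >= 4 else ""
        strand = str(row[5]) if df.shape[1] >= 6 and str(row[5]) in "+-" else "."
        ivs.append(
            GenomicInterval(str(row[0]), int(row[1]), int(row[2]), name, strand)
        )
    return IntervalSet(ivs, source_label or str(path))


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t{iv.strand}\n")


def merge_overlapping(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of spans: merge any overlapping (not merely abutting) intervals."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


def warn_if_disjoint_namespaces(a: IntervalSet, b: IntervalSet) -> bool:
    """Warn when two non-empty sets share no chromosome names."""
    if len(a) and len(b) and not (a.chroms() & b.chroms()):
        warnings.warn(
            f"no shared chromosome names between {a.source_label!r} and "
            f"{b.source_label!r}; results will be empty",
            stacklevel=3,
        )
        return True
    return False
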