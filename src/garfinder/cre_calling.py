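"""Candidate cis-regulatory element (CRE) derivation.

A candidate CRE is an open-chromatin (ATAC) peak that overlaps an active
enhancer mark (H3K27ac broad peak) by at least 1 bp, with any exon-overlapping
portion removed. The full ATAC peak extent is kept as the element (peaks are
the tested unit), and exon subtraction operates at region level: a peak split
by an internal exon yields several sub-peaks.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable

from .intervals import (
    GenomicInterval,
    IntervalSet,
    merge_overlapping,
    warn_if_disjoint_namespaces,
)

__all__ = ["intersect_peaks", "subtract_exons", "call_cres"]

DEFAULT_MIN_LEN = 10


def intersect_peaks(atac: IntervalSet, chip: IntervalSet) -> IntervalSet:
    """Keep ATAC peaks sharing >= 1 bp with any ChIP peak.

    Returns the full ATAC peak extents (not the overlap regions), ids
    preserved. A sweep over per-chromosome sorted lists; equivalent to a
    pairwise overlap check.
    """
    warn_if_disjoint_namespaces(atac, chip)
    chip_by_chrom = {c: merge_overlapping(ivs) for c, ivs in chip.by_chrom().items()}
    kept: list[GenomicInterval] = []
    for chrom, peaks in atac.by_chrom().items():
        marks = chip_by_chrom.get(chrom, [])
        j = 0
        for peak in peaks:  # both lists sorted by start
            while j < len(marks) and marks[j].end <= peak.start:
                j += 1
            k = j
            while k < len(marks) and marks[k].start < peak.end:
                if peak.overlaps(marks[k]):
                    kept.append(peak)
                    break
                k += 1
    return IntervalSet(kept, source_label="CRE")


def subtract_exons(
    peaks: IntervalSet, exons: IntervalSet, min_len: int = DEFAULT_MIN_LEN
) -> IntervalSet:
    """Remove exon-overlapping regions from peaks.

    Peaks fully inside exons are dropped; a peak broken by internal exons is
    split into pieces whose ids carry a ``.1``, ``.2`` ... suffix (a single
    surviving piece keeps the original id). Pieces shorter than ``min_len``
    after subtraction are discarded.
    """
    exon_by_chrom = {c: merge_overlapping(ivs) for c, ivs in exons.by_chrom().items()}
    out: list[GenomicInterval] = []
    for chrom, chrom_peaks in peaks.by_chrom().items():
        chrom_exons = exon_by_chrom.get(chrom, [])
        for peak in chrom_peaks:
            pieces = _subtract_one(peak, chrom_exons)
            pieces = [p for p in pieces if len(p) >= min_len]
            if len(pieces) == 1:
                out.append(replace(pieces[0], id=peak.id))
            else:
                for i, p in enumerate(pieces, start=1):
                    out.append(replace(p, id=f"{peak.id}.{i}" if peak.id else ""))
    return IntervalSet(out, source_label=peaks.source_label or "peaks")


def _subtract_one(
    peak: GenomicInterval, exons: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    pieces: list[GenomicInterval] = []
    cursor = peak.start
    for ex in exons:
        if ex.end <= cursor or ex.start >= peak.end:
            continue
        if ex.start > cursor:
            pieces.append(replace(peak, start=cursor, end=ex.start))
        cursor = max(cursor, ex.end)
    if cursor < peak.end:
        pieces.append(replace(peak, start=cursor, end=peak.end))
    return pieces


def call_cres(
    atac: IntervalSet,
    chip: IntervalSet,
    exons: IntervalSet | None = None,
    min_len: int = DEFAULT_MIN_LEN,
) -> IntervalSet:
    """Full CRE derivation: peak intersection then exon subtraction."""
    cres = intersect_peaks(atac, chip)
    if exons is not None and len(exons):
        cres = subtract_exons(cres, exons, min_len=min_len)
    return IntervalSet(cres, source_label="CRE")
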