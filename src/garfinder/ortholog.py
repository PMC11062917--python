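"""Synteny-anchored validation of candidate CRE orthologues.

A lifted-over candidate in a target species is accepted as the orthologue of
its reference element when, on at least one side (upstream or downstream),
the first flanking gene matches the reference's flanking gene on that same
side AND the target flank distance is no greater than ``max_ratio`` (default
4) times the reference distance. Cross-side matches are not accepted: flank
order encodes synteny, and a side swap implies an inversion.

Candidates that lift to more than one locus in a target genome (same element
id appearing twice) are rejected outright as multi-mappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "FlankContext",
    "OrthologyVerdict",
    "annotate_flanks",
    "validate_orthologue",
    "validate_candidates",
    "extract_sequences",
]

logger = logging.getLogger(__name__)

# When the reference flank distance is tiny the 4x rule collapses to ~0 bp;
# allow this much absolute slack instead (see docs/methods.md).
SMALL_DISTANCE_CUTOFF = 250
ABSOLUTE_SLACK = 1000


@dataclass(frozen=True)
class FlankContext:
    """Nearest non-overlapping gene on each side of an element."""

    element: GenomicInterval
    upstream_gene: str | None = None
    upstream_distance: int | None = None  # gap bp, 0 if abutting
    downstream_gene: str | None = None
    downstream_distance: int | None = None


@dataclass(frozen=True)
class OrthologyVerdict:
    accepted: bool
    matched_flank: str  # "upstream" | "downstream" | "none"
    reason: str

    def __post_init__(self) -> None:
        if self.accepted and self.matched_flank == "none":
            raise ValueError("accepted verdict must name a matched flank")


def annotate_flanks(element: GenomicInterval, genes: IntervalSet) -> FlankContext:
    """Find the nearest gene wholly left and wholly right of an element.

    Genes overlapping the element are excluded. Distances are edge-to-edge
    gap sizes. ``upstream`` means lower coordinates (left), irrespective of
    element strand — flank identity, not transcription direction, is what
    anchors synteny.
    """
    up_gene = up_d = down_gene = down_d = None
    for g in genes:
        if g.chrom != element.chrom or g.overlaps(element):
            continue
        if g.end <= element.start:  # wholly left
            d = element.start - g.end
            if up_d is None or d < up_d:
                up_gene, up_d = g.id, d
        elif g.start >= element.end:  # wholly right
            d = g.start - element.end
            if down_d is None or d < down_d:
                down_gene, down_d = g.id, d
    return FlankContext(element, up_gene, up_d, down_gene, down_d)


def _side_ok(
    ref_gene: str | None,
    ref_d: int | None,
    tgt_gene: str | None,
    tgt_d: int | None,
    max_ratio: float,
) -> tuple[bool, str]:
    if ref_gene is None or tgt_gene is None:
        return False, "missing_flank"
    if ref_gene != tgt_gene:
        return False, "gene_mismatch"
    limit = max_ratio * ref_d
    if ref_d < SMALL_DISTANCE_CUTOFF:
        limit = max(limit, ABSOLUTE_SLACK)
    if tgt_d <= limit:
        return True, "matched"
    return False, "distance_exceeded"


def validate_orthologue(
    ref: FlankContext, target: FlankContext, max_ratio: float = 4
) -> OrthologyVerdict:
    """Apply the two synteny rules; accept if either side satisfies both."""
    if target.upstream_gene is None and target.downstream_gene is None:
        return OrthologyVerdict(False, "none", "no_flanks")
    up_ok, up_reason = _side_ok(
        ref.upstream_gene, ref.upstream_distance,
        target.upstream_gene, target.upstream_distance, max_ratio,
    )
    if up_ok:
        return OrthologyVerdict(True, "upstream", "matched")
    down_ok, down_reason = _side_ok(
        ref.downstream_gene, ref.downstream_distance,
        target.downstream_gene, target.downstream_distance, max_ratio,
    )
    if down_ok:
        return OrthologyVerdict(True, "downstream", "matched")
    # prefer the more informative failure reason
    order = {"distance_exceeded": 0, "gene_mismatch": 1, "missing_flank": 2}
    reason = min((up_reason, down_reason), key=lambda r: order[r])
    return OrthologyVerdict(False, "none", reason)


def validate_candidates(
    ref_contexts: Mapping[str, FlankContext],
    target_candidates: Iterable[GenomicInterval],
    target_genes: IntervalSet,
    max_ratio: float = 4,
) -> dict[str, tuple[GenomicInterval | None, OrthologyVerdict]]:
    """Validate one target species' lifted candidates against the reference.

    ``ref_contexts`` maps element id -> reference FlankContext. Returns, per
    candidate element id, the accepted interval (or None) and a verdict.
    Element ids appearing more than once among the candidates are rejected as
    multi-mappers.
    """
    by_id: dict[str, list[GenomicInterval]] = {}
    for c in target_candidates:
        by_id.setdefault(c.id, []).append(c)
    out: dict[str, tuple[GenomicInterval | None, OrthologyVerdict]] = {}
    for eid, cands in by_id.items():
        if eid not in ref_contexts:
            out[eid] = (None, OrthologyVerdict(False, "none", "unknown_element"))
            continue
        if len(cands) > 1:
            out[eid] = (None, OrthologyVerdict(False, "none", "multi_mapping"))
            continue
        tgt_ctx = annotate_flanks(cands[0], target_genes)
        verdict = validate_orthologue(ref_contexts[eid], tgt_ctx, max_ratio)
        out[eid] = (cands[0] if verdict.accepted else None, verdict)
    return out


def extract_sequences(
    elements: Mapping[str, Iterable[tuple[str, GenomicInterval]]],
    genomes: Mapping[str, Mapping[str, str]],
) -> dict[str, dict[str, str]]:
    """Extract per-species element sequences from genome sequences.

    ``elements``: element id -> iterable of (species, interval).
    ``genomes``: species -> mapping chrom -> sequence (a dict, a pyfaidx
    ``Fasta``, or anything with ``[chrom][start:end]`` string access).

    Returns element id -> {species: sequence}, reverse-complementing minus
    strand intervals. Out-of-bounds intervals and unknown chromosomes are
    skipped with a logged warning.
    """
    out: dict[str, dict[str, str]] = {}
    for eid, records in elements.items():
        for species, iv in records:
            genome = genomes.get(species)
            if genome is None or iv.chrom not in _keys(genome):
                logger.warning("%s/%s: chromosome %s missing; skipped", eid, species, iv.chrom)
                continue
            chrom_seq = genome[iv.chrom]
            if iv.end > len(chrom_seq):
                logger.warning(
                    "%s/%s: %s:%d-%d out of bounds (len %d); skipped",
                    eid, species, iv.chrom, iv.start, iv.end, len(chrom_seq),
                )
                continue
            seq = str(chrom_seq[iv.start : iv.end]).upper()
            if iv.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            out.setdefault(eid, {})[species] = seq
    return out


def _keys(genome) -> Iterable[str]:
    try:
        return genome.keys()
    except AttributeError:  # pyfaidx.Fasta
        return [rec.name for rec in genome]
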