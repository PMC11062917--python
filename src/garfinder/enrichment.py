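"""Contact-domain-based enhancer-gene assignment and GAR enrichment.

Contact domains (TADs) called at several resolutions are merged so that
identical or fully nested calls collapse to the outermost span while partial
overlaps are retained; each candidate CRE is then assigned to the nearest
gene TSS, either restricted to TSSs sharing a merged domain (domain mode) or
unrestricted (distance mode). Per-gene GAR excess is scored with a one-tailed
hypergeometric test (domain mode default) or a binomial test (distance mode
default), and gene-set overlaps with a hypergeometric tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .gff import GeneModel
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "TssAnnotation",
    "EnrichmentResult",
    "merge_contact_domains",
    "annotate_tss",
    "assign_cres",
    "gene_gar_enrichment",
    "overlap_test",
    "domain_size_diagnostic",
]


@dataclass(frozen=True)
class TssAnnotation:
    gene_id: str
    chrom: str
    tss_position: int
    strand: str
    rule_used: str  # "utr_1bp" | "atg_1kb"


@dataclass(frozen=True)
class EnrichmentResult:
    gene_id: str
    n_assigned: int
    k_gar: int
    p_value: float
    model_used: str
    significant: bool


def merge_contact_domains(
    call_sets: list[IntervalSet] | IntervalSet,
) -> IntervalSet:
    """Collapse identical/nested domains to the outermost span.

    Partially overlapping and disjoint domains are retained as distinct
    records. The output is containment-free; applying the merge twice is a
    no-op.
    """
    if isinstance(call_sets, IntervalSet):
        call_sets = [call_sets]
    pool = [iv for s in call_sets for iv in s]
    kept: list[GenomicInterval] = []
    # start asc, end desc: an interval is contained in an earlier kept one
    # iff its end does not exceed the running max end on its chromosome
    max_end: dict[str, int] = {}
    for iv in sorted(pool, key=lambda x: (x.chrom, x.start, -x.end)):
        if iv.end > max_end.get(iv.chrom, -1):
            kept.append(iv)
            max_end[iv.chrom] = iv.end
    return IntervalSet(kept, source_label="merged_domains")


def annotate_tss(
    genes: list[GeneModel],
    genome: dict[str, str],
    atg_offset: int = 1000,
) -> list[TssAnnotation]:
    """TSS per gene from its longest transcript's first exon.

    A first exon beginning with ATG is taken as coding from base one, so the
    true TSS is estimated ~1 kb upstream of the translation start; otherwise
    the exon is a 5' UTR and the TSS sits 1 bp upstream of it. Strand-aware;
    positions clipped to the chromosome.
    """
    out = []
    for g in genes:
        tx = g.longest_transcript()
        first = tx.exons[0] if tx.strand != "-" else tx.exons[-1]
        chrom_seq = genome.get(first.chrom)
        chrom_len = len(chrom_seq) if chrom_seq is not None else None
        starts_atg, rule = False, "utr_1bp"
        if len(first) < 3:
            warnings.warn(
                f"{g.gene_id}: first exon shorter than 3 bp; using 1 bp-upstream rule"
            )
        elif chrom_seq is not None:
            if tx.strand == "-":
                codon = str(
                    Seq(str(chrom_seq[first.end - 3 : first.end])).reverse_complement()
                ).upper()
            else:
                codon = str(chrom_seq[first.start : first.start + 3]).upper()
            starts_atg = codon == "ATG"
        if starts_atg:
            rule = "atg_1kb"
            tss = first.start - atg_offset if tx.strand != "-" else first.end + atg_offset
        else:
            tss = first.start - 1 if tx.strand != "-" else first.end + 1
        tss = max(0, tss)
        if chrom_len is not None:
            tss = min(tss, chrom_len - 1)
        out.append(TssAnnotation(g.gene_id, first.chrom, tss, tx.strand, rule))
    return out


def _domains_containing(pos: int, chrom: str, domains: IntervalSet) -> frozenset[int]:
    return frozenset(
        i
        for i, d in enumerate(domains)
        if d.chrom == chrom and d.start <= pos < d.end
    )


def assign_cres(
    cres: IntervalSet,
    tss_set: list[TssAnnotation],
    domains: IntervalSet | None = None,
    mode: str = "domain",
) -> pd.DataFrame:
    """Assign each CRE to at most one gene: the nearest TSS by midpoint.

    In domain mode a CRE (located by its midpoint) may only link to TSSs
    inside a shared merged domain; CREs outside all domains or in TSS-free
    domains stay unassigned. Ties go to the leftmost TSS, then lexicographic
    gene id.

    Returns a table with one row per CRE: element_id, chrom, start, end,
    gene_id (empty if unassigned), distance, n_candidates.
    """
    if mode not in ("domain", "distance"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "domain" and domains is None:
        raise ValueError("domain mode requires merged domains")
    tss_dom: list[frozenset[int]] = []
    if mode == "domain":
        tss_dom = [
            _domains_containing(t.tss_position, t.chrom, domains) for t in tss_set
        ]
    rows = []
    for cre in cres:
        mid = cre.midpoint
        candidates = []
        if mode == "domain":
            cre_dom = _domains_containing(int(mid), cre.chrom, domains)
            idxs = [
                i
                for i, t in enumerate(tss_set)
                if t.chrom == cre.chrom and cre_dom and (cre_dom & tss_dom[i])
            ]
        else:
            idxs = [i for i, t in enumerate(tss_set) if t.chrom == cre.chrom]
        for i in idxs:
            t = tss_set[i]
            candidates.append((abs(mid - t.tss_position), t.tss_position, t.gene_id))
        if candidates:
            dist, _, gene = min(candidates)
            rows.append((cre.id, cre.chrom, cre.start, cre.end, gene, dist, len(candidates)))
        else:
            rows.append((cre.id, cre.chrom, cre.start, cre.end, "", np.nan, 0))
    return pd.DataFrame(
        rows,
        columns=["element_id", "chrom", "start", "end", "gene_id", "distance", "n_candidates"],
    )


def gene_gar_enrichment(
    assignments: pd.DataFrame,
    gar_ids: set[str],
    model: str = "hypergeometric",
    alpha: float = 0.05,
    correction: str = "none",
) -> list[EnrichmentResult]:
    """Per-gene one-tailed test for excess GARs among assigned CREs.

    N = all assigned CREs in the run, K = GARs among them; a gene with n
    assigned CREs of which k are GARs gets p = P(X >= k) under
    Hypergeom(N, K, n) or Binom(n, K/N). Genes with n = 0 are not tested.
    """
    if model not in ("hypergeometric", "binomial"):
        raise ValueError(f"unknown model {model!r}")
    assigned = assignments[assignments["gene_id"] != ""]
    N = len(assigned)
    K = int(assigned["element_id"].isin(gar_ids).sum())
    if N and K == 0:
        warnings.warn("no GARs among assigned CREs; all enrichment p-values are 1")
    out: list[EnrichmentResult] = []
    pvals: list[float] = []
    for gene, sub in assigned.groupby("gene_id"):
        n = len(sub)
        k = int(sub["element_id"].isin(gar_ids).sum())
        if K == 0:
            p = 1.0
        elif model == "hypergeometric":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            p = float(stats.binom.sf(k - 1, n, K / N))
        p = min(p, 1.0)
        out.append(EnrichmentResult(gene, n, k, p, model, False))
        pvals.append(p)
    if not out:
        return out
    if correction == "BH":
        adj = stats.false_discovery_control(np.array(pvals), method="bh")
    elif correction == "none":
        adj = np.array(pvals)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    final = [
        EnrichmentResult(r.gene_id, r.n_assigned, r.k_gar, r.p_value, r.model_used, bool(a < alpha))
        for r, a in zip(out, adj)
    ]
    final.sort(key=lambda r: (r.p_value, r.gene_id))
    return final


def overlap_test(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[float, int, list[str]]:
    """Hypergeometric tail test for the overlap of two gene sets.

    p = P(X >= |A & B|) with X ~ Hypergeom(|U|, |A|, |B|). Members outside
    the universe are rejected.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    overlap = sorted(set_a & set_b)
    p = float(stats.hypergeom.sf(len(overlap) - 1, len(universe), len(set_a), len(set_b)))
    return min(p, 1.0), len(overlap), overlap


def domain_size_diagnostic(
    domains: IntervalSet, assignments: pd.DataFrame
) -> tuple[pd.DataFrame, float | None]:
    """Per-domain size vs number of assigned CREs, with R² of a linear fit.

    A sanity check that domain size does not drive enhancer counts. With
    fewer than 3 domains R² is undefined (returned as None).
    """
    counts = []
    assigned = assignments[assignments["gene_id"] != ""]
    mids = (assigned["start"] + assigned["end"]) / 2.0
    for d in domains:
        inside = (
            (assigned["chrom"] == d.chrom) & (mids >= d.start) & (mids < d.end)
        ).sum()
        counts.append((d.chrom, d.start, d.end, len(d), int(inside)))
    table = pd.DataFrame(counts, columns=["chrom", "start", "end", "size_bp", "n_cres"])
    if len(table) < 3 or table["size_bp"].nunique() < 2:
        return table, None
    if table["n_cres"].nunique() < 2:
        return table, 0.0  # constant counts: flat fit explains nothing
    fit = stats.linregress(table["size_bp"], table["n_cres"])
    return table, float(fit.rvalue**2)
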