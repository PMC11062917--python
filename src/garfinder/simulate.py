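"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a 17-taxon
tree containing three independent glider lineages (each with a non-gliding
sister) and two outgroup groups; element sequences evolved under the neutral
GTR model with configurable per-branch rate multipliers (planted
acceleration); and a synthetic regulatory genome — genes with multi-exon
transcripts, contact domains called at three resolutions, ATAC/ChIP peak
sets, and differentially-expressed gene lists — including one "planted" gene
whose assigned CREs carry an excess of accelerated elements.

Species names are fictional placeholders; only the role structure (glider /
sister / outgroup groups) mirrors the real study design. All randomness
flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gff import GeneModel, Transcript, write_gff3
from .intervals import GenomicInterval, IntervalSet, write_bed
from .msa import OrthologueAlignment, SpeciesRoles, write_fasta
from .phylo.model import PhyloModel
from .phylo.tree import Phylogeny

__all__ = [
    "DEFAULT_TREE_NEWICK",
    "default_roles",
    "default_model",
    "SimulationConfig",
    "simulate_element",
    "simulate_alignments",
    "SyntheticGenome",
    "simulate_regulatory_genome",
    "simulate_peaksets",
    "simulate_liftover",
]

BASES = "ACGT"

# 17 tips: three glider/sister pairs inside a petauroid-like radiation,
# assorted non-gliding relatives, and two outgroup groups. Branch lengths
# are expected substitutions/site at neutral (fourfold-degenerate) sites.
DEFAULT_TREE_NEWICK = (
    "((((glider1:0.030,sister1:0.032):0.025,(poss1:0.040,poss2:0.038):0.020)"
    ":0.015,((glider2:0.045,sister2:0.047):0.030,((glider3:0.035,sister3:0.033)"
    ":0.020,(ring1:0.025,(ring2:0.022,ring3:0.024):0.012):0.018):0.012):0.010)"
    ":0.030,((poss3:0.050,poss4:0.052):0.025,((outA1:0.030,outA2:0.032):0.060,"
    "(outB1:0.045,outB2:0.047):0.055):0.020):0.012);"
)

REFERENCE_SPECIES = "glider1"
GLIDERS = ("glider1", "glider2", "glider3")


def default_roles() -> SpeciesRoles:
    return SpeciesRoles(
        pairs=(("glider1", "sister1"), ("glider2", "sister2"), ("glider3", "sister3")),
        outgroup_groups={"outA": ("outA1", "outA2"), "outB": ("outB1", "outB2")},
    )


def default_model(tree_newick: str = DEFAULT_TREE_NEWICK) -> PhyloModel:
    """Neutral GTR with a transition/transversion bias and AT-rich freqs."""
    return PhyloModel(
        Phylogeny.from_newick(tree_newick),
        exchangeabilities=np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0]),
        base_freqs=np.array([0.30, 0.20, 0.20, 0.30]),
        label="synthetic_neutral",
    )


@dataclass
class SimulationConfig:
    """Everything that determines a simulated element cohort."""

    model: PhyloModel = field(default_factory=default_model)
    n_elements: int = 100
    element_length: int = 300
    accel_spec: dict[str, tuple[str, float]] = field(default_factory=dict)
    indel_rate: float = 0.0  # events per site per unit branch length
    indel_mean_length: int = 3
    reference: str = REFERENCE_SPECIES
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _sample_transitions(
    parent: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent.size)
    child = np.empty_like(parent)
    for s in range(4):
        mask = parent == s
        if mask.any():
            child[mask] = np.searchsorted(cum[s], u[mask], side="right")
    return np.minimum(child, 3)


def simulate_element(
    config: SimulationConfig,
    element_id: str,
    rng: np.random.Generator | None = None,
    species_subset: set[str] | None = None,
) -> tuple[OrthologueAlignment, dict]:
    """Evolve one element down the tree; returns the true alignment + truth.

    The root sequence is drawn from the stationary frequencies; each branch
    applies the GTR transition matrix for its (possibly rho-scaled) length.
    With ``indel_rate`` > 0, insertion/deletion events (geometric lengths)
    produce gap columns in the true alignment.
    """
    rng = config.rng() if rng is None else rng
    model = config.model
    tree = model.tree
    eig = model.eigen
    L = config.element_length
    accel = config.accel_spec.get(element_id)
    fg_node = tree.terminal_edge(accel[0]) if accel else -1
    rho = accel[1] if accel else 1.0

    columns: list[int] = list(range(L))
    next_id = [L]
    root_seq = rng.choice(4, size=L, p=model.base_freqs)
    # node sequences as (column id, base) lists, built root -> tips
    seqs: dict[int, list[tuple[int, int]]] = {
        tree.root: list(zip(columns, root_seq.tolist()))
    }
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in tree.children[node]:
            t = tree.branch_lengths[child] * (rho if child == fg_node else 1.0)
            parent_pairs = seqs[node]
            ids = [c for c, _ in parent_pairs]
            bases = np.array([b for _, b in parent_pairs], dtype=np.int64)
            if bases.size:
                P = eig.transition_matrices(np.array([t]))[0]
                bases = _sample_transitions(bases, P, rng)
            pairs = list(zip(ids, bases.tolist()))
            if config.indel_rate > 0.0 and pairs:
                pairs = _apply_indels(
                    pairs, t, config, columns, next_id, rng, model.base_freqs
                )
            seqs[child] = pairs
            stack.append(child)
    col_pos = {c: i for i, c in enumerate(columns)}
    n_cols = len(columns)
    rows: dict[str, str] = {}
    wanted = species_subset if species_subset is not None else set(tree.tip_names)
    for name, node in tree.tip_index.items():
        if name not in wanted:
            continue
        row = ["-"] * n_cols
        for c, b in seqs[node]:
            row[col_pos[c]] = BASES[b]
        rows[name] = "".join(row)
    # drop columns gapped in every retained row (lineage-private insertions)
    keep = [
        i for i in range(n_cols) if any(r[i] != "-" for r in rows.values())
    ]
    if len(keep) < n_cols:
        rows = {sp: "".join(r[i] for i in keep) for sp, r in rows.items()}
    ref = config.reference if config.reference in rows else sorted(rows)[0]
    msa = OrthologueAlignment(element_id, rows, ref)
    truth = {
        "element_id": element_id,
        "accelerated": accel is not None,
        "foreground": accel[0] if accel else None,
        "rho": rho,
    }
    return msa, truth


def _apply_indels(pairs, t, config, columns, next_id, rng, freqs):
    n_events = rng.poisson(config.indel_rate * t * len(pairs))
    for _ in range(n_events):
        if not pairs:
            break
        length = 1 + rng.geometric(1.0 / config.indel_mean_length)
        pos = int(rng.integers(0, len(pairs)))
        if rng.random() < 0.5:  # deletion
            del pairs[pos : pos + length]
        else:  # insertion after pos
            anchor = pairs[pos][0]
            new_ids = list(range(next_id[0], next_id[0] + length))
            next_id[0] += length
            at = columns.index(anchor) + 1
            columns[at:at] = new_ids
            new_bases = rng.choice(4, size=length, p=freqs)
            pairs[pos + 1 : pos + 1] = list(zip(new_ids, new_bases.tolist()))
    return pairs


def simulate_alignments(
    config: SimulationConfig,
    element_ids: list[str] | None = None,
    species_per_element: dict[str, set[str]] | None = None,
) -> tuple[dict[str, OrthologueAlignment], pd.DataFrame]:
    """Simulate the whole cohort deterministically under the config seed."""
    rng = config.rng()
    ids = element_ids or [f"cre_{i:05d}" for i in range(config.n_elements)]
    alignments: dict[str, OrthologueAlignment] = {}
    truths = []
    for eid in ids:
        subset = species_per_element.get(eid) if species_per_element else None
        msa, truth = simulate_element(config, eid, rng=rng, species_subset=subset)
        alignments[eid] = msa
        truths.append(truth)
    return alignments, pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# synthetic regulatory genome
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenome:
    """A small reference genome with annotations and planted ground truth."""

    chrom: str
    sequence: str
    genes: list[GeneModel]
    domain_call_sets: dict[str, IntervalSet]
    true_domains: IntervalSet
    cre_truth: IntervalSet
    accel_spec: dict[str, tuple[str, float]]
    planted_gene: str
    planted_cres: list[str]
    de_genes: list[str]
    seed: int

    @property
    def genome(self) -> dict[str, str]:
        return {self.chrom: self.sequence}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta({self.chrom: self.sequence}, outdir / "genome.fa")
        write_gff3(self.genes, outdir / "genes.gff3")
        write_bed(self.cre_truth, outdir / "cre_truth.bed")
        for label, s in self.domain_call_sets.items():
            write_bed(s, outdir / f"domains_{label}.bed")
        pd.DataFrame({"gene_id": self.de_genes}).to_csv(
            outdir / "de_genes.tsv", sep="\t", index=False
        )
        truth = {
            "seed": self.seed,
            "planted_gene": self.planted_gene,
            "planted_cres": self.planted_cres,
            "accel_spec": {k: list(v) for k, v in self.accel_spec.items()},
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))


def simulate_regulatory_genome(
    n_domains: int = 25,
    genes_per_domain: tuple[int, int] = (1, 3),
    cres_per_domain: tuple[int, int] = (2, 7),
    cre_length: int = 300,
    n_planted_cres: int = 12,
    n_planted_accelerated: int = 10,
    background_accel_frac: float = 0.05,
    accel_rho: float = 8.0,
    accel_foreground: str = "glider1",
    n_de_genes: int = 8,
    seed: int = 0,
    base_freqs: np.ndarray | None = None,
) -> SyntheticGenome:
    """Build the synthetic reference genome with one GAR-enriched gene.

    Domains tile one chromosome; each hosts a few multi-exon genes (mixing
    ATG-initial and UTR-initial first exons) and intergenic CREs. One gene is
    "planted": it receives ``n_planted_cres`` nearby CREs of which
    ``n_planted_accelerated`` are marked accelerated, against a
    ``background_accel_frac`` genome-wide rate. DE lists include the planted
    gene.
    """
    rng = np.random.default_rng(seed)
    freqs = base_freqs if base_freqs is not None else np.array([0.3, 0.2, 0.2, 0.3])
    chrom = "chr1"
    dom_sizes = rng.integers(40_000, 100_000, size=n_domains)
    gap_sizes = rng.integers(2_000, 10_000, size=n_domains)
    domains, cursor = [], 10_000
    for i in range(n_domains):
        domains.append(GenomicInterval(chrom, cursor, cursor + int(dom_sizes[i]), f"dom_{i:03d}"))
        cursor += int(dom_sizes[i]) + int(gap_sizes[i])
    genome_len = cursor + 10_000
    seq = rng.choice(list(BASES), size=genome_len, p=freqs)

    genes: list[GeneModel] = []
    cres: list[GenomicInterval] = []
    planted_cre_ids: list[str] = []
    accel_spec: dict[str, tuple[str, float]] = {}
    planted_domain = int(rng.integers(0, n_domains))
    planted_gene_id = ""
    cre_counter = 0

    for di, dom in enumerate(domains):
        n_genes = int(rng.integers(genes_per_domain[0], genes_per_domain[1] + 1))
        if di == planted_domain:
            n_genes = 1  # planted domain: all its CREs assign to one gene
        # genes occupy the left half of the domain, CREs the right half
        gene_zone_hi = dom.start + (dom.end - dom.start) // 2
        slots = np.sort(rng.choice(
            np.arange(dom.start + 2_000, gene_zone_hi, 6_000), size=n_genes, replace=False
        ))
        occupied: list[GenomicInterval] = []
        for gi, gstart in enumerate(slots):
            gid = f"gene_{di:03d}_{gi}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            exons, pos = [], int(gstart)
            for _ in range(n_exons):
                elen = int(rng.integers(100, 400))
                exons.append(GenomicInterval(chrom, pos, pos + elen, strand=strand))
                pos += elen + int(rng.integers(200, 800))
            tx = Transcript(f"{gid}.t1", strand, exons)
            genes.append(GeneModel(gid, [tx]))
            occupied.append(GenomicInterval(chrom, exons[0].start, exons[-1].end))
            # make the first exon (transcript orientation) ATG- or UTR-initial
            first = exons[0] if strand == "+" else exons[-1]
            codon = "ATG" if rng.random() < 0.5 else "GCT"
            if strand == "+":
                seq[first.start : first.start + 3] = list(codon)
            else:
                comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
                rc = "".join(comp[b] for b in reversed(codon))
                seq[first.end - 3 : first.end] = list(rc)
            if di == planted_domain and not planted_gene_id:
                planted_gene_id = gid
        gene_zone_end = max(o.end for o in occupied) if occupied else dom.start
        free_lo, free_hi = gene_zone_end + 1_000, dom.end - cre_length - 100
        if free_hi <= free_lo:
            continue
        n_cres = int(rng.integers(cres_per_domain[0], cres_per_domain[1] + 1))
        if di == planted_domain:
            n_cres = max(n_cres, n_planted_cres)
        starts = np.sort(rng.choice(
            np.arange(free_lo, free_hi, cre_length + 50), size=min(n_cres, max(1, (free_hi - free_lo) // (cre_length + 50))), replace=False
        ))
        for s in starts:
            eid = f"cre_{cre_counter:05d}"
            cre_counter += 1
            cres.append(GenomicInterval(chrom, int(s), int(s) + cre_length, eid))
            if di == planted_domain and len(planted_cre_ids) < n_planted_cres:
                planted_cre_ids.append(eid)
            elif rng.random() < background_accel_frac:
                fg = accel_foreground if rng.random() < 0.5 else GLIDERS[int(rng.integers(0, 3))]
                accel_spec[eid] = (fg, accel_rho)
    for eid in planted_cre_ids[:n_planted_accelerated]:
        accel_spec[eid] = (accel_foreground, accel_rho)

    true_domains = IntervalSet(domains, "domains")
    call_sets = _derive_call_sets(domains, rng)
    other_genes = [g.gene_id for g in genes if g.gene_id != planted_gene_id]
    de_pick = rng.choice(other_genes, size=min(n_de_genes - 1, len(other_genes)), replace=False)
    de_genes = sorted([planted_gene_id, *de_pick.tolist()])
    return SyntheticGenome(
        chrom, "".join(seq.tolist()), genes, call_sets, true_domains,
        IntervalSet(cres, "cre_truth"), accel_spec, planted_gene_id,
        planted_cre_ids, de_genes, seed,
    )


def _derive_call_sets(
    domains: list[GenomicInterval], rng: np.random.Generator
) -> dict[str, IntervalSet]:
    """Three resolution-labelled call sets: base, nested/duplicate, shifted."""
    set_10kb = list(domains)
    set_25kb = []
    for d in domains:
        if rng.random() < 0.5:  # duplicate call
            set_25kb.append(d)
        if rng.random() < 0.5 and len(d) > 20_000:  # fully nested call
            off = int(rng.integers(1_000, 5_000))
            set_25kb.append(
                GenomicInterval(d.chrom, d.start + off, d.end - off, d.id + "_nested")
            )
    set_50kb = []
    for a, b in zip(domains[:-1], domains[1:]):
        if a.chrom == b.chrom and rng.random() < 0.3:  # partial overlap spanning the gap
            set_50kb.append(
                GenomicInterval(a.chrom, (a.start + a.end) // 2, b.start + 5_000, a.id + "_span")
            )
    return {
        "10kb": IntervalSet(set_10kb, "10kb"),
        "25kb": IntervalSet(set_25kb, "25kb"),
        "50kb": IntervalSet(set_50kb, "50kb"),
    }


def simulate_peaksets(
    cre_truth: IntervalSet,
    chrom_length: int,
    jitter: int = 0,
    n_decoys: int = 0,
    chip_cover_frac: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[IntervalSet, IntervalSet]:
    """ATAC and H3K27ac peak sets around the truth CREs.

    ATAC peaks are the truth CREs (ids preserved) jittered by up to
    ``jitter`` bp per edge, plus decoy peaks with no ChIP support; ChIP broad
    peaks cover ``chip_cover_frac`` of the truth CREs, so CRE calling should
    recover exactly the covered subset.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    atac, chip = [], []
    cres = list(cre_truth)
    covered = rng.random(len(cres)) < chip_cover_frac
    for i, cre in enumerate(cres):
        j1 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        j2 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        start = max(0, cre.start + j1)
        end = min(chrom_length, max(start + 50, cre.end + j2))
        atac.append(GenomicInterval(cre.chrom, start, end, cre.id))
        if covered[i]:
            # broad-peak padding must not bleed onto neighbouring CREs, so
            # covered/uncovered status maps 1:1 onto recovered elements
            pad = int(rng.integers(50, 400))
            pad_l, pad_r = pad, pad
            if i > 0 and cres[i - 1].chrom == cre.chrom:
                pad_l = min(pad_l, max(0, cre.start - cres[i - 1].end - 1 - jitter))
            if i + 1 < len(cres) and cres[i + 1].chrom == cre.chrom:
                pad_r = min(pad_r, max(0, cres[i + 1].start - cre.end - 1 - jitter))
            chip.append(
                GenomicInterval(
                    cre.chrom, max(0, cre.start - pad_l),
                    min(chrom_length, cre.end + pad_r), f"chip_{i:05d}",
                )
            )
    occupied = sorted((iv.start, iv.end) for iv in atac)
    for k in range(n_decoys):
        for _ in range(50):  # rejection-sample a free slot
            s = int(rng.integers(0, chrom_length - 400))
            if all(e <= s or b >= s + 300 for b, e in occupied):
                atac.append(GenomicInterval(cre_truth.intervals[0].chrom if len(cre_truth) else "chr1", s, s + 300, f"decoy_{k:04d}"))
                break
    return IntervalSet(atac, "ATAC"), IntervalSet(chip, "H3K27ac")


def simulate_liftover(
    genome: SyntheticGenome,
    species: list[str],
    frac_fail: float = 0.05,
    rng: np.random.Generator | None = None,
) -> dict[str, dict]:
    """Per-target-species lifted candidates and gene annotations.

    Each target genome is the reference with a species-specific coordinate
    scale and jitter (synteny preserved); a ``frac_fail`` fraction of
    candidates is corrupted (moved far from its flanking genes) so the
    synteny check has something to reject.
    """
    rng = np.random.default_rng(1) if rng is None else rng
    out: dict[str, dict] = {}
    for sp in species:
        scale = float(rng.uniform(0.92, 1.12))
        genes = IntervalSet(
            [
                GenomicInterval(
                    g.chrom,
                    int(g.start * scale),
                    max(int(g.start * scale) + 1, int(g.end * scale)),
                    g.gene_id,
                    g.strand,
                )
                for g in genome.genes
            ],
            f"{sp}_genes",
        )
        candidates = []
        for cre in genome.cre_truth:
            s = int(cre.start * scale) + int(rng.integers(-200, 201))
            e = s + len(cre)
            if rng.random() < frac_fail:
                s += 500_000  # break the distance rule
                e = s + len(cre)
            candidates.append(GenomicInterval(cre.chrom, max(0, s), max(1, e), cre.id))
        out[sp] = {"genes": genes, "candidates": candidates, "scale": scale}
    return out
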