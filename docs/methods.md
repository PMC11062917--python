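# Methods

`garfinder` implements a comparative-regulatory-genomics pipeline for
detecting candidate cis-regulatory elements (CREs) whose nucleotide
substitution rate is accelerated on designated lineages — here, three
independently evolved gliding-marsupial lineages, so the hits are called
GARs (glider-accelerated regions) — and for asking which genes accumulate an
excess of such elements. Every stage is verifiable at desk scale against a
seeded synthetic-data generator with known ground truth.

## CRE derivation

A candidate CRE is an ATAC (open chromatin) peak sharing **at least 1 bp**
with an H3K27ac (active enhancer mark) broad peak. The full ATAC peak extent
is the element — peaks are the tested unit, so the overlap region itself is
not what is kept. Exon-overlapping regions are then removed at region level:
a peak broken by an internal exon is split into sub-peaks (suffixed ids)
rather than discarded, and pieces shorter than `min_cre_len` (default 10 bp,
our addition: shorter fragments produce degenerate alignments downstream)
are dropped. Coordinates are 0-based half-open internally; GFF3 input is
converted on read.

## Synteny-anchored orthologue validation

Lifted-over candidates in each target species are accepted as orthologues
when, on at least one side, (1) the first flanking gene matches the
reference element's flanking gene on that same side and (2) the target
flank distance is at most `synteny_ratio` (default **4×**) the reference
distance. Design choices where the procedure was open:

- *No cross-side matching.* Flank order encodes synteny; a side swap implies
  an inversion, which the anchor is meant to exclude.
- *Degenerate small distances.* A reference distance near 0 collapses the 4×
  bound to ~0 bp; for reference distances < 250 bp an absolute slack of 1 kb
  applies instead.
- *Multi-mappers.* An element id lifting to several target loci is rejected
  outright — the flanking-sequence lift-over parameter exists precisely to
  suppress multi-mapping, so surviving duplicates are treated as unresolved.
- Distances are edge-to-edge gaps (element boundary to gene boundary); 0 for
  abutting features.

## Alignment filtering

Rate estimation is unreliable in gap-rich alignment regions, but filtering
on *similarity* would bias a test that measures divergence, so all rules act
on gap structure only, in a fixed order. `'-'` and `'N'` count alike as gaps
throughout.

1. **Trim to reference** — columns outside the reference row's first/last
   base (lift-over flanks) are cut.
2. **Window end-trim** — a 20 bp window slides inward from each end,
   stopping at the first offset where ≥ ceil(0.75 × rows present) rows have
   ≤ 5 gap/N characters in the window; columns outside the two stopped
   windows are removed. The window advances 1 bp at a time, and the 75%
   criterion counts rows present in this element's alignment (both choices
   configurable).
3. **Internal gap columns** — default `gappyout` mode chooses a data-driven
   cutoff from the sorted per-column gap-fraction curve: the largest jump
   between consecutive distinct values sets the threshold, and columns above
   it are removed. Jumps below 0.1 are ignored so near-uniform gap
   distributions are left alone. This is a slope-heuristic re-implementation
   in the spirit of the published gappyout procedure, not a line-for-line
   port; `fixed` mode (remove columns with gap fraction > 0.9) is the
   deterministic alternative.
4. **Row removal** — rows with **> 25%** gaps or any single gap run
   **> 10%** of the alignment length are dropped (strict inequalities: ties
   survive). The reference row is exempt; if it fails, the element is
   rejected.
5. **Retention** — an element survives only with ≥ 5 species including at
   least one complete (glider, sister) pair and at least one member of every
   outgroup group.

Every rejection is logged as (element, stage, reason).

## The acceleration likelihood-ratio test

The neutral model is a general time-reversible (GTR) substitution model —
tree, branch lengths in expected substitutions/site, six exchangeabilities,
stationary frequencies — fitted by maximum likelihood on putatively neutral
sites (fourfold-degenerate codon positions in the motivating design) with
the topology fixed, frequencies from empirical counts, and the rate matrix
normalized to unit mean rate. PHAST-style `.mod` files are read and written.

For each element and each glider tip (each glider lineage is tested
independently):

- **Null**: maximize the pruning log-likelihood over a free global scale λ
  applied to all branches. The free null scale absorbs element-wide rate
  variation so the test isolates *branch-specific* acceleration, mirroring
  the subtree-scale LRT design of the PHAST family.
- **Alternative**: maximize jointly over (λ, ρ), where ρ additionally scales
  the foreground terminal branch.
- Λ = 2(lnL_alt − lnL_null), clipped at 0. Because ρ = 1 sits on the
  boundary of the directional alternative, the one-sided p uses the ½χ²₁
  convention: p = ½·P(χ²₁ ≥ Λ) when ρ̂ > 1, else 1 − ½·P(χ²₁ ≥ Λ).

Numerics: likelihoods use Felsenstein pruning with the rate matrix
eigendecomposed in the π-symmetrized basis, per-element site-pattern
compression, and gaps/N as marginalized missing data (all-ones partials).
Optimization is bounded (|log λ|, |log ρ| ≤ 7): Brent for the null,
L-BFGS-B for the alternative from three fixed starts (log ρ = 0, ±log 4)
plus the null optimum (λ̂, ρ=1) — the extra deterministic start guarantees
the lnL_alt ≥ lnL_null nesting numerically. Ties break to the highest lnL,
then the smallest |log ρ|. Elements with zero substitutions return Λ = 0,
p = 0.5: ρ is unidentifiable there, and optimizing at the λ bound would
otherwise manufacture a spurious positive Λ of order 10⁻³.

GAR calling uses α = 0.05 on the raw one-sided p by default (the motivating
analysis states no threshold; the value is surfaced as an option and
recorded in output metadata), with optional Benjamini–Hochberg applied
within each species' family of tests. Per-species GAR sets, their union
("accelerated in at least one glider"), pairwise intersections and the
three-way intersection are reported.

### Conservation score track

Per alignment column, an all-branch scale LRT against λ = 1: score =
−log10(p) with positive sign for λ̂ < 1 (conservation) and negative for
λ̂ > 1 (acceleration), two-sided χ²₁ tail for the magnitude, emitted as a
variableStep wiggle on reference coordinates. Columns with no informative
variation score 0. A known property: under neutral simulation at this tree
length (~1 substitution/site total) the track mean sits near +0.1, not
exactly 0 — an invariant column is individually stronger evidence of
slowdown than a singleton substitution is of speedup. The calibration tests
freeze this measured behaviour.

## Enhancer–gene assignment and enrichment

Contact-domain calls from several window sizes are pooled; identical and
fully nested calls collapse to the outermost span, while partially
overlapping and solitary domains are retained (the merged set is
containment-free and the merge is idempotent). Nested merges keep the
*outer* span to preserve the largest contact context.

Each gene's representative is its longest transcript (ties by transcript
id). The TSS derives from the first exon in transcript orientation: if it
begins with ATG it is treated as coding from base one and the TSS is placed
1 kb upstream of the translation start; otherwise the exon is a 5′ UTR and
the TSS sits 1 bp upstream. Minus-strand genes mirror; positions clip to the
chromosome; first exons shorter than 3 bp fall back to the UTR rule with a
warning.

Each CRE is assigned to at most one gene — the TSS nearest its midpoint —
restricted in `domain` mode to TSSs sharing a merged domain with the CRE
midpoint (CREs outside all domains, or in TSS-free domains, stay
unassigned), unrestricted in `distance` mode. Midpoint-to-TSS distance is
used because edge conventions are tool-dependent and the midpoint is
symmetric. Ties go to the leftmost TSS, then lexicographic gene id.

With N assigned CREs of which K are GARs, a gene with n assigned CREs and k
GARs is scored one-tailed: hypergeometric P(X ≥ k), X ~ Hypergeom(N, K, n)
(domain-mode default, sampling without replacement within the tested pool)
or binomial P(X ≥ k), X ~ Binom(n, K/N) (distance-mode default). Both
models are available in both modes and the output names the model used.
Genes with n = 0 are untested; K = 0 yields p = 1 with a warning. No
multiple-testing correction by default (BH optional). Gene-set overlaps
(e.g. enriched genes vs differentially expressed genes) use the
hypergeometric tail on a configurable universe. A diagnostic reports the R²
of domain size vs assigned-CRE count — a check that domain size does not
drive enhancer counts.

## Motif scanning and site conservation

An IUPAC consensus (default ATTARCNV, the EMX2-binding motif) expands to a
PWM: each position spreads probability uniformly over its allowed bases,
then p = (share + pc)/(1 + 4pc) with pseudocount pc = 0.01. Windows are
scored by log2 odds against a 0-order background (default: empirical
mononucleotide frequencies of the scanned set). The p-value is the exact
tail probability of the score among random background words: per-position
scores are rounded to a 10⁻⁴-log2-unit lattice, the rounded-score
distribution is built by convolution, and windows are scored on the same
lattice — so the reported p is exact for the rounded score, and the
deviation from full enumeration stays below 10⁻⁴ for motif lengths up to
~12. Hits at p ≤ 0.01 are kept (ties included); N-containing windows are
skipped; both strands are scanned by default.

Per-species hits within an element's alignment are grouped into sites by
alignment-column overlap of at least half the motif length on the same
strand (exact column identity would be broken by indels). A site present in
≥ ceil(0.5 × species in this element's alignment) species is *conserved*;
otherwise it is *glider-specific* if it covers every glider present and no
non-glider, else *sporadic*. The denominator counts species present in the
element's filtered alignment (configurable), since conservation is assessed
within the per-element alignment.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed:

- **Tree**: 17 tips mirroring the study design — three glider/sister pairs
  inside a petauroid-like radiation with non-gliding relatives, plus two
  outgroup groups of two species each. Species names are fictional; only
  the role structure is meaningful. Branch lengths (0.01–0.06 subs/site
  terminally, total ~1.0) are typical of neutral fourfold-degenerate-site
  divergence in a shallow mammalian radiation.
- **Model**: GTR with base frequencies (0.30, 0.20, 0.20, 0.30) and a 4:1
  transition/transversion exchangeability bias — an unremarkable
  mammalian-like parameterization.
- **Elements**: root sequence drawn from the stationary distribution,
  evolved branch-by-branch with the GTR transition matrices; a per-element
  `accel_spec` multiplies one terminal branch by ρ. Optional indel events
  (Poisson in rate × branch length, geometric lengths, insertions threaded
  through a global column registry) produce true alignments; indels default
  *off* because the LRT treats gaps as missing data — they exist to
  exercise the filtering stages.
- **Regulatory genome**: one chromosome of tiled contact domains (40–100
  kb), each hosting 1–3 multi-exon genes (ATG-initial and UTR-initial first
  exons mixed 50/50, written into the sequence) in its left half and
  intergenic CREs (default 300 bp) in its right half; three domain call
  sets exercise the merge rule (base calls, nested/duplicate calls,
  partial-overlap calls). One planted domain holds a single gene with 12
  CREs of which 10 are accelerated (ρ = 8 on a glider branch) against a 5%
  background acceleration rate — the hypergeometric excess the enrichment
  stage must recover. Differential-expression lists include the planted
  gene. Peak sets are the truth CREs (ids preserved, optional jitter and
  ChIP-free decoys) with broad ChIP peaks whose padding is clipped so
  coverage maps one-to-one onto recoverable elements. Lift-over emulation
  scales each target genome's coordinates by a species factor (0.92–1.12)
  with jitter, corrupting a 5% fraction of candidates to exercise the
  synteny rejection path.

What the generator does **not** emulate: alignment error (true alignments
are emitted), assembly artefacts, lineage-specific duplications, GC-biased
gene conversion, rate variation across sites, non-stationary composition,
and correlated peak noise. Passing tests therefore demonstrate correctness
of the statistics and plumbing under the model's assumptions, not
robustness to real-data pathologies.

All randomness flows from one integer seed; identical config + seed
reproduces every output byte-for-byte (outputs carry no timestamps).

## Problem sizes used in the test and acceptance runs

Calibration uses 500 neutral elements (500 bp, 17 taxa); power uses 200
elements per ρ ∈ {2, 4, 8}. End-to-end planted recovery uses 20 seeded
pipeline runs on compact cohorts (8 domains, ≈ 40–60 CREs, 300 bp
elements); at these sizes the planted gene's enrichment p is ~10⁻⁵–10⁻⁶, so
top-rank recovery is expected in ≥ 18/20 runs. Exact-oracle checks
enumerate all 4⁸ = 65,536 words for the PWM and all internal-state
assignments for 4-taxon likelihoods. These sizes are the package's chosen
desk-scale study conditions; the statistics themselves have no size limits
beyond memory.

## Known limitations

- The ½χ²₁ one-sided p is asymptotic; at very short elements (< ~100 bp) it
  turns conservative.
- `gappyout` mode is a slope heuristic, not a port of the original tool;
  outputs can differ on alignments without clear two-cluster gap structure.
- The conservation track's null mean offset (+~0.1) noted above.
- Foregrounds are single terminal branches; clade (subtree) foregrounds and
  site-rate variation (Γ) are out of scope.
- The exact-p motif scan is practical for motif lengths up to ~15 (lattice
  size grows linearly in length × score range).
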