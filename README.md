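# garfinder

Detection of lineage-accelerated candidate cis-regulatory elements and the
genes they cluster around.

## The problem

When a trait evolves independently in several closely related lineages —
the motivating case is the gliding membrane (patagium) of three petauroid
marsupial species — the regulatory DNA driving it should show
lineage-specific bursts of nucleotide substitution. `garfinder` implements
the comparative pipeline that finds such elements:

1. **CRE calling** — candidate cis-regulatory elements are ATAC
   (open-chromatin) peaks overlapping H3K27ac (active enhancer) marks by
   ≥ 1 bp, minus exonic regions.
2. **Orthologue validation** — lifted-over candidates in each target genome
   are accepted only when a flanking gene matches the reference's flank on
   the same side at ≤ 4× the reference distance (synteny anchoring).
3. **Alignment filtering** — window-based end trimming, gappy-column
   removal, gap-heavy row removal, and a species-composition retention rule
   (≥ 5 species, a complete glider/sister pair, every outgroup group).
4. **Acceleration LRT** — per element and per glider lineage, the test at
   the core of the package. Under a neutral GTR model (tree + rate matrix
   fitted to fourfold-degenerate sites), the null maximizes the pruning
   likelihood over a global branch scale λ; the alternative adds a scale ρ
   on the foreground terminal branch:

       Λ = 2·[ max_{λ,ρ} ln L(λ, ρ) − max_λ ln L(λ, ρ=1) ]

   with one-sided p = ½·P(χ²₁ ≥ Λ) when ρ̂ > 1 (the ½χ² boundary
   convention). Elements significant in at least one glider are GARs
   (glider-accelerated regions).
5. **Gene enrichment** — contact domains (TADs) merged across resolutions
   constrain CRE→gene assignment to the nearest TSS in the same domain;
   per-gene GAR excess is scored with a one-tailed hypergeometric
   (or binomial) test, P(X ≥ k), X ~ Hypergeom(N, K, n).
6. **Motif conservation** — exact-p-value PWM scanning (default motif
   ATTARCNV) and cross-species site-conservation calls within each element
   alignment.

A fully seeded synthetic-data generator (17-taxon tree with three
glider/sister pairs and two outgroup groups, synthetic regulatory genome
with a planted GAR-enriched gene) makes every stage testable with known
ground truth. See `docs/methods.md` for models, defaults, and numerical
choices.

## Worked example

The `analysis/` scripts run the whole study on synthetic data:

```sh
python analysis/01_simulate_inputs.py   # build inputs under results/study/
python analysis/02_run_pipeline.py      # run all stages
python analysis/03_lrt_calibration.py   # null calibration + power curve
python analysis/04_conservation_track.py
```

`01` plants one gene (`gene_009_0`) whose domain holds 12 CREs, 10 of them
evolved with an 8-fold rate multiplier on one glider branch, in a genome of
53 CREs. `02` then prints, among the per-stage counts:

```
top enrichment hit: gene_009_0 (k=11/12, p=0.000157)
planted gene      : gene_009_0 (recovered)
```

i.e. the pipeline called 53 CREs, validated orthologues, tested each
element on all three glider branches (23 GAR elements in the union), and
ranked the planted gene first: 11 of its 12 assigned CREs were called
accelerated, hypergeometric p = 1.6 × 10⁻⁴. `03` prints the operating
characteristics of the LRT (500-bp elements, 200 per condition):

```
rho= 1.0: reject 0.040, median rho_hat 0.98
rho= 2.0: reject 0.905, median rho_hat 1.98
rho= 4.0: reject 1.000, median rho_hat 3.98
rho= 8.0: reject 1.000, median rho_hat 7.99
```

— a ~4–5% false-positive rate at the nominal α = 0.05 with essentially
unbiased recovery of the planted rate multiplier.

Equivalent CLI entry points exist for each stage
(`garfinder cre-call | fit-neutral | msa-filter | accel-test | enrich |
overlap-test | motif-scan | simulate | run`); `garfinder run --config
config.json -o out/` executes the whole pipeline from a JSON config and
writes a `manifest.json` of per-stage counts.

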