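"""End-to-end orchestration: CRE calling through enrichment and motif scan.

A run consumes a directory of inputs described by a JSON config (every
threshold surfaced as a named option with its default), executes the stages
in order, and writes fixed-name outputs plus a ``manifest.json`` of per-stage
counts and rejection reasons under the output directory. Outputs contain no
timestamps, so reruns with identical inputs and config are byte-identical.

``simulate_run_dir`` materializes a complete synthetic input directory with
known ground truth; ``run_synthetic_study`` wires the two together for
planted-recovery experiments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cre_calling, msa_filter
from .enrichment import (
    annotate_tss,
    assign_cres,
    domain_size_diagnostic,
    gene_gar_enrichment,
    merge_contact_domains,
    overlap_test,
)
from .gff import exon_interval_set, read_gff3
from .intervals import GenomicInterval, IntervalSet, read_bed, write_bed
from .motif import call_site_conservation, empirical_background, iupac_to_pwm, scan_sequences
from .msa import OrthologueAlignment, read_fasta, read_roles, write_fasta
from .msa_filter import FilterRejection, RetentionRule
from .ortholog import annotate_flanks, validate_candidates
from .phylo import PhyloModel, call_gars, read_mod, results_table, test_acceleration
from .simulate import (
    REFERENCE_SPECIES,
    SimulationConfig,
    SyntheticGenome,
    default_model,
    default_roles,
    simulate_alignments,
    simulate_liftover,
    simulate_peaksets,
    simulate_regulatory_genome,
)

__all__ = ["RunConfig", "run_pipeline", "simulate_run_dir", "run_synthetic_study"]


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run (all paths run-dir relative)."""

    run_dir: str
    atac: str = "atac.bed"
    chip: str = "chip.bed"
    genes_gff: str = "genes.gff3"
    genome_fasta: str = "genome.fa"
    alignments_dir: str = "alignments"
    roles_tsv: str = "roles.tsv"
    mod_file: str = "neutral.mod"
    domain_beds: list[str] = field(default_factory=list)
    de_genes_tsv: str = "de_genes.tsv"
    target_species: list[str] = field(default_factory=list)
    # thresholds (defaults are the pipeline's standard operating values)
    min_cre_len: int = 10
    synteny_ratio: float = 4.0
    window: int = 20
    species_frac: float = 0.75
    max_window_gaps: int = 5
    column_mode: str = "gappyout"
    max_gap_frac: float = 0.25
    max_run_frac: float = 0.10
    min_species: int = 5
    alpha: float = 0.05
    correction: str = "none"
    enrichment_mode: str = "domain"
    enrichment_model: str = "hypergeometric"
    motif: str = "ATTARCNV"
    motif_p: float = 0.01
    conservation_frac: float = 0.5
    seed: int = 0

    def path(self, name: str) -> Path:
        return Path(self.run_dir) / name

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate(self) -> None:
        for attr in ("atac", "chip", "genes_gff", "genome_fasta", "roles_tsv",
                     "mod_file", "de_genes_tsv"):
            p = self.path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"config input missing: {p}")
        if not 0 < self.species_frac <= 1 or not 0 < self.conservation_frac <= 1:
            raise ValueError("fractions must be in (0, 1]")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must be in (0, 1)")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception) -> None:
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {err}")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    # stage 1: CRE calling -------------------------------------------------
    stage = "cre_call"
    try:
        atac = read_bed(config.path(config.atac), "ATAC")
        chip = read_bed(config.path(config.chip), "H3K27ac")
        genes = read_gff3(config.path(config.genes_gff))
        cres = cre_calling.call_cres(
            atac, chip, exon_interval_set(genes), min_len=config.min_cre_len
        )
        write_bed(cres, outdir / "cres.bed")
        manifest["stages"][stage] = {
            "n_atac": len(atac), "n_chip": len(chip), "n_cres": len(cres),
        }
    except Exception as e:  # noqa: BLE001
        _fail(outdir, manifest, stage, e)

    # stage 2: synteny-anchored orthologue validation ----------------------
    stage = "ortho_validate"
    try:
        gene_spans = IntervalSet([g.span() for g in genes], "ref_genes")
        ref_contexts = {
            cre.id: annotate_flanks(cre, gene_spans) for cre in cres
        }
        accepted: dict[str, set[str]] = {cre.id: {REFERENCE_SPECIES} for cre in cres}
        reject_rows = []
        for sp in config.target_species:
            tgt_genes = read_bed(config.path(f"genes_{sp}.bed"), f"{sp}_genes")
            cands = read_bed(config.path(f"candidates_{sp}.bed"), f"{sp}_cands")
            verdicts = validate_candidates(
                ref_contexts, list(cands), tgt_genes, config.synteny_ratio
            )
            for eid, (iv, v) in verdicts.items():
                if v.accepted:
                    accepted[eid].add(sp)
                else:
                    reject_rows.append((eid, sp, v.reason))
        pd.DataFrame(
            sorted((e, ",".join(sorted(s))) for e, s in accepted.items()),
            columns=["element_id", "accepted_species"],
        ).to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_elements": len(accepted),
            "n_rejected_candidates": len(reject_rows),
        }
    except Exception as e:  # noqa: BLE001
        _fail(outdir, manifest, stage, e)

    # stage 3: alignment filtering ----------------------------------------
    stage = "msa_filter"
    try:
        roles = read_roles(config.path(config.roles_tsv))
        rule = RetentionRule.from_roles(roles, config.min_species)
        aln_dir = config.path(config.alignments_dir)
        filtered: dict[str, OrthologueAlignment] = {}
        rejections = []
        n_in = 0
        for cre in cres:
            fa = aln_dir / f"{cre.id}.fa"
            if not fa.exists():
                continue
            n_in += 1
            rows = read_fasta(fa)
            keep = accepted.get(cre.id, {REFERENCE_SPECIES})
            rows = {sp: s for sp, s in rows.items() if sp in keep}
            if REFERENCE_SPECIES not in rows:
                rejections.append((cre.id, "load", "no_reference_row"))
                continue
            msa = OrthologueAlignment(cre.id, rows, REFERENCE_SPECIES)
            try:
                filtered[cre.id] = msa_filter.filter_alignment(
                    msa, rule,
                    window=config.window, species_frac=config.species_frac,
                    max_gaps=config.max_window_gaps, column_mode=config.column_mode,
                    max_gap_frac=config.max_gap_frac, max_run_frac=config.max_run_frac,
                )
            except FilterRejection as rej:
                rejections.append((rej.element_id, rej.stage, rej.reason))
        pd.DataFrame(
            rejections, columns=["element_id", "stage", "reason"]
        ).to_csv(outdir / "filter_rejections.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_alignments_in": n_in,
            "n_retained": len(filtered),
            "n_rejected": len(rejections),
        }
    except Exception as e:  # noqa: BLE001
        _fail(outdir, manifest, stage, e)

    # stage 4-5: acceleration tests + GAR calling --------------------------
    stage = "accel_test"
    try:
        model = read_mod(config.path(config.mod_file))
        gliders = list(roles.gliders)
        results = []
        for eid in sorted(filtered):
            for sp in gliders:
                results.append(
                    test_acceleration(filtered[eid], model, sp, config.alpha)
                )
        table = results_table(results)
        gars = call_gars(
            table[~table["untestable"]], config.alpha, config.correction
        )
        gars["table"].to_csv(outdir / "acceleration.tsv", sep="\t", index=False)
        with open(outdir / "gars.tsv", "w") as fh:
            fh.write("element_id\tspecies\n")
            for sp in sorted(gars["per_species"]):
                for eid in sorted(gars["per_species"][sp]):
                    fh.write(f"{eid}\t{sp}\n")
        manifest["stages"][stage] = {
            "n_tested": int((~table["untestable"]).sum()),
            "n_untestable": int(table["untestable"].sum()),
            **gars["counts"],
        }
    except Exception as e:  # noqa: BLE001
        _fail(outdir, manifest, stage, e)

    # stage 6: enhancer-gene assignment + enrichment -----------------------
    stage = "enrichment"
    try:
        genome = read_fasta(config.path(config.genome_fasta))
        tss = annotate_tss(genes, genome)
        merged = merge_contact_domains(
            [read_bed(config.path(b), b) for b in config.domain_beds]
        )
        write_bed(merged, outdir / "merged_domains.bed")
        assignments = assign_cres(
            cres, tss, merged if config.enrichment_mode == "domain" else None,
            mode=config.enrichment_mode,
        )
        assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        gar_union = gars["union"]
        enr = gene_gar_enrichment(
            assignments, gar_union, config.enrichment_model,
            config.alpha, config.correction,
        )
        enr_df = pd.DataFrame([asdict(r) for r in enr])
        enr_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        _, r2 = domain_size_diagnostic(merged, assignments)
        de = set(pd.read_csv(config.path(config.de_genes_tsv), sep="\t")["gene_id"])
        universe = {g.gene_id for g in genes}
        enriched = {r.gene_id for r in enr if r.significant}
        p_overlap, n_overlap, _ = overlap_test(
            enriched, de & universe, universe
        )
        manifest["stages"][stage] = {
            "n_merged_domains": len(merged),
            "n_assigned": int((assignments["gene_id"] != "").sum()),
            "n_genes_tested": len(enr),
            "n_genes_enriched": len(enriched),
            "domain_size_r2": r2,
            "de_overlap_n": n_overlap,
            "de_overlap_p": p_overlap,
        }
    except Exception as e:  # noqa: BLE001
        _fail(outdir, manifest, stage, e)

    # stage 7: motif conservation across GAR orthologues -------------------
    stage = "motif"
    try:
        gar_elements = sorted(gar_union & set(filtered))
        seq_pool = {
            f"{eid}|{sp}": filtered[eid].degapped(sp).replace("N", "")
            for eid in gar_elements
            for sp in filtered[eid].species
        }
        bg = empirical_background(seq_pool) if seq_pool else None
        pwm = iupac_to_pwm(config.motif, background=bg)
        site_tables = []
        for eid in gar_elements:
            msa = filtered[eid]
            hits = {
                sp: scan_sequences(
                    {sp: msa.degapped(sp)}, pwm, config.motif_p
                )[sp]
                for sp in msa.species
            }
            site_tables.append(
                call_site_conservation(
                    msa, hits, len(pwm), config.conservation_frac,
                    set(roles.gliders),
                )
            )
        sites = (
            pd.concat(site_tables, ignore_index=True)
            if site_tables
            else pd.DataFrame(
                columns=["site_id", "strand", "col_start", "col_end",
                         "n_species", "species", "status"]
            )
        )
        sites.to_csv(outdir / "motif_sites.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_gar_elements_scanned": len(gar_elements),
            "n_sites": len(sites),
            "n_conserved": int((sites["status"] == "conserved").sum()),
            "n_glider_specific": int((sites["status"] == "glider_specific").sum()),
        }
    except Exception as e:  # noqa: BLE001
        _fail(outdir, manifest, stage, e)

    manifest["status"] = "ok"
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def _fail(outdir: Path, manifest: dict, stage: str, err: Exception) -> None:
    manifest["status"] = f"failed:{stage}"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "FAILED").write_text(f"{stage}: {err}\n")
    raise StageError(stage, err)


# ---------------------------------------------------------------------------
# synthetic run assembly
# ---------------------------------------------------------------------------


def simulate_run_dir(
    run_dir,
    seed: int = 0,
    n_domains: int = 12,
    element_length: int = 300,
    n_planted_cres: int = 12,
    n_planted_accelerated: int = 10,
    background_accel_frac: float = 0.05,
    accel_rho: float = 8.0,
    n_target_species: int | None = None,
    indel_rate: float = 0.0,
) -> tuple[RunConfig, SyntheticGenome]:
    """Write a complete synthetic input directory and its RunConfig."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    model = default_model()
    roles = default_roles()
    genome = simulate_regulatory_genome(
        n_domains=n_domains,
        cre_length=element_length,
        n_planted_cres=n_planted_cres,
        n_planted_accelerated=n_planted_accelerated,
        background_accel_frac=background_accel_frac,
        accel_rho=accel_rho,
        seed=int(rng.integers(0, 2**31 - 1)),
        base_freqs=model.base_freqs,
    )
    genome.write(run_dir)

    atac, chip = simulate_peaksets(
        genome.cre_truth, len(genome.sequence), rng=rng
    )
    write_bed(atac, run_dir / "atac.bed")
    write_bed(chip, run_dir / "chip.bed")

    all_species = [sp for sp in model.tree.tip_names if sp != REFERENCE_SPECIES]
    targets = all_species if n_target_species is None else all_species[:n_target_species]
    lift = simulate_liftover(genome, targets, rng=rng)
    for sp, d in lift.items():
        write_bed(d["genes"], run_dir / f"genes_{sp}.bed")
        write_bed(d["candidates"], run_dir / f"candidates_{sp}.bed")

    sim = SimulationConfig(
        model=model,
        n_elements=len(genome.cre_truth),
        element_length=element_length,
        accel_spec=genome.accel_spec,
        indel_rate=indel_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    alignments, _ = simulate_alignments(sim, element_ids=genome.cre_truth.ids())
    aln_dir = run_dir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for eid, msa in alignments.items():
        write_fasta(msa.rows, aln_dir / f"{eid}.fa")

    from .phylo.model import write_mod

    write_mod(model, run_dir / "neutral.mod")
    rows = [(sp, "glider", "") for sp in roles.gliders]
    rows += [(s, "sister", g) for g, s in roles.pairs]
    rows += [
        (m, "outgroup", label)
        for label, members in roles.outgroup_groups.items()
        for m in members
    ]
    done = {r[0] for r in rows}
    rows += [
        (sp, "other", "") for sp in model.tree.tip_names if sp not in done
    ]
    pd.DataFrame(rows, columns=["species", "role", "group"]).to_csv(
        run_dir / "roles.tsv", sep="\t", index=False
    )
    config = RunConfig(
        run_dir=str(run_dir),
        domain_beds=[f"domains_{label}.bed" for label in genome.domain_call_sets],
        target_species=targets,
        seed=seed,
    )
    config.to_json(run_dir / "config.json")
    return config, genome


def run_synthetic_study(
    workdir, seed: int = 0, **sim_kwargs
) -> tuple[dict, SyntheticGenome, pd.DataFrame]:
    """Simulate inputs, run the pipeline, and return (manifest, truth, enrichment)."""
    workdir = Path(workdir)
    config, genome = simulate_run_dir(workdir / "inputs", seed=seed, **sim_kwargs)
    manifest = run_pipeline(config, workdir / "out")
    enr = pd.read_csv(workdir / "out" / "enrichment.tsv", sep="\t")
    return manifest, genome, enr
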