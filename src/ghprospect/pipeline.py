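"""End-to-end orchestration: simulate -> screen -> search -> profile ->
trees -> association, as one reproducible, seeded run.

The run report is a plain dict (JSON-serializable) with per-stage counts,
the resolved configuration and the package version; identical config and
seed give identical reports.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .align import distance_matrix
from .formats import SequenceRecord
from .profiling import build_matrix, filter_genomes, summarize_by_clade
from .screen import assign_by_margin, filter_contigs, flag_contaminant, screen_assembly
from .search import (
    build_profile,
    search_assembly,
    select_representative,
)
from .simulate import (
    AMINO_ACIDS,
    SimulationConfig,
    simulate_dataset,
)
from .stats import chi_squared_test, presence_by_trait
from .trees import (
    count_group_origins,
    dollo_history,
    nj_tree,
    reconcile,
    root_by_outgroup,
    tanglegram,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All numeric thresholds of the analysis chain in one place."""

    seed: int = 0
    margin: float = 0.10
    flank: int = 500
    max_training: int = 6
    domain_fpr: float = 0.01
    min_completeness: float = 0.50
    max_gap_fraction: float = 0.50
    min_occupancy: float = 0.75
    min_orf_codons: int = 30
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if not 0 < self.margin < 1:
            raise ValueError(f"margin must lie in (0, 1), got {self.margin}")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if not 1 <= self.max_training <= 6:
            raise ValueError("max_training must lie in [1, 6]")
        if not 0 < self.domain_fpr < 1:
            raise ValueError("domain_fpr must lie in (0, 1)")
        for name in ("min_completeness", "max_gap_fraction", "min_occupancy"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_orf_codons < 1:
            raise ValueError("min_orf_codons must be >= 1")
        self.simulation.seed = self.seed
        self.simulation.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _decoy_proteome(seed: int, n: int = 10, length: int = 150) -> list[SequenceRecord]:
    """Unrelated background proteins for the reciprocal-best-hit check."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    return [
        SequenceRecord(
            f"decoy{i + 1:02d}",
            "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)]),
        )
        for i in range(n)
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the machine-readable report."""
    config.validate()
    report: dict = {"config": config.to_dict(), "version": __version__, "seed": config.seed}

    # ---- stage 1: synthetic data -------------------------------------
    ds = simulate_dataset(config.simulation)
    report["simulate"] = {
        "n_species": len(ds.assemblies),
        "n_planted_genes": len(ds.truth.planted_loci),
        "n_contaminant_contigs": sum(len(v) for v in ds.truth.contaminant_contigs.values()),
        "origin_branch": ds.truth.origin_branch,
        "n_duplications_true": len(ds.truth.duplications),
        "n_losses_true": len(ds.truth.losses),
    }

    # ---- stage 2: taxonomic screening --------------------------------
    kept_contigs: dict[str, set[str]] = {}
    flagged_genes: dict[str, list[str]] = {}
    n_flagged = n_genes = n_contigs_dropped = 0
    for sp in sorted(ds.assemblies):
        rep = screen_assembly(ds.gene_hits[sp], ds.species_taxid[sp], ds.taxonomy, config.margin)
        flagged_genes[sp] = rep.flagged_genes
        n_flagged += rep.n_flagged
        n_genes += len(rep.assignments)
        contig_assignments = {}
        for contig in [c.id for c in ds.assemblies[sp]]:
            gene_ids = ds.contig_genes.get(sp, {}).get(contig, [])
            hits = [h for g in gene_ids for h in ds.gene_hits[sp][g]]
            a = assign_by_margin(hits, self_id="__none__", taxonomy=ds.taxonomy, margin=config.margin)
            a.query_id = contig
            contig_assignments[contig] = a
        kept = filter_contigs(contig_assignments, ds.target_phylum, ds.taxonomy)
        kept_contigs[sp] = kept
        n_contigs_dropped += len(ds.assemblies[sp]) - len(kept)
    report["screen"] = {
        "n_genes_screened": n_genes,
        "n_genes_flagged": n_flagged,
        "n_contigs_dropped": n_contigs_dropped,
    }

    # ---- stage 3: targeted search ------------------------------------
    seed_rec = SequenceRecord("seed", ds.seed_protein)
    core = [seed_rec] + ds.foreign_proteins[: config.max_training - 1]
    profile = build_profile(core, domain_fpr=config.domain_fpr)
    proteome = [seed_rec] + _decoy_proteome(config.seed)
    candidates: dict[str, list] = {}
    n_candidates = n_accepted = 0
    for sp in sorted(ds.assemblies):
        assembly = [c for c in ds.assemblies[sp] if c.id in kept_contigs[sp]]
        cands = search_assembly(
            assembly, profile, seed_rec, proteome,
            flank=config.flank, min_codons=config.min_orf_codons,
        )
        candidates[sp] = cands
        n_candidates += len(cands)
        n_accepted += sum(1 for c in cands if c.domain_pass and c.orthology_pass)
    report["search"] = {"n_candidates": n_candidates, "n_accepted": n_accepted}

    # ---- stage 4: profiling ------------------------------------------
    kept_species = filter_genomes(ds.metadata, config.min_completeness)
    matrix = build_matrix(
        {sp: candidates.get(sp, []) for sp in kept_species}, kept_species, ds.metadata
    )
    clades = summarize_by_clade(matrix)
    truth_presence = {sp: n >= 1 for sp, n in ds.truth.per_tip_copy_number.items()}
    agree = sum(
        1
        for sp in matrix.species()
        if bool(matrix.presence("GH45")[sp]) == truth_presence.get(sp, False)
    )
    report["profile"] = {
        "n_genomes_kept": len(kept_species),
        "per_clade": clades.to_dict(orient="records"),
        "presence_accuracy_vs_truth": agree / max(1, len(matrix.species())),
    }

    # ---- stage 5: tree analysis --------------------------------------
    reps: list[SequenceRecord] = []
    for sp in sorted(candidates):
        accepted = [c for c in candidates[sp] if c.domain_pass and c.orthology_pass]
        if not accepted:
            continue
        rep = select_representative(accepted, seed_rec)
        reps.append(SequenceRecord(f"{sp}", rep.protein.seq))
    trees_report: dict = {}
    if len(reps) + len(ds.foreign_proteins) >= 4:
        leaves = reps + ds.foreign_proteins
        labels, dmat = distance_matrix(leaves)
        gene_tree = nj_tree(labels, dmat)
        outgroup = [r.id for r in ds.foreign_proteins]
        try:
            rooted = root_by_outgroup(gene_tree, outgroup)
            groups = {lab: ("native" if not lab.startswith("foreign") else "foreign") for lab in labels}
            origins = count_group_origins(rooted, groups, "native")
        except ValueError:
            rooted = None
            origins = None
        gain, losses = dollo_history(
            ds.species_tree, {sp: int(matrix.presence("GH45").get(sp, 0)) for sp in matrix.species()}
        )
        trees_report.update(
            {
                "n_gene_tree_leaves": len(labels),
                "origins_count": origins,
                "dollo_gain_branch": gain,
                "dollo_loss_count": len(losses),
            }
        )
        if rooted is not None and len(reps) >= 2:
            native = rooted.clone(depth=1)
            native.retain_taxa_with_labels([r.id for r in reps])
            present_species = [r.id for r in reps]
            sp_tree = ds.species_tree.clone(depth=1)
            sp_tree.retain_taxa_with_labels(present_species)
            rec = reconcile(native, sp_tree, {sp: sp for sp in present_species})
            links = [(sp, sp) for sp in present_species]
            _, crossings, _ = tanglegram(native, sp_tree, links)
            trees_report.update(
                {
                    "reconciliation_duplications": rec.duplications,
                    "reconciliation_losses": rec.losses,
                    "tanglegram_crossings": crossings,
                }
            )
    report["trees"] = trees_report

    # ---- stage 6: association ----------------------------------------
    try:
        table = presence_by_trait(matrix)
        stat, df, p = chi_squared_test(table)
        report["assoc"] = {
            "observed": table.observed.astype(int).tolist(),
            "statistic": stat,
            "df": df,
            "p_value": p,
            "excluded": table.excluded,
        }
    except ValueError as exc:
        report["assoc"] = {"error": str(exc)}
    return report
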