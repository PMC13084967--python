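"""Taxonomic screening of candidate genes and contigs.

Reimplements the assignment-and-contaminant-flagging procedure used to rule
out microbial contamination as the source of apparent animal cellulases:

1. for each query, drop the trivial self-hit(s), keep every hit whose bit
   score lies within a fixed margin (default 10%) of the best remaining hit,
   and assign the query to the last common ancestor of those hits' taxa;
2. flag the query as a putative contaminant if that assignment does not lie
   on the lineage from the query species to the root of cellular life;
3. at the contig level, keep only contigs assigned within the target
   phylum, plus unassigned contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .formats import HitRecord
from .taxonomy import Taxonomy, TaxonomyError

__all__ = [
    "UNASSIGNED",
    "Assignment",
    "ScreeningReport",
    "assign_by_margin",
    "flag_contaminant",
    "filter_contigs",
    "screen_assembly",
]

UNASSIGNED = None  # sentinel for "no informative hit"

DEFAULT_MARGIN = 0.10


@dataclass
class Assignment:
    """Taxonomic call for one query sequence."""

    query_id: str
    assigned_taxid: int | None
    margin_used: float
    contributing_hits: list[HitRecord] = field(default_factory=list)
    flagged: bool = False

    @property
    def unassigned(self) -> bool:
        return self.assigned_taxid is UNASSIGNED


def assign_by_margin(
    hits: Iterable[HitRecord],
    self_id: str,
    taxonomy: Taxonomy,
    margin: float = DEFAULT_MARGIN,
) -> Assignment:
    """Assign a query to the LCA of taxa within a bit-score margin of the best hit.

    Every hit whose ``subject_id`` equals ``self_id`` is excluded first.
    Among the rest, hits with ``bitscore >= (1 - margin) * best`` (boundary
    inclusive, so score ties never drop taxa) contribute, and the assignment
    is the LCA of their taxon ids.  With no non-self hits the query is
    unassigned, which downstream never treats as contamination.
    """
    if not 0 < margin < 1:
        raise ValueError(f"margin must lie in (0, 1), got {margin}")
    query_id = self_id
    informative = []
    for h in hits:
        query_id = h.query_id
        if h.subject_id != self_id:
            informative.append(h)
    if not informative:
        return Assignment(query_id=query_id, assigned_taxid=UNASSIGNED, margin_used=margin)
    best = max(h.bitscore for h in informative)
    threshold = (1.0 - margin) * best
    contributing = [h for h in informative if h.bitscore >= threshold]
    taxid = taxonomy.lca({h.subject_taxid for h in contributing})
    return Assignment(
        query_id=query_id,
        assigned_taxid=taxid,
        margin_used=margin,
        contributing_hits=contributing,
    )


def flag_contaminant(assignment: Assignment, query_species_taxid: int, taxonomy: Taxonomy) -> Assignment:
    """Flag an assignment whose taxon is off the query species' root lineage.

    "On the lineage" covers the species itself, all its ancestors up to the
    root, and — to tolerate sub-species resolution in the reference — any
    descendant of the species.  Unassigned queries are never flagged.
    """
    if query_species_taxid not in taxonomy:
        raise TaxonomyError(f"unknown query species taxid {query_species_taxid}")
    if assignment.assigned_taxid is UNASSIGNED:
        assignment.flagged = False
        return assignment
    t = assignment.assigned_taxid
    on_lineage = taxonomy.is_ancestor_or_self(t, query_species_taxid) or taxonomy.is_ancestor_or_self(
        query_species_taxid, t
    )
    assignment.flagged = not on_lineage
    return assignment


def filter_contigs(
    per_contig_assignments: Mapping[str, Assignment],
    target_phylum_taxid: int,
    taxonomy: Taxonomy,
    warn: list[str] | None = None,
) -> set[str]:
    """Contig-level filter: keep target-phylum and unassigned contigs.

    A contig passes if its assignment is unassigned, lies inside the target
    phylum's subtree, or is an ancestor of the target phylum (an assignment
    to e.g. the kingdom is compatible with the target, not evidence against
    it).  Everything else — confidently foreign contigs — is dropped.
    """
    if taxonomy.rank(target_phylum_taxid) != "phylum" and warn is not None:
        warn.append(
            f"target taxid {target_phylum_taxid} has rank "
            f"{taxonomy.rank(target_phylum_taxid)!r}, not 'phylum'"
        )
    kept: set[str] = set()
    for contig_id, assignment in per_contig_assignments.items():
        if assignment.assigned_taxid is UNASSIGNED:
            kept.add(contig_id)
            continue
        t = assignment.assigned_taxid
        compatible = taxonomy.is_ancestor_or_self(target_phylum_taxid, t) or taxonomy.is_ancestor_or_self(
            t, target_phylum_taxid
        )
        if compatible:
            kept.add(contig_id)
    return kept


@dataclass
class ScreeningReport:
    """Aggregate result of screening one assembly's gene set."""

    assignments: dict[str, Assignment]
    n_assigned: int
    n_unassigned: int
    n_flagged: int
    flagged_genes: list[str]

    def to_dict(self) -> dict:
        return {
            "n_genes": len(self.assignments),
            "n_assigned": self.n_assigned,
            "n_unassigned": self.n_unassigned,
            "n_flagged": self.n_flagged,
            "flagged_genes": list(self.flagged_genes),
        }


def screen_assembly(
    gene_hits: Mapping[str, list[HitRecord]],
    query_species_taxid: int,
    taxonomy: Taxonomy,
    margin: float = DEFAULT_MARGIN,
) -> ScreeningReport:
    """Run margin-LCA assignment plus contaminant flagging over a gene set."""
    assignments: dict[str, Assignment] = {}
    for gene_id in sorted(gene_hits):
        try:
            a = assign_by_margin(gene_hits[gene_id], self_id=gene_id, taxonomy=taxonomy, margin=margin)
            a.query_id = gene_id
            assignments[gene_id] = flag_contaminant(a, query_species_taxid, taxonomy)
        except (TaxonomyError, ValueError) as exc:
            raise type(exc)(f"gene {gene_id!r}: {exc}") from exc
    flagged = [g for g, a in assignments.items() if a.flagged]
    n_unassigned = sum(1 for a in assignments.values() if a.unassigned)
    return ScreeningReport(
        assignments=assignments,
        n_assigned=len(assignments) - n_unassigned,
        n_unassigned=n_unassigned,
        n_flagged=len(flagged),
        flagged_genes=flagged,
    )
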