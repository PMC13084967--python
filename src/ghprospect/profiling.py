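"""Presence/absence phylogenetic profiling across a species set.

Aggregates validated candidates into a species x gene-family copy-number
matrix, applies the assembly-quality inclusion rule (completeness of at
least 50%), summarizes presence per clade, and emits the 3-column
profile table (geneID, ncbiID, orthoID) consumed by profile viewers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .simulate import SpeciesMeta

__all__ = [
    "PresenceMatrix",
    "filter_genomes",
    "build_matrix",
    "summarize_by_clade",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_metadata_tsv",
    "read_metadata_tsv",
]

DEFAULT_MIN_COMPLETENESS = 0.50


@dataclass
class PresenceMatrix:
    """Species x gene-family copy counts plus per-species metadata."""

    counts: pd.DataFrame  # index: species_id, columns: family names, int
    meta: dict[str, SpeciesMeta]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("copy counts must be non-negative")

    def presence(self, family: str) -> pd.Series:
        return self.counts[family] >= 1

    def species(self) -> list[str]:
        return list(self.counts.index)


def filter_genomes(
    metadata: Iterable[SpeciesMeta],
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
) -> set[str]:
    """Keep species whose assembly completeness is at least the threshold
    (inclusive: exactly 50% passes)."""
    return {m.species_id for m in metadata if m.busco_completeness >= min_completeness}


def build_matrix(
    candidates_per_species: Mapping[str, Sequence],
    kept_species: Iterable[str],
    metadata: Iterable[SpeciesMeta],
    family: str = "GH45",
) -> PresenceMatrix:
    """Count accepted candidates (domain AND orthology pass) per species.

    Species in the kept set with no candidates get a zero; candidates for
    species outside the kept set raise a warning and are excluded.
    """
    kept = sorted(set(kept_species))
    meta = {m.species_id: m for m in metadata}
    counts = {}
    for sp, cands in candidates_per_species.items():
        n = sum(1 for c in cands if c.domain_pass and c.orthology_pass)
        if sp not in kept:
            warnings.warn(f"candidates for excluded species {sp!r} ignored", stacklevel=2)
            continue
        counts[sp] = n
    data = pd.DataFrame({family: [counts.get(sp, 0) for sp in kept]}, index=pd.Index(kept, name="species"))
    return PresenceMatrix(counts=data.astype(int), meta={sp: meta[sp] for sp in kept if sp in meta})


def summarize_by_clade(matrix: PresenceMatrix, family: str = "GH45") -> pd.DataFrame:
    """Per-clade presence summary: (n_present, n_total, fraction).

    Species whose metadata is missing a clade label are grouped under
    "unknown".  Clade totals partition the species set.
    """
    rows = []
    present = matrix.presence(family)
    clades: dict[str, list[str]] = {}
    for sp in matrix.species():
        meta = matrix.meta.get(sp)
        clade = meta.clade if meta is not None and meta.clade else "unknown"
        clades.setdefault(clade, []).append(sp)
    for clade in sorted(clades):
        members = clades[clade]
        n_present = int(sum(present[sp] for sp in members))
        rows.append(
            {"clade": clade, "n_present": n_present, "n_total": len(members),
             "fraction": n_present / len(members)}
        )
    return pd.DataFrame(rows)


def write_profile_tsv(
    matrix: PresenceMatrix,
    path: str | Path,
    orthologue_ids: Mapping[str, Sequence[str]] | None = None,
    family: str = "GH45",
) -> None:
    """Write the minimal 3-column profile table.

    One row per (family, species, orthologue); species with zero copies
    get no row.  ``ncbiID`` is rendered ``ncbi<taxid>``.  When explicit
    orthologue ids are not given, placeholder ids ``species|gN`` are
    emitted, one per counted copy.
    """
    with open(path, "w") as fh:
        fh.write("geneID\tncbiID\torthoID\n")
        for sp in matrix.species():
            n = int(matrix.counts.loc[sp, family])
            if n == 0:
                continue
            taxid = matrix.meta[sp].taxid if sp in matrix.meta else 0
            ids = (
                list(orthologue_ids.get(sp, []))
                if orthologue_ids is not None
                else [f"{sp}|g{i + 1}" for i in range(n)]
            )
            for oid in ids:
                fh.write(f"{family}\tncbi{taxid}\t{oid}\n")


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["geneID", "ncbiID", "orthoID"]
    if list(df.columns) != expected:
        raise ValueError(f"profile table must have columns {expected}, got {list(df.columns)}")
    return df


def write_metadata_tsv(metadata: Iterable[SpeciesMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\ttaxid\tbusco_completeness\treproduction_mode\tclade\n")
        for m in metadata:
            fh.write(f"{m.species_id}\t{m.taxid}\t{m.busco_completeness:.4f}\t{m.reproduction_mode}\t{m.clade}\n")


def read_metadata_tsv(path: str | Path) -> list[SpeciesMeta]:
    df = pd.read_csv(path, sep="\t")
    return [
        SpeciesMeta(r.species_id, int(r.taxid), float(r.busco_completeness),
                    r.reproduction_mode, r.clade)
        for r in df.itertuples()
    ]
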