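"""Strict readers and writers for the formats the pipeline touches.

Everything here rejects malformed input rather than coercing it, and every
error names the offending record, line or position.  Supported formats:

* FASTA (nucleotide or amino acid), via Biopython's parser plus validation;
* Newick trees, via dendropy (the tree container used package-wide);
* homology hit tables — 5-column BLAST-tabular-like TSV
  (``qseqid  sseqid  staxid  bitscore  evalue``, no header);
* taxonomies — 4-column TSV (``taxid  parent_taxid  rank  name``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceRecord",
    "HitRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_hit_table",
    "write_hit_table",
    "read_taxonomy_table",
    "write_taxonomy_table",
]

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_ALPHABETS = {"nucleotide": NUCLEOTIDE_ALPHABET, "protein": PROTEIN_ALPHABET}

FASTA_WRAP = 60  # column width used on output


class FormatError(ValueError):
    """Malformed input file (bad syntax, bad value, broken invariant)."""


@dataclass
class SequenceRecord:
    """A single FASTA record; sequence stored uppercase."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class HitRecord:
    """One homology hit: the bit score drives the LCA margin rule."""

    query_id: str
    subject_id: str
    subject_taxid: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise FormatError(f"negative bitscore for hit {self.query_id!r} vs {self.subject_id!r}")
        if self.evalue < 0:
            raise FormatError(f"negative evalue for hit {self.query_id!r} vs {self.subject_id!r}")


def _validate_seq(seq: str, mode: str, record_id: str) -> str:
    alphabet = _ALPHABETS[mode]
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise FormatError(
                f"illegal {mode} character {ch!r} at position {pos} in record {record_id!r}"
            )
    return seq


def read_fasta(path: str | Path | io.TextIOBase, mode: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file, validating ids and the declared alphabet.

    ``mode`` is ``"nucleotide"`` (A,C,G,T,N) or ``"protein"`` (20 amino
    acids + X).  Input case is folded to uppercase.  Duplicate ids and
    illegal characters raise :class:`FormatError`; an empty file yields an
    empty list.
    """
    if mode not in _ALPHABETS:
        raise ValueError(f"mode must be 'nucleotide' or 'protein', got {mode!r}")
    if isinstance(path, (str, Path)):
        handle: io.TextIOBase = open(path)
        close = True
    else:
        handle, close = path, False
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            if not parts:
                raise FormatError("FASTA record with empty header line")
            rec_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if rec_id in seen:
                raise FormatError(f"duplicate FASTA id {rec_id!r}")
            seen.add(rec_id)
            if not seq:
                raise FormatError(f"empty sequence for record {rec_id!r}")
            records.append(SequenceRecord(rec_id, _validate_seq(seq, mode, rec_id), desc))
    finally:
        if close:
            handle.close()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path | io.TextIOBase) -> None:
    """Write records wrapped at 60 columns; round-trips with :func:`read_fasta`."""
    if isinstance(path, (str, Path)):
        handle: io.TextIOBase = open(path, "w")
        close = True
    else:
        handle, close = path, False
    try:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.seq), FASTA_WRAP):
                handle.write(rec.seq[i : i + FASTA_WRAP] + "\n")
    finally:
        if close:
            handle.close()


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree.

    Branch lengths default to 1.0 when absent (flagged on the tree as
    ``tree.lengths_defaulted``).  Duplicate leaf labels and syntax errors
    raise :class:`FormatError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon" in str(exc):
            raise FormatError(f"duplicate leaf labels in Newick input: {exc}") from exc
        raise FormatError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf labels in Newick input: {sorted(dupes)}")
    defaulted = False
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
            defaulted = True
    tree.lengths_defaulted = defaulted
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 5-column tab-separated hit table (no header), in file order."""
    hits: list[HitRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 tab-separated columns, got {len(cols)}")
            try:
                hit = HitRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    subject_taxid=int(cols[2]),
                    bitscore=float(cols[3]),
                    evalue=float(cols[4]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for h in hits:
            handle.write(f"{h.query_id}\t{h.subject_id}\t{h.subject_taxid}\t{h.bitscore:g}\t{h.evalue:g}\n")


def read_taxonomy_table(path: str | Path) -> list[tuple[int, int, str, str]]:
    """Read the 4-column taxonomy TSV: taxid, parent_taxid, rank, name."""
    rows: list[tuple[int, int, str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated columns, got {len(cols)}")
            try:
                rows.append((int(cols[0]), int(cols[1]), cols[2], cols[3]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_taxonomy_table(rows: Iterable[tuple[int, int, str, str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for taxid, parent, rank, name in rows:
            handle.write(f"{taxid}\t{parent}\t{rank}\t{name}\n")
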