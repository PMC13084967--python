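"""Pairwise global alignment and alignment-matrix utilities.

Needleman–Wunsch with affine gap costs (Gotoh) is the distance substrate
for orthology checks, representative selection and tree building.  A gap
of length k costs ``gap_open + (k - 1) * gap_extend``; traceback ties are
resolved deterministically (diagonal > up > left).  On top of that sit
gap-column trimming (columns with more than 50% gaps removed), supermatrix
concatenation with an occupancy rule, and p-distance matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .formats import SequenceRecord

__all__ = [
    "Alignment",
    "global_align",
    "alignment_score",
    "trim_alignment",
    "build_supermatrix",
    "p_distance",
    "distance_matrix",
    "star_align",
]

_BLOSUM62 = None


def blosum62() -> dict[tuple[str, str], float]:
    global _BLOSUM62
    if _BLOSUM62 is None:
        m = substitution_matrices.load("BLOSUM62")
        _BLOSUM62 = {
            (a, b): float(m[a, b]) for a in m.alphabet for b in m.alphabet
        }
    return _BLOSUM62


def _score_fn(matrix: Mapping[tuple[str, str], float] | None):
    table = blosum62() if matrix is None else matrix
    fallback = min(table.values())

    def score(a: str, b: str) -> float:
        return table.get((a, b), table.get((b, a), fallback))

    return score


@dataclass
class Alignment:
    """Gapped rows of equal length over the protein alphabet + '-'."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ids(self) -> list[str]:
        return list(self.rows)

    def column(self, i: int) -> list[str]:
        return [s[i] for s in self.rows.values()]


NEG_INF = float("-inf")


def global_align(
    a: str,
    b: str,
    substitution_matrix: Mapping[tuple[str, str], float] | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[str, str, float]:
    """Optimal global alignment with affine gaps; returns (a', b', score).

    Empty sequences are allowed (all-gap alignment).  The traceback is
    deterministic: on score ties the diagonal move wins over the vertical
    (gap in ``b``) which wins over the horizontal (gap in ``a``).
    """
    score = _score_fn(substitution_matrix)
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return "", "", 0.0
    # H: best overall; E: ends with gap in a (consumes b); F: gap in b
    H = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -(gap_open + (j - 1) * gap_extend)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = -(gap_open + (i - 1) * gap_extend)
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(Ei[j - 1] - gap_extend, Hi[j - 1] - gap_open)
            f = max(Fi1[j] - gap_extend, Hi1[j] - gap_open)
            d = Hi1[j - 1] + score(ai, b[j - 1])
            Ei[j] = e
            Fi[j] = f
            Hi[j] = max(d, f, e)
    # deterministic traceback: diagonal > up (F) > left (E)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j, state = n, m, "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + score(a[i - 1], b[j - 1]):
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif i > 0 and H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            out_a.append(a[i - 1])
            out_b.append("-")
            nxt_open = H[i - 1][j] - gap_open
            nxt_ext = F[i - 1][j] - gap_extend if i > 1 else NEG_INF
            i -= 1
            if nxt_open >= nxt_ext:
                state = "H"
            else:
                state = "F"
        else:  # E
            out_a.append("-")
            out_b.append(b[j - 1])
            nxt_open = H[i][j - 1] - gap_open
            nxt_ext = E[i][j - 1] - gap_extend if j > 1 else NEG_INF
            j -= 1
            if nxt_open >= nxt_ext:
                state = "H"
            else:
                state = "E"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), H[n][m]


def alignment_score(
    a: str,
    b: str,
    substitution_matrix: Mapping[tuple[str, str], float] | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Score-only Needleman–Wunsch (same recurrences, no traceback)."""
    return global_align(a, b, substitution_matrix, gap_open, gap_extend)[2]


def trim_alignment(alignment: Alignment, max_gap_fraction: float = 0.50, warn: list[str] | None = None) -> Alignment:
    """Drop columns whose gap fraction strictly exceeds the threshold.

    A column with exactly ``max_gap_fraction`` gaps is retained ("more
    than 50% gaps removed").  Column order is preserved; the operation is
    idempotent.  An all-columns-removed result is a warning, not an error.
    """
    n_rows = len(alignment.rows)
    if n_rows == 0:
        return Alignment(rows={})
    keep = []
    for i in range(alignment.length):
        gaps = sum(1 for c in alignment.column(i) if c == "-")
        if gaps / n_rows <= max_gap_fraction:
            keep.append(i)
    if not keep and alignment.length and warn is not None:
        warn.append("all alignment columns removed by gap trimming")
    return Alignment(rows={k: "".join(v[i] for i in keep) for k, v in alignment.rows.items()})


def build_supermatrix(
    gene_alignments: Mapping[str, Alignment],
    species: Iterable[str],
    min_occupancy: float = 0.75,
) -> tuple[Alignment, list[tuple[str, int, int]]]:
    """Concatenate per-gene alignments into a supermatrix.

    Genes present in fewer than ``min_occupancy`` of the species are
    discarded ("less than 75%" — a gene at exactly the threshold is kept);
    species missing a retained gene are padded with gaps.  Returns the
    supermatrix and a partition table of half-open column intervals.
    """
    species = sorted(species)
    if not species:
        raise ValueError("empty species set")
    retained = []
    for gene in sorted(gene_alignments):
        aln = gene_alignments[gene]
        present = sum(1 for sp in species if sp in aln.rows)
        if present / len(species) >= min_occupancy:
            retained.append(gene)
    if not retained:
        raise ValueError("no gene meets the occupancy threshold")
    rows = {sp: [] for sp in species}
    partitions: list[tuple[str, int, int]] = []
    offset = 0
    for gene in retained:
        aln = gene_alignments[gene]
        width = aln.length
        for sp in species:
            rows[sp].append(aln.rows.get(sp, "-" * width))
        partitions.append((gene, offset, offset + width))
        offset += width
    return Alignment(rows={sp: "".join(parts) for sp, parts in rows.items()}), partitions


def p_distance(a_gapped: str, b_gapped: str) -> float:
    """Mismatches over aligned non-gap columns (no multiple-hit correction)."""
    pairs = [(x, y) for x, y in zip(a_gapped, b_gapped) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def corrected_distance(p: float, n_states: int = 20) -> float:
    """Jukes–Cantor-style multiple-hit correction for ``n_states`` states."""
    k = (n_states - 1) / n_states
    if p >= k:
        return float("inf")
    return -k * math.log(1 - p / k)


def distance_matrix(
    records: Sequence[SequenceRecord],
    correction: bool = False,
    substitution_matrix: Mapping[tuple[str, str], float] | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distance matrix from global alignments."""
    labels = [r.id for r in records]
    n = len(records)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if len(records[i].seq) == len(records[j].seq):
                ga, gb = records[i].seq, records[j].seq  # already colinear
            else:
                ga, gb, _ = global_align(
                    records[i].seq, records[j].seq, substitution_matrix, gap_open, gap_extend
                )
            d = p_distance(ga, gb)
            if correction:
                d = corrected_distance(d)
            mat[i, j] = mat[j, i] = d
    return labels, mat


def star_align(records: Sequence[SequenceRecord]) -> Alignment:
    """Star multiple alignment against the first record.

    Substitution-only inputs of equal length pass through unchanged; for
    unequal lengths each record is pairwise-aligned to the first and gaps
    are projected onto a common coordinate system.  A convenience for
    desk-scale tree building, not a replacement for a real MSA tool.
    """
    if not records:
        return Alignment(rows={})
    if len({len(r.seq) for r in records}) == 1:
        return Alignment(rows={r.id: r.seq for r in records})
    ref = records[0]
    # master gap pattern: positions between reference residues -> max insert
    inserts = [0] * (len(ref.seq) + 1)
    pairs = []
    for rec in records[1:]:
        ga, gb, _ = global_align(ref.seq, rec.seq)
        pairs.append((rec.id, ga, gb))
        pos = 0
        run = 0
        for c in ga:
            if c == "-":
                run += 1
            else:
                inserts[pos] = max(inserts[pos], run)
                run = 0
                pos += 1
        inserts[len(ref.seq)] = max(inserts[len(ref.seq)], run)

    def project(ga: str, gb: str) -> str:
        out = []
        pos = 0
        run_chars: list[str] = []
        for ca, cb in zip(ga, gb):
            if ca == "-":
                run_chars.append(cb)
            else:
                out.append(run_chars + ["-"] * (inserts[pos] - len(run_chars)))
                out.append([cb])
                run_chars = []
                pos += 1
        out.append(run_chars + ["-"] * (inserts[len(ref.seq)] - len(run_chars)))
        return "".join(c for chunk in out for c in chunk)

    rows = {ref.id: project("".join(ref.seq), "".join(ref.seq))}
    for rec_id, ga, gb in pairs:
        rows[rec_id] = project(ga, gb)
    return Alignment(rows=rows)
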