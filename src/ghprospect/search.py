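"""Targeted gene-family search in unannotated assemblies.

A position-specific scoring model (PSSM) built from at most six core
orthologues drives both stages that need a family model:

* a six-frame sliding-window scan over assembly contigs locates candidate
  regions (the homology-search stage), which are extended by a fixed
  flank (default 500 nt) and handed to single-exon gene prediction
  (longest open reading frame overlapping the hit);
* the same kind of model, scanned over a predicted protein, implements
  the domain-presence filter, with the score threshold calibrated so that
  random background passes with frequency at most the configured false
  positive rate (default 0.01).

Predicted proteins are then tested for orthology by reciprocal best hit
against the seed species' proteome using global alignment scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import alignment_score
from .formats import SequenceRecord
from .simulate import AMINO_ACIDS, reverse_complement

__all__ = [
    "Profile",
    "GenomicRegion",
    "CandidateGene",
    "MAX_TRAINING",
    "translate",
    "build_profile",
    "six_frame_translate",
    "search_regions",
    "extend_region",
    "predict_gene",
    "annotate_domain",
    "check_orthology",
    "select_representative",
    "search_assembly",
]

logger = logging.getLogger(__name__)

MAX_TRAINING = 6  # cap on profile training sequences
DEFAULT_FLANK = 500  # nt added on either side of a hit region
MIN_ORF_CODONS = 30
STOP_SCORE = -4.0  # PSSM score of a stop codon in a translated track
X_SCORE = 0.0

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_X_IDX, _STOP_IDX = 20, 21
_N_SYMBOLS = 22

# codon -> amino acid (standard code); codons with N translate to X
_CODON_TABLE: dict[str, str] = {}
from .simulate import _CODONS as _AA_CODONS, _STOPS as _STOP_CODONS  # noqa: E402

for _aa, _cods in _AA_CODONS.items():
    for _c in _cods:
        _CODON_TABLE[_c] = _aa
for _c in _STOP_CODONS:
    _CODON_TABLE[_c] = "*"


def translate(nt: str) -> str:
    """Translate in frame 0; stops as '*', ambiguous codons as 'X'."""
    out = []
    for i in range(0, len(nt) - 2, 3):
        out.append(_CODON_TABLE.get(nt[i : i + 3], "X"))
    return "".join(out)


def _encode_protein(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        if ch == "*":
            out[i] = _STOP_IDX
        else:
            out[i] = _AA_INDEX.get(ch, _X_IDX)
    return out


# uniform protein background and the background of translated random DNA
_UNIFORM_BG = np.zeros(_N_SYMBOLS)
_UNIFORM_BG[:20] = 1 / 20
_CODON_BG = np.zeros(_N_SYMBOLS)
for _c, _aa in _CODON_TABLE.items():
    _CODON_BG[_STOP_IDX if _aa == "*" else _AA_INDEX[_aa]] += 1 / 64


@dataclass
class Profile:
    """Fixed-length log-odds scoring model with a consensus sequence."""

    length: int
    consensus: str
    pssm: np.ndarray  # shape (length, 22): 20 aa + X + stop
    training_ids: list[str]
    score_threshold: float

    def window_score(self, window: str) -> float:
        if len(window) != self.length:
            raise ValueError("window length must equal profile length")
        idx = _encode_protein(window)
        return float(self.pssm[np.arange(self.length), idx].sum())

    def scan(self, track: np.ndarray) -> np.ndarray:
        """Scores of every length-L window over an encoded residue track."""
        n = len(track) - self.length + 1
        if n <= 0:
            return np.empty(0)
        scores = np.zeros(n)
        for i in range(self.length):
            scores += self.pssm[i, track[i : i + n]]
        return scores

    def max_score(self) -> float:
        return float(self.pssm[:, :20].max(axis=1).sum())

    def chernoff_threshold(self, target_p: float, background: np.ndarray | None = None) -> float:
        """Smallest score t with a Chernoff bound P(window >= t) <= target_p.

        Exact exponential-moment bound under the per-column background, so
        the false-positive guarantee holds without Gaussian approximation.
        """
        bgs = [_UNIFORM_BG, _CODON_BG] if background is None else [background]
        best = -math.inf
        for bg in bgs:
            thr = math.inf
            for theta in np.linspace(0.05, 8.0, 160):
                log_mgf = 0.0
                for c in range(self.length):
                    log_mgf += math.log(float(np.sum(bg * np.exp(theta * self.pssm[c]))))
                thr = min(thr, (-math.log(target_p) + log_mgf) / theta)
            best = max(best, thr)
        return best


@dataclass
class GenomicRegion:
    """0-based half-open interval on the forward strand of a contig."""

    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad region coordinates [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def overlaps(self, other: "GenomicRegion") -> bool:
        return self.contig_id == other.contig_id and self.start < other.end and other.start < self.end


@dataclass
class CandidateGene:
    """One predicted family member with its validation flags."""

    region: GenomicRegion
    protein: SequenceRecord
    profile_score: float = 0.0
    domain_pass: bool = False
    orthology_pass: bool = False
    representative: bool = False


def build_profile(
    core_sequences: Sequence[SequenceRecord],
    domain_fpr: float = 0.01,
    assumed_windows: int = 1000,
) -> Profile:
    """Build a PSSM from up to 6 core orthologues.

    Column scores are ``log2((count + 1) / (n + 20)) - log2(1/20)``
    (add-one pseudocounts against a uniform background); the consensus is
    the per-column majority residue with alphabetic tie-break.  Unaligned
    inputs of unequal length are pairwise-aligned to the first sequence
    first.  The stored ``score_threshold`` is calibrated so a random
    protein of ``assumed_windows`` windows passes with probability at most
    ``domain_fpr``.
    """
    if not core_sequences:
        raise ValueError("cannot build a profile from zero sequences")
    if len(core_sequences) > MAX_TRAINING:
        raise ValueError(
            f"profile training set capped at {MAX_TRAINING} sequences, got {len(core_sequences)}"
        )
    from .align import star_align

    aln = star_align(list(core_sequences))
    rows = list(aln.rows.values())
    n = len(rows)
    length = aln.length
    pssm = np.zeros((length, _N_SYMBOLS))
    consensus = []
    for col in range(length):
        counts = {aa: 0 for aa in AMINO_ACIDS}
        for row in rows:
            ch = row[col]
            if ch in counts:
                counts[ch] += 1
        for aa, cnt in counts.items():
            pssm[col, _AA_INDEX[aa]] = math.log2((cnt + 1) / (n + 20)) - math.log2(1 / 20)
        pssm[col, _X_IDX] = X_SCORE
        pssm[col, _STOP_IDX] = STOP_SCORE
        best = max(counts.values())
        consensus.append(sorted(aa for aa, c in counts.items() if c == best)[0])
    profile = Profile(
        length=length,
        consensus="".join(consensus),
        pssm=pssm,
        training_ids=[r.id for r in core_sequences],
        score_threshold=0.0,
    )
    profile.score_threshold = profile.chernoff_threshold(domain_fpr / assumed_windows)
    return profile


@dataclass
class _Track:
    strand: str
    frame: int
    protein: str
    encoded: np.ndarray
    contig_length: int

    def nt_interval(self, res_start: int, res_end: int) -> tuple[int, int]:
        """Forward-strand nt interval of residues [res_start, res_end)."""
        if self.strand == "+":
            return self.frame + 3 * res_start, self.frame + 3 * res_end
        end = self.contig_length - self.frame - 3 * res_start
        start = self.contig_length - self.frame - 3 * res_end
        return start, end


def six_frame_translate(contig: str | SequenceRecord) -> list[_Track]:
    """All six translated tracks of a contig with exact coordinate maps."""
    seq = contig.seq if isinstance(contig, SequenceRecord) else contig
    L = len(seq)
    rc = reverse_complement(seq)
    tracks = []
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            prot = translate(s[frame:])
            tracks.append(_Track(strand, frame, prot, _encode_protein(prot), L))
    return tracks


def search_regions(
    assembly: Sequence[SequenceRecord],
    profile: Profile,
    threshold: float | None = None,
    per_assembly_fp: float = 0.01,
) -> list[GenomicRegion]:
    """Scan all six frames of every contig for profile-scoring windows.

    Windows scoring at or above the threshold are merged when they overlap
    on the same strand and frame and reported as nucleotide regions.  The
    default threshold is Chernoff-calibrated so the expected number of
    false-positive windows in the whole assembly is ``per_assembly_fp``.
    """
    if threshold is None:
        total_windows = 0
        for rec in assembly:
            per_track = max(0, len(rec.seq) // 3 - profile.length + 1)
            total_windows += 6 * per_track
        if total_windows == 0:
            return []
        threshold = max(
            profile.score_threshold,
            profile.chernoff_threshold(per_assembly_fp / total_windows),
        )
    regions: list[GenomicRegion] = []
    for rec in assembly:
        for track in six_frame_translate(rec):
            scores = profile.scan(track.encoded)
            hits = np.nonzero(scores >= threshold)[0]
            if len(hits) == 0:
                continue
            # merge runs of overlapping windows (window i covers residues
            # [i, i + L)), so gaps < L merge)
            run_start = prev = int(hits[0])
            best = float(scores[hits[0]])
            merged: list[tuple[int, int, float]] = []
            for h in hits[1:]:
                h = int(h)
                if h - prev < profile.length:
                    best = max(best, float(scores[h]))
                else:
                    merged.append((run_start, prev + profile.length, best))
                    run_start = h
                    best = float(scores[h])
                prev = h
            merged.append((run_start, prev + profile.length, best))
            for res_start, res_end, score in merged:
                start, end = track.nt_interval(res_start, res_end)
                regions.append(
                    GenomicRegion(rec.id, start, end, track.strand, track.frame, score)
                )
    regions.sort(key=lambda r: (r.contig_id, r.start, r.strand, r.frame))
    return regions


def extend_region(region: GenomicRegion, contig_length: int, flank: int = DEFAULT_FLANK) -> GenomicRegion:
    """Extend a hit region by ``flank`` nt on either side, clipped to the contig."""
    return GenomicRegion(
        region.contig_id,
        max(0, region.start - flank),
        min(contig_length, region.end + flank),
        region.strand,
        region.frame,
        region.score,
    )


def predict_gene(
    extended_region: GenomicRegion,
    contig: SequenceRecord,
    hit_region: GenomicRegion | None = None,
    min_codons: int = MIN_ORF_CODONS,
) -> SequenceRecord | None:
    """Predict the gene in a candidate region as its longest open reading frame.

    All ORFs on the region's strand are considered: ATG..stop, plus
    edge-truncated open stretches at the region borders.  Among those that
    overlap the original hit (when given) and reach ``min_codons``, the
    longest wins (ties: leftmost).  Returns ``None``, with a logged
    reason, when no acceptable ORF exists.
    """
    sub = contig.seq[extended_region.start : extended_region.end]
    s = sub if extended_region.strand == "+" else reverse_complement(sub)
    L = len(s)
    candidates: list[tuple[int, int, str]] = []  # (codons, fwd_start, protein)
    for frame in range(3):
        prot = translate(s[frame:])
        # split into stop-delimited segments
        seg_start = 0
        for k, ch in enumerate(prot + "*"):
            if ch != "*":
                continue
            seg = prot[seg_start:k]
            has_stop = k < len(prot)  # the '*' is real, not the sentinel
            if seg:
                starts = []
                m_idx = seg.find("M")
                if m_idx >= 0:
                    starts.append(m_idx)  # classic ATG..stop / ATG..edge
                if seg_start == 0:
                    starts.append(0)  # 5'-truncated at the region border
                for s0 in sorted(set(starts)):
                    orf = seg[s0:]
                    if len(orf) < min_codons:
                        continue
                    res_start = seg_start + s0
                    res_end = seg_start + len(seg)
                    if extended_region.strand == "+":
                        fwd_start = extended_region.start + frame + 3 * res_start
                        fwd_end = extended_region.start + frame + 3 * res_end
                    else:
                        fwd_end = extended_region.end - frame - 3 * res_start
                        fwd_start = extended_region.end - frame - 3 * res_end
                    if hit_region is not None:
                        if not (fwd_start < hit_region.end and hit_region.start < fwd_end):
                            continue
                    candidates.append((len(orf), fwd_start, orf))
            seg_start = k + 1
    if not candidates:
        logger.info(
            "no ORF >= %d codons overlapping the hit in %s:[%d,%d)%s",
            min_codons, extended_region.contig_id, extended_region.start,
            extended_region.end, extended_region.strand,
        )
        return None
    candidates.sort(key=lambda c: (-c[0], c[1]))
    n_codons, fwd_start, prot = candidates[0]
    gene_id = f"{extended_region.contig_id}:{fwd_start}{extended_region.strand}"
    return SequenceRecord(gene_id, prot)


def annotate_domain(protein: SequenceRecord | str, domain_profile: Profile) -> tuple[float, bool]:
    """Best profile-window score over the protein and the pass/fail call."""
    seq = protein.seq if isinstance(protein, SequenceRecord) else protein
    if len(seq) < domain_profile.length:
        logger.info("protein shorter than domain profile (%d < %d)", len(seq), domain_profile.length)
        return float("-inf"), False
    scores = domain_profile.scan(_encode_protein(seq))
    best = float(scores.max())
    return best, bool(best >= domain_profile.score_threshold)


def check_orthology(
    candidate: SequenceRecord,
    seed_species_proteome: Sequence[SequenceRecord],
    seed_id: str,
    co_orthologue_ids: Iterable[str] = (),
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> bool:
    """Reciprocal-best-hit orthology check against the seed species proteome.

    True iff the candidate's best-scoring global-alignment partner in the
    proteome is the seed gene or one of its listed co-orthologues.  Score
    ties resolve to the lexicographically smallest id, so the check is
    deterministic.
    """
    if not seed_species_proteome:
        raise ValueError("empty seed-species proteome")
    accepted = {seed_id, *co_orthologue_ids}
    best_id, best_score = None, -math.inf
    for rec in sorted(seed_species_proteome, key=lambda r: r.id):
        sc = alignment_score(candidate.seq, rec.seq, gap_open=gap_open, gap_extend=gap_extend)
        if sc > best_score:
            best_id, best_score = rec.id, sc
    return best_id in accepted


def select_representative(
    co_orthologues: Sequence[CandidateGene],
    seed_protein: SequenceRecord,
) -> CandidateGene:
    """Pick the co-orthologue most similar to the seed for tree building.

    Argmax of the global alignment score against the seed protein; ties
    break by lexicographic gene id.
    """
    if not co_orthologues:
        raise ValueError("no co-orthologues to select from")
    scored = sorted(
        co_orthologues,
        key=lambda c: (-alignment_score(c.protein.seq, seed_protein.seq), c.protein.id),
    )
    chosen = scored[0]
    chosen.representative = True
    return chosen


def search_assembly(
    assembly: Sequence[SequenceRecord],
    profile: Profile,
    seed_protein: SequenceRecord,
    seed_species_proteome: Sequence[SequenceRecord] | None = None,
    flank: int = DEFAULT_FLANK,
    min_codons: int = MIN_ORF_CODONS,
) -> list[CandidateGene]:
    """Full targeted search of one assembly: scan, extend, predict, validate."""
    contigs = {rec.id: rec for rec in assembly}
    candidates: list[CandidateGene] = []
    for region in search_regions(assembly, profile):
        contig = contigs[region.contig_id]
        extended = extend_region(region, len(contig.seq), flank)
        protein = predict_gene(extended, contig, hit_region=region, min_codons=min_codons)
        if protein is None:
            continue
        score, dom_pass = annotate_domain(protein, profile)
        cand = CandidateGene(region=region, protein=protein, profile_score=score, domain_pass=dom_pass)
        if seed_species_proteome is not None:
            cand.orthology_pass = check_orthology(
                protein, seed_species_proteome, seed_id=seed_protein.id
            )
        else:
            cand.orthology_pass = dom_pass
        candidates.append(cand)
    accepted = [c for c in candidates if c.domain_pass and c.orthology_pass]
    if accepted:
        select_representative(accepted, seed_protein)
    return candidates
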