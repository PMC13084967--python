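"""Synthetic genomes with planted gene-family histories.

The generator produces everything the analysis chain consumes, together
with a full truth table, so that every downstream stage (taxonomic
screening, targeted search, profiling, tree analysis) can be verified
end-to-end without external data:

* a Yule species tree with positive branch lengths;
* a gene-family history on that tree — a single origin followed by
  per-copy duplication/loss events (linear birth–death along branches) and
  optional forced events including horizontal transfers;
* protein sequences diverged along the implied gene tree under a 20-state
  Jukes–Cantor-like model (per-site Poisson replacement events, each
  drawing uniformly from the 19 other residues);
* nucleotide contigs with the proteins reverse-translated (uniform
  synonymous codons) and planted as single-exon genes, plus random
  intergenic background;
* contaminant contigs carrying genes from a foreign lineage;
* homology hit tables whose bit scores decay exponentially with taxonomic
  distance from the true source taxon, plus Gaussian noise.

Determinism: every operation is a pure function of its inputs and a seed;
independent per-stage streams are derived from the master seed with
``numpy.random.SeedSequence(seed, spawn_key=(stage,))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .formats import HitRecord, SequenceRecord
from .taxonomy import Taxonomy

__all__ = [
    "SimulationConfig",
    "AssemblySpec",
    "EventTruth",
    "GeneNode",
    "PlantedLocus",
    "SyntheticDataset",
    "stage_rng",
    "simulate_species_tree",
    "label_branches",
    "simulate_gene_family",
    "evolve_sequences",
    "plant_genes",
    "extract_locus",
    "inject_contamination",
    "simulate_hit_table",
    "build_world_taxonomy",
    "simulate_dataset",
    "default_seed_protein",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# integer stream keys, one per stage, hung off the master seed
_STAGES = {
    "species_tree": 1,
    "gene_family": 2,
    "sequences": 3,
    "planting": 4,
    "contamination": 5,
    "hits": 6,
    "metadata": 7,
    "foreign": 8,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent PRNG stream for one simulation stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; defaults are the conditions the
    analysis is designed for (see docs/methods.md)."""

    n_species: int = 20
    seed: int = 0
    duplication_rate: float = 0.0
    loss_rate: float = 0.0
    substitution_rate: float = 0.2
    contig_length: int = 6000
    n_contigs: int = 10
    flank: int = 500
    contamination_fraction: float = 0.0
    hit_noise_sd: float = 0.0
    base_bitscore: float = 200.0
    bitscore_decay: float = 0.3
    forced_events: list[tuple] | None = None
    origin_branch: str | None = None  # default: root

    def validate(self, protein_length: int | None = None) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        for name in ("duplication_rate", "loss_rate", "substitution_rate", "hit_noise_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValueError("contamination_fraction must lie in [0, 1]")
        if protein_length is not None and self.contig_length < 3 * protein_length + 2 * self.flank:
            raise ValueError(
                f"contig_length {self.contig_length} too small for a "
                f"{protein_length}-residue gene with {self.flank} nt flanks"
            )


@dataclass
class AssemblySpec:
    """Shape of one synthetic assembly: contig count/size and flank spacing."""

    contig_length: int = 6000
    n_contigs: int = 10
    flank: int = 500


@dataclass
class GeneNode:
    """One lineage segment of the simulated gene tree."""

    length: float = 0.0
    children: list["GeneNode"] = field(default_factory=list)
    species: str | None = None  # set on extant tip copies
    copy_id: str | None = None
    alive: bool = True

    def tips(self) -> list["GeneNode"]:
        if self.species is not None:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out


@dataclass
class PlantedLocus:
    species: str
    contig_id: str
    start: int  # 0-based half-open, forward-strand coordinates
    end: int
    strand: str  # '+' or '-'
    protein_id: str


@dataclass
class EventTruth:
    """Ground truth of a simulated gene-family history."""

    origin_branch: str
    duplications: list[str] = field(default_factory=list)
    losses: list[str] = field(default_factory=list)
    transfers: list[tuple[str, str]] = field(default_factory=list)
    per_tip_copy_number: dict[str, int] = field(default_factory=dict)
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    contaminant_contigs: dict[str, dict[str, int]] = field(default_factory=dict)
    gene_tree: GeneNode | None = None

    def to_dict(self) -> dict:
        return {
            "origin_branch": self.origin_branch,
            "duplications": list(self.duplications),
            "losses": list(self.losses),
            "transfers": [list(t) for t in self.transfers],
            "per_tip_copy_number": dict(self.per_tip_copy_number),
            "planted_loci": [vars(l) for l in self.planted_loci],
            "contaminant_contigs": {s: dict(c) for s, c in self.contaminant_contigs.items()},
        }


# ---------------------------------------------------------------- species tree


def simulate_species_tree(n_species: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Yule (pure-birth) species tree with ``n_species`` leaves.

    Exponential waiting times between speciations; every extant lineage is
    equally likely to split.  Leaves are labelled ``sp01 .. spNN`` in
    traversal order; all branch lengths are positive and the tree is
    ultrametric.  Identical seeds give byte-identical Newick output.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = stage_rng(seed, "species_tree")
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    root.birth = 0.0
    active = []
    for _ in range(2):  # the root split starts the clock
        child = dendropy.Node()
        child.birth = 0.0
        root.add_child(child)
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.end = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth = t
            parent.add_child(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for leaf in active:
        leaf.end = t_end
    # convert birth/end times to edge lengths
    for node in tree.preorder_node_iter():
        node.edge.length = None if node is root else node.end - node.birth
    ns = tree.taxon_namespace
    width = max(2, len(str(n_species)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = ns.new_taxon(label=f"sp{i:0{width}d}")
        leaf.taxon = taxon
    return tree


def label_branches(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    """Assign stable branch ids: ``root`` for the seed node, leaf labels for
    leaves, ``n01..`` preorder for internal nodes.  Returns id -> node."""
    mapping: dict[str, dendropy.Node] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            label = "root"
        elif node.is_leaf():
            label = node.taxon.label
        else:
            counter += 1
            label = f"n{counter:02d}"
        node.branch_id = label
        if not node.is_leaf() and node.label is None:
            node.label = label
        mapping[label] = node
    return mapping


# ---------------------------------------------------------------- gene family


def _birth_death_on_branch(
    lineages: list[GeneNode],
    branch_id: str,
    length: float,
    dup_rate: float,
    loss_rate: float,
    rng: np.random.Generator,
    truth: EventTruth,
    forced_here: list[tuple],
    pending_transfers: dict[str, list[GeneNode]],
) -> list[GeneNode]:
    """Run per-copy duplication/loss along one branch; returns survivors."""
    # forced events fire at the branch midpoint, before stochastic replay of
    # the remaining half; adequate for the rates-0 scenarios they serve
    for ev in forced_here:
        kind = ev[0]
        if not lineages:
            raise ValueError(f"forced {kind} on branch {branch_id!r} with no gene copy present")
        target = lineages[0]
        if kind == "duplication":
            target.length += length / 2
            a, b = GeneNode(), GeneNode()
            target.children = [a, b]
            lineages = [a, b] + lineages[1:]
            truth.duplications.append(branch_id)
            length = length / 2  # remaining time for the daughters
        elif kind == "loss":
            target.length += length / 2
            target.alive = False
            lineages = lineages[1:]
            truth.losses.append(branch_id)
        elif kind == "transfer":
            donor, recipient = ev[1], ev[2]
            target.length += length / 2
            stay = GeneNode()
            moved = GeneNode()
            target.children = [stay, moved]
            lineages = [stay] + lineages[1:]
            pending_transfers.setdefault(recipient, []).append(moved)
            truth.transfers.append((donor, recipient))
            length = length / 2
        else:
            raise ValueError(f"unknown forced event kind {kind!r}")
    survivors: list[GeneNode] = []
    stack = [(g, length) for g in lineages]
    while stack:
        g, remaining = stack.pop(0)
        t = 0.0
        while True:
            wd = rng.exponential(1.0 / dup_rate) if dup_rate > 0 else math.inf
            wl = rng.exponential(1.0 / loss_rate) if loss_rate > 0 else math.inf
            w = min(wd, wl)
            if t + w >= remaining:
                g.length += remaining - t
                survivors.append(g)
                break
            t += w
            g.length += w
            if wd <= wl:
                truth.duplications.append(branch_id)
                a, b = GeneNode(), GeneNode()
                g.children = [a, b]
                stack.append((a, remaining - t))
                stack.append((b, remaining - t))
                break
            truth.losses.append(branch_id)
            g.alive = False
            break
    return survivors


def simulate_gene_family(
    species_tree: dendropy.Tree,
    config: SimulationConfig,
) -> EventTruth:
    """Simulate one gene-family history down the species tree.

    A single copy originates on ``config.origin_branch`` (default: the
    root) and then undergoes linear birth–death (duplication/loss) per copy
    along every branch.  ``config.forced_events`` injects deterministic
    events: ``("duplication", branch)``, ``("loss", branch)`` or
    ``("transfer", donor_branch, recipient_branch)``.  With all rates zero
    and the origin at the root, every tip carries exactly one copy.
    The returned truth is checked against an aggregate count replay.
    """
    config.validate()
    rng = stage_rng(config.seed, "gene_family")
    branches = label_branches(species_tree)
    origin = config.origin_branch or "root"
    if origin not in branches:
        raise ValueError(f"origin branch {origin!r} not in species tree")
    forced = list(config.forced_events or [])
    for ev in forced:
        for b in ev[1:]:
            if b not in branches:
                raise ValueError(f"forced event references unknown branch {b!r}")
    forced_by_branch: dict[str, list[tuple]] = {}
    for ev in forced:
        key = ev[1]  # loss/dup branch, or transfer donor branch
        forced_by_branch.setdefault(key, []).append(ev)

    truth = EventTruth(origin_branch=origin)
    root_gene = GeneNode()
    truth.gene_tree = root_gene
    pending: dict[str, list[GeneNode]] = {}

    def descend(node: dendropy.Node, entering: list[GeneNode]) -> None:
        bid = node.branch_id
        blen = node.edge.length or 0.0
        incoming = list(entering)
        extra = pending.pop(bid, [])
        # transferred copies land at the branch midpoint
        survivors = []
        if incoming or forced_by_branch.get(bid):
            survivors = _birth_death_on_branch(
                incoming, bid, blen, config.duplication_rate, config.loss_rate,
                rng, truth, forced_by_branch.get(bid, []), pending,
            )
        if extra:
            survivors += _birth_death_on_branch(
                extra, bid, blen / 2, config.duplication_rate, config.loss_rate,
                rng, truth, [], pending,
            )
        if node.is_leaf():
            for g in survivors:
                g.species = node.taxon.label
            return
        for child in node.child_nodes():
            handles = []
            for g in survivors:
                h = GeneNode()
                g.children.append(h)
                handles.append(h)
            descend(child, handles)

    origin_node = branches[origin]
    if origin_node is species_tree.seed_node:
        descend_children = origin_node.child_nodes()
        survivors = [root_gene]
        for child in descend_children:
            handles = []
            for g in survivors:
                h = GeneNode()
                g.children.append(h)
                handles.append(h)
            descend(child, handles)
    else:
        # the copy appears at the midpoint of the origin branch
        blen = origin_node.edge.length or 0.0
        survivors = _birth_death_on_branch(
            [root_gene], origin, blen / 2, config.duplication_rate,
            config.loss_rate, rng, truth, [], pending,
        )
        if origin_node.is_leaf():
            for g in survivors:
                g.species = origin_node.taxon.label
        else:
            for child in origin_node.child_nodes():
                handles = []
                for g in survivors:
                    h = GeneNode()
                    g.children.append(h)
                    handles.append(h)
                descend(child, handles)
    if pending:
        raise ValueError(f"transfer recipients never reached: {sorted(pending)}")

    # tip copy numbers, with deterministic copy ids
    counts: dict[str, int] = {leaf.taxon.label: 0 for leaf in species_tree.leaf_node_iter()}
    per_species_counter: dict[str, int] = {}
    for tip in truth.gene_tree.tips():
        sp = tip.species
        per_species_counter[sp] = per_species_counter.get(sp, 0) + 1
        tip.copy_id = f"{sp}|g{per_species_counter[sp]}"
        counts[sp] += 1
    truth.per_tip_copy_number = counts
    _assert_replay_consistent(species_tree, truth)
    return truth


def _assert_replay_consistent(species_tree: dendropy.Tree, truth: EventTruth) -> None:
    """Aggregate count replay of the event list must reproduce tip counts."""
    from collections import Counter

    dups = Counter(truth.duplications)
    losses = Counter(truth.losses)
    transfers_in = Counter(r for _, r in truth.transfers)

    def replay(node: dendropy.Node, n_in: int) -> dict[str, int]:
        bid = node.branch_id
        n = n_in + dups[bid] - losses[bid] + transfers_in[bid]
        if n < 0:
            raise AssertionError(f"replay drove copy number negative on branch {bid!r}")
        if node.is_leaf():
            return {node.taxon.label: n}
        out: dict[str, int] = {}
        for child in node.child_nodes():
            out.update(replay(child, n))
        return out

    origin_node = next(
        n for n in species_tree.preorder_node_iter() if n.branch_id == truth.origin_branch
    )
    expected: dict[str, int] = {leaf.taxon.label: 0 for leaf in species_tree.leaf_node_iter()}
    if origin_node is species_tree.seed_node:
        for child in origin_node.child_nodes():
            expected.update(replay(child, 1))
    else:
        bid = origin_node.branch_id
        n = 1 + dups[bid] - losses[bid] + transfers_in[bid]
        if origin_node.is_leaf():
            expected[origin_node.taxon.label] = n
        else:
            for child in origin_node.child_nodes():
                expected.update(replay(child, n))
    if expected != truth.per_tip_copy_number:
        raise AssertionError(
            f"event replay mismatch: replay {expected} vs simulated {truth.per_tip_copy_number}"
        )


# ---------------------------------------------------------------- sequences


def expected_diff_fraction(rate: float, t: float) -> float:
    """Exact expected fraction of differing sites after time ``t``.

    For per-site Poisson(rate*t) replacement events each drawing uniformly
    from the other 19 residues, the 20-state chain gives
    P(diff) = (19/20) * (1 - exp(-(20/19) * rate * t)).
    """
    return 19.0 / 20.0 * (1.0 - math.exp(-20.0 / 19.0 * rate * t))


def _mutate(seq: np.ndarray, rate: float, t: float, rng: np.random.Generator, pin_first: bool) -> np.ndarray:
    out = seq.copy()
    n_events = rng.poisson(rate * t, size=len(seq))
    if pin_first:
        n_events[0] = 0
    for site in np.nonzero(n_events)[0]:
        state = out[site]
        for _ in range(n_events[site]):
            step = int(rng.integers(19))
            state = step if step < state else step + 1  # uniform over the other 19
        out[site] = state
    return out


def evolve_sequences(
    seed_protein: str,
    species_tree: dendropy.Tree,
    truth: EventTruth,
    substitution_rate: float,
    seed: int,
) -> list[SequenceRecord]:
    """Evolve the seed protein along the simulated gene tree.

    One output record per extant (tip, copy), ids ``species|gN``.  With
    rate 0 every sequence equals the seed.  When the seed starts with M the
    initiator methionine is held invariant so planted genes stay valid
    ATG-initiated single-exon genes (start-codon conservation).
    """
    if not seed_protein:
        raise ValueError("seed protein must be non-empty")
    if len(seed_protein) < 30:
        raise ValueError("seed protein must be at least 30 residues")
    if truth.gene_tree is None:
        raise ValueError("truth carries no gene tree (was simulate_gene_family run?)")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES["sequences"],)))
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    try:
        root_seq = np.array([index[a] for a in seed_protein], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"seed protein contains non-standard residue {exc}") from exc
    pin = seed_protein[0] == "M"
    records: list[SequenceRecord] = []

    def walk(node: GeneNode, seq: np.ndarray) -> None:
        seq = _mutate(seq, substitution_rate, node.length, rng, pin)
        if node.species is not None:
            records.append(
                SequenceRecord(node.copy_id, "".join(AMINO_ACIDS[i] for i in seq))
            )
            return
        for child in node.children:
            walk(child, seq)

    walk(truth.gene_tree, root_seq)
    return records


# ---------------------------------------------------------------- planting

_CODONS = {  # standard genetic code, amino acid -> codon list
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG", "TGA"]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniformly chosen synonymous codons."""
    codons = []
    for aa in protein:
        options = _CODONS[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def _random_background(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def plant_genes(
    spec: AssemblySpec,
    proteins: Sequence[SequenceRecord],
    truth: EventTruth,
    seed: int,
    species: str | None = None,
    contig_prefix: str | None = None,
) -> tuple[dict[str, list[SequenceRecord]], EventTruth]:
    """Plant proteins as single-exon genes in random-background contigs.

    Each gene cassette is ``TAA + CDS + stop`` (the in-frame TAA upstream
    prevents the open reading frame from extending into background), with
    strand chosen at random and loci separated by at least ``2 * flank``
    background nucleotides.  The planted locus covers exactly the CDS, so
    strand-aware extraction + translation reproduces the protein.
    Per-species contigs are returned together with the truth updated with
    ``planted_loci``.  Species simulated with zero copies get pure
    background contigs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES["planting"],)))
    by_species: dict[str, list[SequenceRecord]] = {}
    for rec in proteins:
        sp = rec.id.split("|")[0]
        by_species.setdefault(sp, []).append(rec)
    if species is not None:
        all_species = [species]
    else:
        all_species = sorted(set(truth.per_tip_copy_number) | set(by_species))
    assemblies: dict[str, list[SequenceRecord]] = {}
    for sp in all_species:
        prefix = contig_prefix or f"{sp}_ctg"
        contigs = [
            list(_random_background(spec.contig_length, rng))
            for _ in range(spec.n_contigs)
        ]
        contig_ids = [f"{prefix}{i + 1:03d}" for i in range(spec.n_contigs)]
        cursor = spec.flank
        contig_idx = 0
        for rec in by_species.get(sp, []):
            cds = reverse_translate(rec.seq, rng)
            stop = _STOPS[int(rng.integers(3))]
            cassette = "TAA" + cds + stop
            gap = 2 * spec.flank + int(rng.integers(spec.flank + 1))
            while contig_idx < spec.n_contigs and cursor + len(cassette) + spec.flank > spec.contig_length:
                contig_idx += 1
                cursor = spec.flank
            if contig_idx >= spec.n_contigs:
                raise ValueError(
                    f"contig capacity exceeded for species {sp!r}: "
                    f"{len(by_species[sp])} genes do not fit {spec.n_contigs} x {spec.contig_length} nt"
                )
            strand = "+" if rng.integers(2) == 0 else "-"
            insert = cassette if strand == "+" else reverse_complement(cassette)
            start = cursor + 3
            end = start + 3 * len(rec.seq)
            contigs[contig_idx][cursor : cursor + len(cassette)] = list(insert)
            truth.planted_loci.append(
                PlantedLocus(sp, contig_ids[contig_idx], start, end, strand, rec.id)
            )
            cursor += len(cassette) + gap
        assemblies[sp] = [
            SequenceRecord(cid, "".join(chars)) for cid, chars in zip(contig_ids, contigs)
        ]
    return assemblies, truth


def extract_locus(contig_seq: str, locus: PlantedLocus) -> str:
    """Strand-aware CDS extraction for a planted locus."""
    sub = contig_seq[locus.start : locus.end]
    return sub if locus.strand == "+" else reverse_complement(sub)


def inject_contamination(
    assembly: list[SequenceRecord],
    foreign_proteins: Sequence[SequenceRecord],
    fraction: float,
    seed: int,
    foreign_taxid: int = 0,
    contig_length: int = 6000,
    flank: int = 500,
) -> tuple[list[SequenceRecord], dict[str, int], list[PlantedLocus]]:
    """Append foreign-lineage contigs to an assembly.

    ``round(fraction * len(assembly))`` contigs are appended, each carrying
    one foreign gene planted exactly like native genes.  Returns the
    extended assembly, labels mapping contaminant contig id -> source
    taxid, and the loci of the planted foreign genes.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"contamination fraction must lie in [0, 1], got {fraction}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES["contamination"],)))
    n_foreign = round(fraction * len(assembly))
    if n_foreign == 0:
        return list(assembly), {}, []
    if not foreign_proteins:
        raise ValueError("no foreign proteins supplied")
    out = list(assembly)
    labels: dict[str, int] = {}
    loci: list[PlantedLocus] = []
    for i in range(n_foreign):
        rec = foreign_proteins[i % len(foreign_proteins)]
        contig = list(_random_background(contig_length, rng))
        cds = reverse_translate(rec.seq, rng)
        stop = _STOPS[int(rng.integers(3))]
        cassette = "TAA" + cds + stop
        max_pos = contig_length - len(cassette) - flank
        pos = flank + int(rng.integers(max(1, max_pos - flank)))
        strand = "+" if rng.integers(2) == 0 else "-"
        insert = cassette if strand == "+" else reverse_complement(cassette)
        contig[pos : pos + len(cassette)] = list(insert)
        cid = f"contam_{i + 1:03d}"
        out.append(SequenceRecord(cid, "".join(contig)))
        labels[cid] = foreign_taxid
        loci.append(PlantedLocus("", cid, pos + 3, pos + 3 + 3 * len(rec.seq), strand, f"{cid}|{rec.id}"))
    return out, labels, loci


# ---------------------------------------------------------------- hit tables


def simulate_hit_table(
    query_id: str,
    true_source_taxid: int,
    taxonomy: Taxonomy,
    hit_noise_sd: float,
    seed: int,
    base_score: float = 200.0,
    decay: float = 0.3,
    subject_taxids: Iterable[int] | None = None,
) -> list[HitRecord]:
    """Simulate a reference-database hit table for one query.

    Bit scores decay exponentially with taxonomic path distance from the
    true source taxon (``base * exp(-decay * d)``) plus Gaussian noise; a
    self-hit (subject_id == query_id) with strictly maximal score is always
    present, mirroring the trivial self-match every database search
    returns.
    """
    from .taxonomy import TaxonomyError

    if true_source_taxid not in taxonomy:
        raise TaxonomyError(f"unknown source taxid {true_source_taxid}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES["hits"],)))
    if subject_taxids is None:
        subjects = [t for t in taxonomy.taxids() if taxonomy.rank(t) == "species"]
        if true_source_taxid not in subjects:
            subjects.append(true_source_taxid)
    else:
        subjects = list(subject_taxids)
        for t in subjects:
            if t not in taxonomy:
                raise TaxonomyError(f"unknown subject taxid {t}")
    hits = [
        HitRecord(query_id, query_id, true_source_taxid, round(base_score * 1.2, 4), 1e-180)
    ]
    for t in sorted(subjects):
        d = taxonomy.distance(true_source_taxid, t)
        score = base_score * math.exp(-decay * d)
        if hit_noise_sd > 0:
            score += rng.normal(0.0, hit_noise_sd)
        score = max(score, 0.1)
        evalue = min(10.0, 10.0 ** (2 - score / 10.0))
        hits.append(HitRecord(query_id, f"ref{t}", t, round(score, 4), evalue))
    return hits


# ---------------------------------------------------------------- world


def default_seed_protein(length: int = 180) -> str:
    """Synthetic seed protein standing in for a fungal GH45 cellulase.

    Generated once from a fixed PRNG constant; starts with an initiator M.
    It is a synthetic stand-in, not a real GH45 sequence.
    """
    rng = np.random.default_rng(np.random.SeedSequence(20450))
    body = "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length - 1)])
    return "M" + body


def build_world_taxonomy(species_tree: dendropy.Tree) -> tuple[Taxonomy, dict[str, int], dict]:
    """Build a toy tree-of-life taxonomy around the simulated species tree.

    Root (1) splits into a target kingdom (2) holding the target phylum
    (10) — under which the species tree is mirrored node-for-node — and a
    foreign kingdom (3) with a foreign phylum (11) and three foreign
    species (101..103).  Returns (taxonomy, species -> taxid, info dict).
    """
    label_branches(species_tree)
    rows = [
        (1, 1, "root", "cellular organisms"),
        (2, 1, "kingdom", "TargetKingdom"),
        (3, 1, "kingdom", "ForeignKingdom"),
        (10, 2, "phylum", "TargetPhylum"),
        (11, 3, "phylum", "ForeignPhylum"),
        (101, 11, "species", "foreignA"),
        (102, 11, "species", "foreignB"),
        (103, 11, "species", "foreignC"),
    ]
    next_id = 1000
    node_taxid: dict[str, int] = {}
    species_taxid: dict[str, int] = {}
    for node in species_tree.preorder_node_iter():
        taxid = next_id
        next_id += 1
        node_taxid[node.branch_id] = taxid
        parent = 10 if node is species_tree.seed_node else node_taxid[node.parent_node.branch_id]
        if node.is_leaf():
            rows.append((taxid, parent, "species", node.taxon.label))
            species_taxid[node.taxon.label] = taxid
        else:
            rows.append((taxid, parent, "clade", node.branch_id))
    info = {
        "target_phylum": 10,
        "foreign_phylum": 11,
        "foreign_species": [101, 102, 103],
        "node_taxid": node_taxid,
    }
    return Taxonomy(rows), species_taxid, info


@dataclass
class SpeciesMeta:
    species_id: str
    taxid: int
    busco_completeness: float
    reproduction_mode: str  # sexual | parthenogenetic | unknown
    clade: str

    def __post_init__(self) -> None:
        if not 0 <= self.busco_completeness <= 1:
            raise ValueError("busco_completeness must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, plus the truth."""

    config: SimulationConfig
    species_tree: dendropy.Tree
    taxonomy: Taxonomy
    species_taxid: dict[str, int]
    target_phylum: int
    seed_protein: str
    proteins: list[SequenceRecord]
    foreign_proteins: list[SequenceRecord]
    assemblies: dict[str, list[SequenceRecord]]
    gene_hits: dict[str, dict[str, list[HitRecord]]]  # species -> gene -> hits
    contig_genes: dict[str, dict[str, list[str]]]  # species -> contig -> gene ids
    metadata: list[SpeciesMeta]
    truth: EventTruth


def simulate_dataset(config: SimulationConfig, seed_protein: str | None = None) -> SyntheticDataset:
    """Run the full generator: tree, history, sequences, genomes, hits."""
    seed_protein = seed_protein or default_seed_protein()
    config.validate(protein_length=len(seed_protein))
    tree = simulate_species_tree(config.n_species, config.seed)
    taxonomy, species_taxid, info = build_world_taxonomy(tree)
    truth = simulate_gene_family(tree, config)
    proteins = evolve_sequences(seed_protein, tree, truth, config.substitution_rate, config.seed)

    # foreign-lineage homologues: same family, diverged further
    frng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(_STAGES["foreign"],)))
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    foreign_proteins = []
    for i, ftax in enumerate(info["foreign_species"]):
        arr = np.array([index[a] for a in seed_protein], dtype=np.int64)
        arr = _mutate(arr, 0.5, 1.0, frng, pin_first=True)
        foreign_proteins.append(
            SequenceRecord(f"foreign{i + 1}", "".join(AMINO_ACIDS[j] for j in arr))
        )

    spec = AssemblySpec(config.contig_length, config.n_contigs, config.flank)
    assemblies, truth = plant_genes(spec, proteins, truth, config.seed)

    gene_hits: dict[str, dict[str, list[HitRecord]]] = {}
    contig_genes: dict[str, dict[str, list[str]]] = {}
    locus_by_species: dict[str, list[PlantedLocus]] = {}
    for locus in truth.planted_loci:
        locus_by_species.setdefault(locus.species, []).append(locus)
    hit_seed = 0
    for sp in sorted(assemblies):
        gene_hits[sp] = {}
        contig_genes[sp] = {}
        for locus in locus_by_species.get(sp, []):
            hit_seed += 1
            gene_hits[sp][locus.protein_id] = simulate_hit_table(
                locus.protein_id, species_taxid[sp], taxonomy, config.hit_noise_sd,
                seed=config.seed * 100003 + hit_seed,
                base_score=config.base_bitscore, decay=config.bitscore_decay,
            )
            contig_genes[sp].setdefault(locus.contig_id, []).append(locus.protein_id)
        if config.contamination_fraction > 0:
            ftaxids = info["foreign_species"]
            contaminated, labels, floci = inject_contamination(
                assemblies[sp], foreign_proteins, config.contamination_fraction,
                seed=config.seed * 100003 + hash(sp) % 65536,
                foreign_taxid=ftaxids[0], contig_length=config.contig_length,
                flank=config.flank,
            )
            assemblies[sp] = contaminated
            # distribute sources over the foreign species deterministically
            for j, (cid, _) in enumerate(sorted(labels.items())):
                labels[cid] = ftaxids[j % len(ftaxids)]
            truth.contaminant_contigs[sp] = labels
            for j, locus in enumerate(floci):
                locus.species = sp
                truth.planted_loci.append(
                    PlantedLocus(sp, locus.contig_id, locus.start, locus.end, locus.strand, locus.protein_id)
                )
                hit_seed += 1
                gene_hits[sp][locus.protein_id] = simulate_hit_table(
                    locus.protein_id, labels[locus.contig_id], taxonomy, config.hit_noise_sd,
                    seed=config.seed * 100003 + hit_seed,
                    base_score=config.base_bitscore, decay=config.bitscore_decay,
                )
                contig_genes[sp].setdefault(locus.contig_id, []).append(locus.protein_id)

    mrng = stage_rng(config.seed, "metadata")
    root_children = tree.seed_node.child_nodes()
    clade_a = {l.taxon.label for l in root_children[0].leaf_iter()}
    metadata = []
    for sp in sorted(assemblies):
        mode = "sexual" if mrng.random() < 0.5 else "parthenogenetic"
        completeness = float(mrng.uniform(0.5, 1.0))
        metadata.append(
            SpeciesMeta(sp, species_taxid[sp], completeness, mode,
                        "cladeA" if sp in clade_a else "cladeB")
        )
    return SyntheticDataset(
        config=config,
        species_tree=tree,
        taxonomy=taxonomy,
        species_taxid=species_taxid,
        target_phylum=info["target_phylum"],
        seed_protein=seed_protein,
        proteins=proteins,
        foreign_proteins=foreign_proteins,
        assemblies=assemblies,
        gene_hits=gene_hits,
        contig_genes=contig_genes,
        metadata=metadata,
        truth=truth,
    )
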