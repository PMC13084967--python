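# Methods

This note documents the models, parameter choices and numerical details
behind `ghprospect`, and what the synthetic verification does and does
not establish about real data.

## Problem setting

The package detects members of a protein family (GH45 cellulases,
Pfam Glyco_hydro_45) in unannotated genome assemblies, rules out
microbial contamination as the source of each detection, profiles
presence/absence across a species panel, and characterizes the family's
evolutionary history (independent acquisitions, duplications, losses)
by comparing gene trees with species trees. Each stage is a desk-scale,
fully specified re-statement of a step that production pipelines delegate
to external tools; the decision each stage makes (where is the locus /
what is the protein / is it orthologous / is it foreign) is preserved,
the heavy machinery is not.

## Taxonomic screening

Assignment follows the margin-LCA rule: for a query with hit set `H`,
self-hits (`subject_id == query_id`, all of them, not just the top one)
are removed; with `S* = max bitscore`, the contributing set is
`{h : S_h ≥ (1−m)·S*}` with margin `m = 0.10`. The threshold is
inclusive so that score ties never silently drop taxa. The query is
assigned to the LCA of the contributing taxa; queries with no informative
hit stay unassigned. A gene is flagged as a putative contaminant iff its
assignment is neither an ancestor-or-self nor a descendant of the query
species (descendants cover sub-species resolution in the reference).
Unassigned is never flagged, and at contig level unassigned contigs are
retained — absence of evidence is not treated as contamination. When a
subject is hit multiple times only the hits as given are used; callers
that want per-subject max-bitscore collapsing should pre-aggregate
(the margin is defined on bit scores, and this is the one place where a
different HSP-handling convention could change results on real data).

Properties verified: agreement with a brute-force lineage-intersection
oracle on ≥ 1000 random hit tables (exact), root-ward monotonicity of
the assignment in the margin, and precision = recall = 1 against planted
contamination at zero hit noise.

## Targeted search

* **Profile.** A PSSM over up to 6 training sequences (the cap is part of
  the protocol); column scores `log2((c+1)/(n+20)) − log2(1/20)`.
  Unequal-length training sets are star-aligned to the first sequence.
  Consensus = per-column majority, ties alphabetic.
* **Thresholds by Chernoff bound.** For a target per-window probability
  `p`, the threshold is `min_θ (−log p + Σ_c log M_c(θ))/θ` where `M_c`
  is the column-score moment generating function under the background —
  an exact upper bound, not a Gaussian approximation. Two backgrounds are
  used (uniform amino acids; amino acids as translated from uniform
  random DNA, including stops at 3/64) and the stricter threshold wins.
  The domain filter targets a false-positive rate of 0.01 per protein
  (assuming 1000 windows); the genome scan targets 0.01 expected false
  windows per assembly. Stops score −4, X scores 0.
* **Gene model.** Hit regions (merged overlapping same-strand/frame
  windows) are extended by `flank = 500` nt, clipped at contig bounds
  (idempotent). The gene is the longest open reading frame on the
  region's strand overlapping the original hit: `ATG..stop`, or
  edge-truncated at region borders; minimum 30 codons (GH45 domains
  exceed 100 residues, so micro-ORFs are noise). Coordinates are 0-based
  half-open on the forward strand throughout.
* **Validation.** Domain filter as above; orthology by reciprocal best
  hit: the candidate's best global-alignment partner in the seed-species
  proteome must be the seed (or a listed co-orthologue). Ties resolve to
  the lexicographically smallest id. The representative for tree building
  is the accepted candidate most similar to the seed protein.

## Alignment and trees

Global alignment is affine-gap Needleman–Wunsch (Gotoh), BLOSUM62 by
default, gap of length `k` costing `open + (k−1)·extend`
(open = 10, extend = 1); traceback ties resolve diagonal > up > left, so
output is deterministic. It is verified exactly against exhaustive
alignment enumeration and cross-checked against Biopython's
`PairwiseAligner` scores (the Biopython aligner is never the
implementation).

Distances are p-distances (mismatches / aligned non-gap columns) with an
optional 20-state multiple-hit correction `−(19/20)·ln(1 − (20/19)p)`;
the default is uncorrected, which suffices for the topology-level
conclusions the package draws on clean synthetic data. Trees are built
by Saitou–Nei neighbor joining (deterministic smallest-index tie-break;
negative branch estimates clamped to 0), which provably recovers the
topology on additive inputs — verified on 100 random trees and
cross-checked against scikit-bio's NJ. Gap-column trimming removes
columns with strictly more than 50% gaps; supermatrix construction drops
genes present in fewer than 75% of species (boundary kept) and pads
missing species with gaps. Majority consensus keeps splits in strictly
more than half of the input trees (ties at exactly 50% drop, yielding
polytomies). Outgroup rooting requires the outgroup to be one side of a
split and roots at that branch's midpoint.

Comparative operations: monophyly is exact leaf-set equality of some
clade; independent origins = number of maximal uniform clades (1 ⇔
monophyletic); Dollo reconstruction places the single gain at the LCA of
the present species and takes the maximal empty subtrees below it as
losses, which is the loss-minimal single-gain history (verified by
exhaustive enumeration over all 2^n presence patterns, n ≤ 8). Note that
the minimal loss count is *not* monotone in the presence set when the
gain node moves — a property one might intuitively expect but which is
false in general. Reconciliation uses the standard LCA mapping
(duplication iff a child shares the node's image; losses along mapping
depth gaps), the parsimony minimum, verified against an independent
exhaustive-mapping oracle. The tanglegram minimizes link crossings by
exhaustive subtree rotation for trees up to 8 leaves and greedy rotation
descent beyond (local optimality only, by design); `untangle=False`
scores the trees as drawn.

## Association test

Presence (count ≥ 1 after both filters) is cross-tabulated against
reproduction mode (sexual vs parthenogenetic; unknowns excluded and
reported). The 2×2 chi-squared statistic uses the Yates continuity
correction by default, matching R's `chisq.test` convention for 2×2
tables, with a flag to disable; `p = Q(1/2, X²/2)` through SciPy's
regularized incomplete gamma. Calibration is verified by simulation
(type-I error 5% ± Monte-Carlo error at n = 80, 1000 cohorts; power
≥ 0.8 at odds ratio 10). A phylogenetically corrected association test
would be the statistically preferable extension and is out of scope.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions under which the pipeline is
verified:

* **Species tree** — Yule process, birth rate 1, ultrametric, n species
  (default 20; root-to-tip depth ≈ ln n).
* **Gene-family history** — one origin (default: root), then linear
  birth–death per copy along branches with duplication/loss rates in
  events per unit branch length (defaults 0; typical verification runs
  use 0.05–0.08 so 20 species carry 0–3 copies). Forced events (losses,
  duplications, transfers at branch midpoints) create exactly known
  histories. Tip copy numbers are re-derived by replaying the recorded
  event list and asserted equal after every simulation.
* **Sequences** — per-site Poisson replacement events at rate r per unit
  branch length, each drawing uniformly from the other 19 residues; the
  expected differing-site fraction after time t is exactly
  `(19/20)(1 − exp(−(20/19)rt))`, which the tests assert. Default
  r = 0.2; with tree depth ≈ 3 this gives root-to-tip divergences around
  0.3 substitutions/site, the regime the search is specified to handle.
  The initiator methionine is held invariant (start-codon conservation),
  keeping planted genes discoverable as ATG-initiated ORFs.
* **Genomes** — uniform-random ACGT background (contig length 6000,
  10 contigs/species by default); genes reverse-translated with uniform
  synonymous codons and planted as `TAA + CDS + stop` cassettes (the
  in-frame upstream TAA stops the ORF from extending into background),
  strands random, loci ≥ 2×flank apart.
* **Contamination** — `round(fraction · n_contigs)` appended contigs
  carrying genes from a foreign lineage (same family, heavily diverged),
  labelled with their source taxid.
* **Hit tables** — bit score `b·exp(−λ d)` with `b = 200`, `λ = 0.3`,
  `d` the taxonomic path distance from the true source, plus
  `N(0, σ)` noise; a strictly maximal self-hit is always present.
  Monotone decay is the only property the LCA rule needs, and λ = 0.3
  makes the 10% margin span ≈ 0.35 units of distance, i.e. the margin set
  is the source taxon and its immediate neighborhood.

Deliberately not emulated: introns and frameshifts (single-exon genes
only, so gene prediction is exact), indels in the substitution model
(so planted and recovered proteins stay colinear), codon-usage bias,
assembly errors, and database incompleteness. Passing tests therefore
demonstrate the correctness of the decision rules and their
implementations — not the sensitivity of the search on spliced genes,
nor robustness to real-world reference bias. The per-stage PRNG streams
are split from the master seed with `SeedSequence(seed, spawn_key)`, so
every stage is independently reproducible.

## Problem sizes

Verification runs use 5–20 species, 180-residue proteins, 4–12 contigs
of 4–8 kb per species, hit tables over taxonomies of ≤ 40 nodes, and
exhaustive oracles at ≤ 8 leaves (trees), ≤ 6 residues (alignments) and
≤ 12 hits (margin rule) — sizes where brute-force enumeration is exact
and fast, which is what makes the oracle-equivalence guarantees
meaningful.

## Known limitations

* The ORF-based gene model cannot represent spliced genes; on real
  assemblies it would truncate at intron boundaries.
* RBH orthology is a declared approximation of graph-based orthology
  inference with feature-architecture weighting.
* NJ on p-distances replaces maximum-likelihood inference; fine for
  topology recovery on clean data, not for branch-length interpretation
  at high divergence.
* The tanglegram heuristic does not promise global optimality above 8
  leaves.
* The chi-squared test ignores phylogenetic non-independence of species.
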