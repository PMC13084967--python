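"""Generate a synthetic study: species tree, gene-family history, genomes.

The generator plants diverged copies of a GH45-like protein as
single-exon genes in random-background contigs, adds contaminant contigs
from a foreign lineage, and fabricates homology hit tables whose bit
scores decay with taxonomic distance — all with a full truth table.
"""

from ghprospect.formats import write_newick
from ghprospect.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(
    n_species=8, seed=1, substitution_rate=0.15,
    duplication_rate=0.05, loss_rate=0.05, contamination_fraction=0.2,
)
ds = simulate_dataset(cfg)

print("species tree:", write_newick(ds.species_tree))
print("per-species gene copies:", ds.truth.per_tip_copy_number)
print("duplication branches:", ds.truth.duplications)
print("loss branches:", ds.truth.losses)
n_contam = sum(len(v) for v in ds.truth.contaminant_contigs.values())
print(f"{len(ds.truth.planted_loci)} planted loci, {n_contam} contaminant contigs")
# Copy numbers are the replayed outcome of the simulated event history;
# the contaminant contigs carry genes whose hit tables point at the
# foreign lineage, which is what the screening stage must detect.
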