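import numpy as np
import pytest

from ghprospect.formats import HitRecord
from ghprospect.taxonomy import Taxonomy


@pytest.fixture
def small_taxonomy() -> Taxonomy:
    """Root -> two kingdoms; target phylum with two species, foreign phylum
    with one species."""
    rows = [
        (1, 1, "root", "cellular organisms"),
        (2, 1, "kingdom", "Animals"),
        (3, 1, "kingdom", "Fungi"),
        (10, 2, "phylum", "Arthropoda"),
        (11, 3, "phylum", "Basidiomycota"),
        (100, 10, "species", "springtail"),
        (101, 10, "species", "mite"),
        (102, 11, "species", "fungus"),
    ]
    return Taxonomy(rows)


def random_taxonomy(rng: np.random.Generator, n: int) -> Taxonomy:
    """Random rooted taxonomy with taxids 1..n (1 = root)."""
    rows = [(1, 1, "root", "root")]
    for taxid in range(2, n + 1):
        parent = int(rng.integers(1, taxid))
        rows.append((taxid, parent, "clade", f"t{taxid}"))
    return Taxonomy(rows)


def brute_force_margin_lca(hits, self_id, taxonomy, margin):
    """Independent margin-rule oracle: sort scores, inclusive threshold,
    intersect full root-ward lineages, pick the deepest shared node."""
    informative = [h for h in hits if h.subject_id != self_id]
    if not informative:
        return None
    best = sorted(h.bitscore for h in informative)[-1]
    keep = [h for h in informative if h.bitscore >= (1 - margin) * best]
    lineages = [taxonomy.lineage(h.subject_taxid) for h in keep]
    shared = set(lineages[0])
    for lin in lineages[1:]:
        shared &= set(lin)
    # the deepest shared node is the first shared entry of any lineage
    for t in lineages[0]:
        if t in shared:
            return t
    raise AssertionError("no shared ancestor (broken taxonomy)")


def make_hits(rng: np.random.Generator, taxonomy: Taxonomy, n_hits: int, query="q1"):
    taxids = taxonomy.taxids()
    hits = []
    for _ in range(n_hits):
        hits.append(
            HitRecord(
                query, f"s{int(rng.integers(1_000_000))}",
                int(taxids[int(rng.integers(len(taxids)))]),
                float(np.round(rng.uniform(10, 200), 2)), 1e-10,
            )
        )
    return hits
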