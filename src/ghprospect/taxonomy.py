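"""Taxonomy container with lineage and last-common-ancestor queries.

The taxonomy is a rooted tree of integer taxon ids with parent pointers,
ranks and names, as used for taxonomic assignment of homology hits.  The
root is its own parent (NCBI convention, taxid 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .formats import FormatError, read_taxonomy_table, write_taxonomy_table

__all__ = ["Taxonomy", "TaxonomyError"]


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy table (orphans, cycles, bad root)."""


@dataclass(frozen=True)
class _Node:
    taxid: int
    parent: int
    rank: str
    name: str


class Taxonomy:
    """Rooted taxon-id tree supporting parent, lineage and LCA queries."""

    def __init__(self, rows: Iterable[tuple[int, int, str, str]]):
        nodes: dict[int, _Node] = {}
        roots: list[int] = []
        for taxid, parent, rank, name in rows:
            if taxid in nodes:
                raise TaxonomyError(f"duplicate taxid {taxid}")
            nodes[taxid] = _Node(taxid, parent, rank, name)
            if taxid == parent:
                roots.append(taxid)
        if not nodes:
            raise TaxonomyError("empty taxonomy")
        for node in nodes.values():
            if node.parent not in nodes:
                raise TaxonomyError(f"orphan parent {node.parent} (referenced by taxid {node.taxid})")
        if len(roots) == 0:
            raise TaxonomyError("no root (no row with taxid == parent_taxid)")
        if len(roots) > 1:
            raise TaxonomyError(f"multiple roots: {sorted(roots)}")
        self._nodes = nodes
        self.root = roots[0]
        # cycle check doubles as depth precomputation
        self._depth: dict[int, int] = {self.root: 0}
        for taxid in nodes:
            chain = []
            t = taxid
            while t not in self._depth:
                chain.append(t)
                t = nodes[t].parent
                if t in chain:
                    raise TaxonomyError(f"cycle in taxonomy involving taxid {t}")
            base = self._depth[t]
            for i, c in enumerate(reversed(chain), start=1):
                self._depth[c] = base + i

    @classmethod
    def from_table(cls, path: str | Path) -> "Taxonomy":
        return cls(read_taxonomy_table(path))

    def to_table(self, path: str | Path) -> None:
        rows = [(n.taxid, n.parent, n.rank, n.name) for n in sorted(self._nodes.values(), key=lambda n: n.taxid)]
        write_taxonomy_table(rows, path)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def taxids(self) -> list[int]:
        return sorted(self._nodes)

    def _require(self, taxid: int) -> _Node:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def parent(self, taxid: int) -> int:
        return self._require(taxid).parent

    def rank(self, taxid: int) -> str:
        return self._require(taxid).rank

    def name(self, taxid: int) -> str:
        return self._require(taxid).name

    def depth(self, taxid: int) -> int:
        self._require(taxid)
        return self._depth[taxid]

    def children(self, taxid: int) -> list[int]:
        self._require(taxid)
        return sorted(n.taxid for n in self._nodes.values() if n.parent == taxid and n.taxid != taxid)

    def lineage(self, taxid: int) -> list[int]:
        """Root-ward path from ``taxid`` (inclusive) to the root (inclusive)."""
        node = self._require(taxid)
        path = [node.taxid]
        while node.taxid != self.root:
            node = self._nodes[node.parent]
            path.append(node.taxid)
        return path

    def is_ancestor_or_self(self, ancestor: int, descendant: int) -> bool:
        return ancestor in self.lineage(descendant)

    def lca(self, taxids: Iterable[int]) -> int:
        """Last common ancestor of a non-empty set of taxon ids.

        Deepest node whose subtree contains every input; commutative and
        idempotent by construction (intersection of root-ward lineages).
        """
        taxids = list(taxids)
        if not taxids:
            raise TaxonomyError("lca of empty taxid set")
        common: set[int] | None = None
        for t in taxids:
            lin = set(self.lineage(t))
            common = lin if common is None else common & lin
        assert common  # root is always shared
        return max(common, key=lambda t: self._depth[t])

    def distance(self, a: int, b: int) -> int:
        """Path length (number of edges) between two taxa through their LCA."""
        anc = self.lca([a, b])
        return (self.depth(a) - self.depth(anc)) + (self.depth(b) - self.depth(anc))

    def subtree(self, taxid: int) -> set[int]:
        """All taxids whose lineage passes through ``taxid`` (inclusive)."""
        self._require(taxid)
        return {t for t in self._nodes if taxid in self.lineage(t)}
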