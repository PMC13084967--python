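"""Tree building and gene-family history analysis.

Desk-scale comparative machinery over dendropy trees: neighbor joining on
distance matrices, outgroup rooting, majority-rule consensus, monophyly
and independent-origin counting, Dollo gain/loss reconstruction,
duplication/loss reconciliation of a gene tree against a species tree,
and tanglegram crossing minimization.

All split-based comparisons run on canonical split sets (each split is
the leaf subset not containing a fixed reference leaf), so permuting the
input leaf order never changes an output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "ReconciliationResult",
    "leaf_labels",
    "split_set",
    "rf_distance",
    "nj_tree",
    "root_by_outgroup",
    "majority_consensus",
    "is_monophyletic",
    "count_group_origins",
    "dollo_history",
    "reconcile",
    "tanglegram",
]


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _leafset_below(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def split_set(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Canonical non-trivial splits of a tree, read as unrooted.

    Each split is represented by the side not containing the reference
    leaf (the lexicographically smallest label).
    """
    leaves = frozenset(leaf_labels(tree))
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leafset_below(node)
        if ref in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            splits.add(side)
    return splits


def rf_distance(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Robinson–Foulds distance (symmetric difference of split sets)."""
    if leaf_labels(a) != leaf_labels(b):
        raise ValueError("trees have different leaf sets")
    return len(split_set(a) ^ split_set(b))


# ---------------------------------------------------------------- neighbor joining


def nj_tree(labels: Sequence[str], matrix: np.ndarray) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; exact on additive distance matrices.

    The input must be symmetric with a zero diagonal and non-negative
    entries.  Ties in the Q criterion resolve to the smallest index pair,
    so the output is deterministic.  Negative branch-length estimates are
    clamped to zero.  Fewer than 3 taxa yield the trivial tree.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match labels")
    if not np.allclose(matrix, matrix.T) or not np.allclose(np.diag(matrix), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if (matrix < 0).any():
        raise ValueError("distance matrix must be non-negative")
    tree = dendropy.Tree()
    tree.is_rooted = False
    ns = tree.taxon_namespace
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = ns.new_taxon(label=lab)
        nodes.append(node)
    if n == 0:
        return tree
    if n == 1:
        tree.seed_node.add_child(nodes[0])
        nodes[0].edge.length = 0.0
        return tree
    if n == 2:
        tree.seed_node.add_child(nodes[0])
        tree.seed_node.add_child(nodes[1])
        nodes[0].edge.length = nodes[1].edge.length = matrix[0, 1] / 2
        return tree
    active = list(range(n))
    D = {(i, j): matrix[i, j] for i in range(n) for j in range(n)}
    all_nodes = dict(enumerate(nodes))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        d_ij = D[i, j]
        bi = d_ij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        bj = d_ij - bi
        parent = dendropy.Node()
        parent.add_child(all_nodes[i])
        parent.add_child(all_nodes[j])
        all_nodes[i].edge.length = max(0.0, bi)
        all_nodes[j].edge.length = max(0.0, bj)
        u = next_id
        next_id += 1
        all_nodes[u] = parent
        for k in active:
            if k in (i, j):
                continue
            d = (D[i, k] + D[j, k] - d_ij) / 2
            D[u, k] = D[k, u] = max(0.0, d)
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    center = tree.seed_node
    for x in (i, j, k):
        center.add_child(all_nodes[x])
    all_nodes[i].edge.length = max(0.0, (D[i, j] + D[i, k] - D[j, k]) / 2)
    all_nodes[j].edge.length = max(0.0, (D[i, j] + D[j, k] - D[i, k]) / 2)
    all_nodes[k].edge.length = max(0.0, (D[i, k] + D[j, k] - D[i, j]) / 2)
    return tree


# ---------------------------------------------------------------- rooting


def root_by_outgroup(tree: dendropy.Tree, outgroup_labels: Iterable[str]) -> dendropy.Tree:
    """Root at the midpoint of the branch separating outgroup from ingroup.

    The outgroup must form one side of a split of the unrooted topology;
    otherwise the violating leaves are named in the error.
    """
    outgroup = frozenset(outgroup_labels)
    leaves = frozenset(leaf_labels(tree))
    missing = outgroup - leaves
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")
    if not outgroup or outgroup == leaves:
        raise ValueError("outgroup must be a proper non-empty subset of the leaves")
    tree = tree.clone(depth=1)
    target = None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = _leafset_below(node)
        if below == outgroup or below == leaves - outgroup:
            target = node
            break
    if target is None:
        # name the leaves breaking monophyly: outgroup members inside the
        # best-covering clade plus intruders
        raise ValueError(
            f"outgroup {sorted(outgroup)} does not form one side of any split"
        )
    edge_len = target.edge.length if target.edge.length is not None else 1.0
    tree.reroot_at_edge(target.edge, length1=edge_len / 2, length2=edge_len / 2)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------- consensus


def majority_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Strict-majority consensus: splits in more than 50% of the inputs.

    Inputs must share one leaf set.  Splits at exactly 50% are dropped
    (two conflicting splits in two trees yield a polytomy).  Retained
    splits are mutually compatible by construction, so the consensus is
    assembled directly from their nesting structure.
    """
    if len(trees) < 2:
        raise ValueError("consensus needs at least 2 trees")
    leafsets = [frozenset(leaf_labels(t)) for t in trees]
    if len(set(leafsets)) != 1:
        raise ValueError("input trees have differing leaf sets")
    leaves = leafsets[0]
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for s in split_set(t):
            counts[s] = counts.get(s, 0) + 1
    kept = [s for s, c in counts.items() if c / len(trees) > 0.5]
    kept.sort(key=lambda s: (-len(s), sorted(s)))
    out = dendropy.Tree()
    out.is_rooted = False
    ns = out.taxon_namespace
    root = out.seed_node
    node_for: dict[frozenset[str], dendropy.Node] = {}
    parents: dict[frozenset[str], frozenset[str] | None] = {}
    for s in kept:
        parent = None
        for t in kept:
            if t != s and s < t and (parent is None or t < parent):
                parent = t
        parents[s] = parent
        node = dendropy.Node()
        node.edge.length = 1.0
        node_for[s] = node
    for s in kept:
        p = parents[s]
        (node_for[p] if p is not None else root).add_child(node_for[s])
    for leaf in sorted(leaves):
        holder = None
        for s in kept:
            if leaf in s and (holder is None or s < holder):
                holder = s
        node = dendropy.Node()
        node.taxon = ns.new_taxon(label=leaf)
        node.edge.length = 1.0
        (node_for[holder] if holder is not None else root).add_child(node)
    return out


# ---------------------------------------------------------------- monophyly & origins


def is_monophyletic(rooted_tree: dendropy.Tree, label_set: Iterable[str]) -> bool:
    """True iff some clade's leaf set equals ``label_set`` exactly."""
    target = frozenset(label_set)
    leaves = frozenset(leaf_labels(rooted_tree))
    missing = target - leaves
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    if not target:
        raise ValueError("empty label set")
    for node in rooted_tree.preorder_node_iter():
        if _leafset_below(node) == target:
            return True
    return False


def count_group_origins(
    rooted_gene_tree: dendropy.Tree,
    leaf_to_group: Mapping[str, str],
    group: str,
) -> int:
    """Number of maximal clades whose leaves all belong to ``group``.

    Equals 1 exactly when the group is monophyletic; 0 when the group has
    no leaf in the tree.  This is the formal counterpart of counting
    independent introductions of a gene family into a host clade.
    """
    uniform: dict[int, bool] = {}
    count = 0

    def post(node: dendropy.Node) -> bool:
        if node.is_leaf():
            ok = leaf_to_group.get(node.taxon.label) == group
        else:
            child_flags = [post(c) for c in node.child_nodes()]
            ok = all(child_flags)
        uniform[id(node)] = ok
        return ok

    post(rooted_gene_tree.seed_node)

    def pre(node: dendropy.Node, parent_uniform: bool) -> None:
        nonlocal count
        if uniform[id(node)]:
            if not parent_uniform:
                count += 1
            return
        for c in node.child_nodes():
            pre(c, False)

    pre(rooted_gene_tree.seed_node, False)
    return count


# ---------------------------------------------------------------- Dollo


def _branch_id(node: dendropy.Node) -> str:
    if hasattr(node, "branch_id"):
        return node.branch_id
    if node.is_leaf():
        return node.taxon.label
    return node.label or f"node{id(node) % 10_000}"


def dollo_history(
    rooted_species_tree: dendropy.Tree,
    presence: Mapping[str, int | bool],
) -> tuple[str | None, list[str]]:
    """Single-gain Dollo reconstruction of a presence/absence pattern.

    The gain is placed on the branch to the LCA of all present species;
    losses are the maximal subtrees below the gain containing no present
    species, which minimizes the loss count given one gain.  All-absent
    input yields ``(None, [])``.
    """
    from .simulate import label_branches

    rooted_species_tree.is_rooted = True
    label_branches(rooted_species_tree)
    present = {sp for sp, v in presence.items() if v}
    tree_leaves = leaf_labels(rooted_species_tree)
    unknown = present - tree_leaves
    if unknown:
        raise ValueError(f"present species not in tree: {sorted(unknown)}")
    if not present:
        return None, []
    taxa = [l.taxon for l in rooted_species_tree.leaf_node_iter() if l.taxon.label in present]
    gain_node = (
        rooted_species_tree.find_node_with_taxon_label(next(iter(present)))
        if len(present) == 1
        else rooted_species_tree.mrca(taxa=taxa)
    )
    losses: list[str] = []

    def descend(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            below = _leafset_below(child)
            if below & present:
                descend(child)
            else:
                losses.append(_branch_id(child))

    descend(gain_node)
    return _branch_id(gain_node), sorted(losses)


# ---------------------------------------------------------------- reconciliation


@dataclass
class ReconciliationResult:
    duplications: int
    losses: int
    mapping: dict[str, str]  # gene node id -> species node id


def reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_map: Mapping[str, str],
) -> ReconciliationResult:
    """LCA reconciliation: parsimony duplication and loss counts.

    Every gene leaf must map to a species leaf.  A gene node is a
    duplication iff its species image equals a child's image; losses are
    counted along the depth gaps of the mapping.  The LCA mapping attains
    the parsimony minimum for duplication–loss reconciliation.
    """
    from .simulate import label_branches

    label_branches(gene_tree)
    label_branches(species_tree)
    sp_nodes = {}
    depth = {}
    for node in species_tree.preorder_node_iter():
        sp_nodes[_branch_id(node)] = node
        depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1

    def sp_ancestors(node: dendropy.Node) -> list[dendropy.Node]:
        out = [node]
        while node.parent_node is not None:
            node = node.parent_node
            out.append(node)
        return out

    def sp_lca(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        seen = {id(x) for x in sp_ancestors(a)}
        for x in sp_ancestors(b):
            if id(x) in seen:
                return x
        raise AssertionError("disconnected species tree")

    image: dict[int, dendropy.Node] = {}
    is_dup: dict[int, bool] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab not in leaf_map:
                raise ValueError(f"gene leaf {lab!r} has no species mapping")
            sp_label = leaf_map[lab]
            target = None
            for leaf in species_tree.leaf_node_iter():
                if leaf.taxon.label == sp_label:
                    target = leaf
                    break
            if target is None:
                raise ValueError(f"species {sp_label!r} not in species tree")
            image[id(node)] = target
        else:
            children = node.child_nodes()
            m = image[id(children[0])]
            for c in children[1:]:
                m = sp_lca(m, image[id(c)])
            image[id(node)] = m
            is_dup[id(node)] = any(image[id(c)] is m for c in children)
    dup_count = sum(1 for v in is_dup.values() if v)
    loss_count = 0
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            continue
        for c in node.child_nodes():
            gap = depth[id(image[id(c)])] - depth[id(image[id(node)])]
            loss_count += gap if is_dup[id(node)] else gap - 1
    mapping = {
        _branch_id(g): _branch_id(image[id(g)]) for g in gene_tree.preorder_node_iter()
    }
    return ReconciliationResult(duplications=dup_count, losses=loss_count, mapping=mapping)


# ---------------------------------------------------------------- tanglegram

EXACT_TANGLEGRAM_LEAVES = 8  # exhaustive rotation search up to this size


def _leaf_orders(tree: dendropy.Tree) -> list[list[str]]:
    """All leaf orders reachable by child-order rotations (binary nodes)."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]

    def order_for(flips: tuple[int, ...]) -> list[str]:
        flip_of = dict(zip((id(n) for n in internals), flips))
        out: list[str] = []

        def walk(node: dendropy.Node) -> None:
            if node.is_leaf():
                out.append(node.taxon.label)
                return
            children = node.child_nodes()
            if flip_of[id(node)]:
                children = list(reversed(children))
            for c in children:
                walk(c)

        walk(tree.seed_node)
        return out

    return [order_for(f) for f in itertools.product((0, 1), repeat=len(internals))]


def _crossings(order_a: Sequence[str], order_b: Sequence[str], links: Sequence[tuple[str, str]]) -> int:
    pos_a = {l: i for i, l in enumerate(order_a)}
    pos_b = {l: i for i, l in enumerate(order_b)}
    n = 0
    for (g1, s1), (g2, s2) in itertools.combinations(links, 2):
        if (pos_a[g1] - pos_a[g2]) * (pos_b[s1] - pos_b[s2]) < 0:
            n += 1
    return n


def _current_order(tree: dendropy.Tree) -> list[str]:
    return [l.taxon.label for l in tree.leaf_node_iter()]


def tanglegram(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    links: Sequence[tuple[str, str]],
    untangle: bool = True,
) -> tuple[list[tuple[str, str]], int, tuple[list[str], list[str]]]:
    """Crossing-minimized tanglegram between two trees.

    Links pair gene-tree leaves with species-tree leaves; the crossing
    count is the number of inverted link pairs between the two leaf
    orders.  With ``untangle=False`` the trees' given leaf orders are
    scored as-is.  Otherwise small trees (both <= 8 leaves) are solved
    exactly by exhaustive subtree rotation; larger trees use greedy
    rotation descent until no single rotation reduces crossings.
    """
    g_leaves = leaf_labels(gene_tree)
    s_leaves = leaf_labels(species_tree)
    for g, s in links:
        if g not in g_leaves:
            raise ValueError(f"link references missing gene-tree leaf {g!r}")
        if s not in s_leaves:
            raise ValueError(f"link references missing species-tree leaf {s!r}")
    if not untangle:
        oa, ob = _current_order(gene_tree), _current_order(species_tree)
        return list(links), _crossings(oa, ob, links), (oa, ob)
    if len(g_leaves) <= EXACT_TANGLEGRAM_LEAVES and len(s_leaves) <= EXACT_TANGLEGRAM_LEAVES:
        best = None
        for oa in _leaf_orders(gene_tree):
            for ob in _leaf_orders(species_tree):
                c = _crossings(oa, ob, links)
                if best is None or c < best[0]:
                    best = (c, oa, ob)
        return list(links), best[0], (best[1], best[2])
    ga = gene_tree.clone(depth=1)
    sa = species_tree.clone(depth=1)
    order_a, order_b = _current_order(ga), _current_order(sa)
    current = _crossings(order_a, order_b, links)
    improved = True
    while improved:
        improved = False
        for tree in (ga, sa):
            for node in list(tree.preorder_node_iter()):
                if node.is_leaf():
                    continue
                children = list(node.child_nodes())
                node.set_child_nodes(list(reversed(children)))
                oa, ob = _current_order(ga), _current_order(sa)
                c = _crossings(oa, ob, links)
                if c < current:
                    current = c
                    improved = True
                else:
                    node.set_child_nodes(children)
    return list(links), current, (_current_order(ga), _current_order(sa))
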