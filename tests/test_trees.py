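"""NJ, rooting, consensus, origins, Dollo and reconciliation against
independent brute-force oracles."""

import itertools

import dendropy
import numpy as np
import pytest

from ghprospect.formats import read_newick, write_newick
from ghprospect.simulate import label_branches, simulate_species_tree
from ghprospect.trees import (
    count_group_origins,
    dollo_history,
    is_monophyletic,
    majority_consensus,
    nj_tree,
    reconcile,
    rf_distance,
    root_by_outgroup,
    split_set,
    tanglegram,
)

# ------------------------------------------------------------- helpers


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> dendropy.Tree:
    return simulate_species_tree(n_leaves, int(rng.integers(1 << 30)))


def path_distance_matrix(tree: dendropy.Tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return labels, mat


# ------------------------------------------------------------- NJ


class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        t = nj_tree(["a", "b", "c"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]))
        assert len(list(t.leaf_node_iter())) == 3
        assert split_set(t) == set()

    def test_four_taxon_ultrametric_split(self):
        # ((A,B),(C,D)): within-pair distance 2, across 6
        labels = ["A", "B", "C", "D"]
        m = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], dtype=float
        )
        t = nj_tree(labels, m)
        assert split_set(t) == {frozenset({"C", "D"})}

    def test_recovers_topology_from_additive_distances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            true = random_binary_tree(rng, int(rng.integers(4, 17)))
            labels, m = path_distance_matrix(true)
            est = nj_tree(labels, m)
            assert rf_distance(true, est) == 0

    def test_recovers_branch_lengths_on_additive_input(self):
        rng = np.random.default_rng(5)
        true = random_binary_tree(rng, 8)
        labels, m = path_distance_matrix(true)
        est = nj_tree(labels, m)
        _, m2 = path_distance_matrix(est)
        assert np.allclose(m, m2, atol=1e-9)

    def test_agrees_with_skbio_on_random_matrices(self):
        """Independent cross-check: scikit-bio's NJ yields the same topology."""
        import skbio

        rng = np.random.default_rng(9)
        for _ in range(10):
            true = random_binary_tree(rng, 10)
            labels, m = path_distance_matrix(true)
            dm = skbio.DistanceMatrix(m, ids=labels)
            sk = skbio.tree.nj(dm)
            sk_tree = read_newick(str(sk))
            assert rf_distance(nj_tree(labels, m), sk_tree) == 0

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(["a", "b"], np.array([[0, 1], [2, 0.0]]))
        with pytest.raises(ValueError):
            nj_tree(["a", "b"], np.array([[0, -1], [-1, 0.0]]))


# ------------------------------------------------------------- rooting


class TestRooting:
    def test_four_leaf_outgroup(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = root_by_outgroup(t, ["D"])
        kids = rooted.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids]
        assert frozenset({"D"}) in sides

    def test_all_leaves_outgroup_rejected(self):
        t = read_newick("((A,B),C);")
        with pytest.raises(ValueError):
            root_by_outgroup(t, ["A", "B", "C"])

    def test_non_split_outgroup_rejected_with_names(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError, match="A.*C"):
            root_by_outgroup(t, ["A", "C"])

    def test_rooting_preserves_split_set(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            t = random_binary_tree(rng, 8)
            leaf = sorted(l.taxon.label for l in t.leaf_node_iter())[0]
            rooted = root_by_outgroup(t, [leaf])
            assert split_set(rooted) == split_set(t)

    def test_missing_outgroup_label_rejected(self):
        t = read_newick("((A,B),C);")
        with pytest.raises(ValueError, match="not in tree"):
            root_by_outgroup(t, ["Z"])


# ------------------------------------------------------------- consensus


class TestConsensus:
    def test_identical_trees_reproduced(self):
        trees = [read_newick("((A,B),(C,D));") for _ in range(4)]
        cons = majority_consensus(trees)
        assert split_set(cons) == split_set(trees[0])

    def test_three_to_one_majority_kept(self):
        with_split = [read_newick("((A,B),(C,D));") for _ in range(3)]
        without = [read_newick("((A,C),(B,D));")]
        cons = majority_consensus(with_split + without)
        assert split_set(cons) == split_set(with_split[0])

    def test_even_conflict_gives_polytomy(self):
        trees = [read_newick("((A,B),(C,D));"), read_newick("((A,C),(B,D));")]
        cons = majority_consensus(trees)
        assert split_set(cons) == set()

    def test_differing_leaf_sets_rejected(self):
        with pytest.raises(ValueError):
            majority_consensus([read_newick("((A,B),C);"), read_newick("((A,B),D);")])

    def test_split_frequencies_respected_on_random_trees(self):
        rng = np.random.default_rng(17)
        trees = [random_binary_tree(rng, 8) for _ in range(5)]
        # force identical label sets
        cons = majority_consensus(trees)
        counts: dict[frozenset, int] = {}
        for t in trees:
            for s in split_set(t):
                counts[s] = counts.get(s, 0) + 1
        expected = {s for s, c in counts.items() if c / len(trees) > 0.5}
        assert split_set(cons) == expected


# ------------------------------------------------------------- monophyly / origins


def brute_force_origins(tree: dendropy.Tree, leaf_to_group, group):
    """Independent oracle: enumerate every clade's leaf set, keep uniform
    ones, count those not nested in a larger uniform clade."""
    clades = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if all(leaf_to_group.get(x) == group for x in leaves):
            clades.append(leaves)
    maximal = [c for c in clades if not any(c < d for d in clades)]
    return len(set(maximal))


class TestMonophylyAndOrigins:
    def test_monophyly_examples(self):
        t = read_newick("((A,B),C);")
        assert is_monophyletic(t, {"A", "B"})
        t2 = read_newick("((A,C),B);")
        assert not is_monophyletic(t2, {"A", "B"})
        assert is_monophyletic(t2, {"A"})  # singleton always monophyletic

    def test_missing_labels_rejected(self):
        with pytest.raises(ValueError):
            is_monophyletic(read_newick("((A,B),C);"), {"A", "Z"})

    def test_origin_count_examples(self):
        t = read_newick("(((a1,f1),(a2,f2)),f3);")
        groups = {"a1": "animal", "a2": "animal", "f1": "fungus", "f2": "fungus", "f3": "fungus"}
        assert count_group_origins(t, groups, "animal") == 2
        assert count_group_origins(t, groups, "fungus") == 3
        assert count_group_origins(t, groups, "plant") == 0

    def test_monophilty_iff_single_origin(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            t = random_binary_tree(rng, int(rng.integers(4, 10)))
            rooted = t
            labels = sorted(l.taxon.label for l in t.leaf_node_iter())
            members = {l for l in labels if rng.random() < 0.5}
            if not members:
                continue
            groups = {l: ("in" if l in members else "out") for l in labels}
            single = count_group_origins(rooted, groups, "in") == 1
            assert single == is_monophyletic(rooted, members)

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            t = random_binary_tree(rng, int(rng.integers(3, 11)))
            labels = sorted(l.taxon.label for l in t.leaf_node_iter())
            groups = {l: ("in" if rng.random() < 0.5 else "out") for l in labels}
            assert count_group_origins(t, groups, "in") == brute_force_origins(t, groups, "in")


# ------------------------------------------------------------- Dollo


def brute_force_dollo_losses(tree: dendropy.Tree, present: set[str]) -> int:
    """Exhaustive oracle: smallest set of pruned branches below the gain
    (LCA of present leaves) that removes exactly the absent leaves."""
    if not present:
        return 0
    taxa = [l.taxon for l in tree.leaf_node_iter() if l.taxon.label in present]
    gain = taxa[0].label if len(taxa) == 1 else None
    gain_node = (
        tree.find_node_with_taxon_label(taxa[0].label)
        if len(taxa) == 1
        else tree.mrca(taxa=taxa)
    )
    below = [n for n in gain_node.preorder_iter() if n is not gain_node]
    leaves_below = frozenset(l.taxon.label for l in gain_node.leaf_iter())
    absent = leaves_below - present
    best = None
    for k in range(len(below) + 1):
        for combo in itertools.combinations(below, k):
            covered = set()
            for n in combo:
                covered |= {l.taxon.label for l in n.leaf_iter()}
            if covered == absent:
                best = k
                break
        if best is not None:
            break
    return best


class TestDollo:
    def test_all_present_gain_at_root_no_loss(self):
        t = simulate_species_tree(6, 3)
        gain, losses = dollo_history(t, {l: 1 for l in (x.taxon.label for x in t.leaf_node_iter())})
        assert gain == "root" and losses == []

    def test_single_absent_leaf_single_loss(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gain, losses = dollo_history(t, {"A": 1, "B": 1, "C": 1, "D": 0})
        assert losses == ["D"]

    def test_all_absent(self):
        t = read_newick("((A,B),(C,D));")
        assert dollo_history(t, {}) == (None, [])

    def test_gain_below_root_when_presence_restricted(self):
        t = read_newick("((A:1,B:1)ab:1,(C:1,D:1)cd:1);")
        gain, losses = dollo_history(t, {"A": 1, "B": 1})
        branches = label_branches(t)
        assert {l.taxon.label for l in branches[gain].leaf_iter()} == {"A", "B"}
        assert losses == []

    def test_loss_count_bounded_by_absent_leaves(self):
        # each loss prunes at least one absent leaf, so the minimal loss
        # set is never larger than the absent set below the gain
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = random_binary_tree(rng, 8)
            labels = sorted(l.taxon.label for l in t.leaf_node_iter())
            present = {l for l in labels if rng.random() < 0.5} or {labels[0]}
            _, losses = dollo_history(t, {l: 1 for l in present})
            assert len(losses) <= len(set(labels) - present)

    def test_exhaustive_loss_minimization_all_patterns(self):
        rng = np.random.default_rng(41)
        for n in (4, 6, 8):
            t = random_binary_tree(rng, n)
            labels = sorted(l.taxon.label for l in t.leaf_node_iter())
            for mask in range(1, 2**n):
                present = {labels[i] for i in range(n) if mask >> i & 1}
                _, losses = dollo_history(t, {l: 1 for l in present})
                assert len(losses) == brute_force_dollo_losses(t, present)


# ------------------------------------------------------------- reconciliation


def brute_force_reconcile(gene_tree, species_tree, leaf_map):
    """Independent oracle: enumerate all ancestrally-consistent mappings of
    gene nodes to species nodes and minimize (duplications, losses)."""
    sp_nodes = list(species_tree.preorder_node_iter())
    sp_index = {id(n): i for i, n in enumerate(sp_nodes)}
    parent = {id(n): n.parent_node for n in sp_nodes}
    depth = {}
    for n in sp_nodes:
        depth[id(n)] = 0 if n.parent_node is None else depth[id(n.parent_node)] + 1

    def ancestors(n):
        out = [n]
        while parent[id(n)] is not None:
            n = parent[id(n)]
            out.append(n)
        return out

    def lca(a, b):
        sa = {id(x) for x in ancestors(a)}
        for x in ancestors(b):
            if id(x) in sa:
                return x
        raise AssertionError

    def in_subtree(node, root):
        return root in ancestors(node)

    gene_nodes = list(gene_tree.postorder_node_iter())
    leaf_image = {}
    for g in gene_nodes:
        if g.is_leaf():
            sp = leaf_map[g.taxon.label]
            leaf_image[id(g)] = next(
                l for l in species_tree.leaf_node_iter() if l.taxon.label == sp
            )
    # candidate images per internal node: ancestors of the LCA of its leaves
    best = [None]

    internals = [g for g in gene_nodes if not g.is_leaf()]

    def node_lca_floor(g):
        leaves = [leaf_image[id(l)] for l in g.leaf_iter()]
        m = leaves[0]
        for x in leaves[1:]:
            m = lca(m, x)
        return m

    floors = {id(g): node_lca_floor(g) for g in internals}

    def cost_of(assignment):
        dups = losses = 0
        for g in internals:
            mg = assignment[id(g)]
            imgs = [
                assignment[id(c)] if not c.is_leaf() else leaf_image[id(c)]
                for c in g.child_nodes()
            ]
            floor = imgs[0]
            for x in imgs[1:]:
                floor = lca(floor, x)
            # speciation iff mg is exactly the children's LCA and the two
            # child images lie in different child subtrees of mg
            speciation = False
            if mg is floor and len(imgs) == 2 and imgs[0] is not mg and imgs[1] is not mg:
                kids = mg.child_nodes()
                sides = []
                for img in imgs:
                    side = next(i for i, k in enumerate(kids) if in_subtree(img, k))
                    sides.append(side)
                speciation = sides[0] != sides[1]
            if not speciation:
                dups += 1
            for img in imgs:
                gap = depth[id(img)] - depth[id(mg)]
                losses += gap if not speciation else gap - 1
        return dups, losses

    def rec(idx, assignment):
        if idx == len(internals):
            d, l = cost_of(assignment)
            if best[0] is None or (d + l, d, l) < best[0]:
                best[0] = (d + l, d, l)
            return
        g = internals[idx]
        # candidate images: ancestors-or-self of the LCA of the (already
        # assigned, postorder) child images — keeps maps descent-consistent
        imgs = [
            assignment[id(c)] if not c.is_leaf() else leaf_image[id(c)]
            for c in g.child_nodes()
        ]
        floor = imgs[0]
        for x in imgs[1:]:
            floor = lca(floor, x)
        for cand in ancestors(floor):
            assignment[id(g)] = cand
            rec(idx + 1, assignment)
        del assignment[id(g)]

    rec(0, {})
    return best[0][1], best[0][2]


class TestReconcile:
    def test_congruent_one_copy_zero_events(self):
        sp = read_newick("((A,B),(C,D));")
        gene = read_newick("((a,b),(c,d));")
        res = reconcile(gene, sp, {"a": "A", "b": "B", "c": "C", "d": "D"})
        assert (res.duplications, res.losses) == (0, 0)

    def test_hand_reconciled_duplication_in_one_lineage(self):
        # dup after the A/B speciation, inside lineage A: parsimony needs
        # one duplication and no loss
        sp = read_newick("(A,B);")
        gene = read_newick("((a1,a2),b);")
        res = reconcile(gene, sp, {"a1": "A", "a2": "A", "b": "B"})
        assert (res.duplications, res.losses) == (1, 0)

    def test_root_duplication_with_loss(self):
        # ((a1,b1),a2): the basal split maps to the root twice -> one
        # pre-speciation duplication and one lost copy in lineage B
        sp = read_newick("(A,B);")
        gene = read_newick("((a1,b1),a2);")
        res = reconcile(gene, sp, {"a1": "A", "b1": "B", "a2": "A"})
        assert (res.duplications, res.losses) == (1, 1)

    def test_unmapped_leaf_rejected(self):
        sp = read_newick("(A,B);")
        gene = read_newick("(a,b);")
        with pytest.raises(ValueError):
            reconcile(gene, sp, {"a": "A"})

    def test_mapping_respects_descent(self):
        rng = np.random.default_rng(3)
        sp = random_binary_tree(rng, 6)
        labels = sorted(l.taxon.label for l in sp.leaf_node_iter())
        gene = random_binary_tree(rng, 6)
        gmap = dict(zip(sorted(l.taxon.label for l in gene.leaf_node_iter()), labels))
        res = reconcile(gene, sp, gmap)
        label_branches(sp)
        sp_by_id = {n.branch_id: n for n in sp.preorder_node_iter()}
        label_branches(gene)
        for g in gene.preorder_node_iter():
            if g.parent_node is None:
                continue
            child_img = sp_by_id[res.mapping[g.branch_id]]
            parent_img = sp_by_id[res.mapping[g.parent_node.branch_id]]
            anc = child_img
            ok = False
            while anc is not None:
                if anc is parent_img:
                    ok = True
                    break
                anc = anc.parent_node
            assert ok

    def test_matches_brute_force_on_random_six_leaf_cases(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            sp = random_binary_tree(rng, int(rng.integers(3, 7)))
            sp_labels = sorted(l.taxon.label for l in sp.leaf_node_iter())
            gene = random_binary_tree(rng, int(rng.integers(3, 7)))
            g_labels = sorted(l.taxon.label for l in gene.leaf_node_iter())
            gmap = {g: sp_labels[int(rng.integers(len(sp_labels)))] for g in g_labels}
            res = reconcile(gene, sp, gmap)
            want_d, want_l = brute_force_reconcile(gene, sp, gmap)
            assert (res.duplications, res.losses) == (want_d, want_l)


# ------------------------------------------------------------- tanglegram


def valid_leaf_orders(tree: dendropy.Tree):
    """Independent oracle: permutations of leaves where every clade is
    contiguous (exactly the rotation-reachable orders)."""
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    clades = [
        frozenset(l.taxon.label for l in n.leaf_iter())
        for n in tree.preorder_node_iter()
        if not n.is_leaf()
    ]
    orders = []
    for perm in itertools.permutations(labels):
        pos = {l: i for i, l in enumerate(perm)}
        ok = True
        for c in clades:
            idx = sorted(pos[l] for l in c)
            if idx[-1] - idx[0] != len(idx) - 1:
                ok = False
                break
        if ok:
            orders.append(list(perm))
    return orders


def count_inversions(order_a, order_b, links):
    pos_a = {l: i for i, l in enumerate(order_a)}
    pos_b = {l: i for i, l in enumerate(order_b)}
    n = 0
    for (g1, s1), (g2, s2) in itertools.combinations(links, 2):
        if (pos_a[g1] - pos_a[g2]) * (pos_b[s1] - pos_b[s2]) < 0:
            n += 1
    return n


class TestTanglegram:
    def test_identical_trees_zero_crossings(self):
        a = read_newick("((A,B),(C,D));")
        b = read_newick("((A,B),(C,D));")
        links = [(l, l) for l in "ABCD"]
        _, crossings, _ = tanglegram(a, b, links)
        assert crossings == 0

    def test_two_leaves_swapped_links(self):
        a = read_newick("(A,B);")
        b = read_newick("(X,Y);")
        # as drawn, the swapped links cross once; untangling removes it
        _, raw, _ = tanglegram(a, b, [("A", "Y"), ("B", "X")], untangle=False)
        assert raw == 1
        _, untangled, _ = tanglegram(a, b, [("A", "Y"), ("B", "X")])
        assert untangled == 0

    def test_missing_leaf_rejected(self):
        a = read_newick("(A,B);")
        b = read_newick("(X,Y);")
        with pytest.raises(ValueError):
            tanglegram(a, b, [("A", "Z")])

    def test_matches_exhaustive_order_search_small_trees(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            a = random_binary_tree(rng, n)
            b = random_binary_tree(rng, n)
            a_labels = sorted(l.taxon.label for l in a.leaf_node_iter())
            b_labels = list(rng.permutation(sorted(l.taxon.label for l in b.leaf_node_iter())))
            links = list(zip(a_labels, b_labels))
            _, crossings, orders = tanglegram(a, b, links)
            best = min(
                count_inversions(oa, ob, links)
                for oa in valid_leaf_orders(a)
                for ob in valid_leaf_orders(b)
            )
            assert crossings == best
            assert count_inversions(orders[0], orders[1], links) == crossings
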