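"""JTT model, ML distances, neighbor joining, bootstrap, Newick output."""

import dendropy
import numpy as np
import pytest

from sorfpipe import phylo


class TestJttModel:
    def test_rate_matrix_rows_sum_to_zero(self):
        assert np.allclose(phylo.JTT_Q.sum(axis=1), 0.0, atol=1e-10)

    def test_frequencies_are_stationary(self):
        assert np.allclose(phylo.JTT_FREQS @ phylo.JTT_Q, 0.0, atol=1e-10)

    def test_mean_rate_is_one(self):
        rate = -np.sum(phylo.JTT_FREQS * np.diag(phylo.JTT_Q))
        assert rate == pytest.approx(1.0)

    def test_transition_matrix_is_stochastic(self):
        for t in (0.0, 0.1, 1.0, 5.0):
            P = phylo.jtt_transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)
            assert np.all(P >= 0)
        assert np.allclose(phylo.jtt_transition_matrix(0.0), np.eye(20), atol=1e-8)

    def test_time_reversibility(self):
        P = phylo.jtt_transition_matrix(0.7)
        flux = phylo.JTT_FREQS[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-10)


class TestJttDistance:
    def test_identical_sequences_have_zero_distance(self):
        seq = "MKVLAEGHIRNDQSTWYFPCMKVLAEGHIRNDQSTWYFPCMKVLAEGHIR"
        assert phylo.jtt_distance(seq, seq) == 0.0

    def test_saturated_pair_caps_at_dmax(self):
        # every column different across varied residues: likelihood keeps
        # rising toward infinite divergence, so the estimate hits the cap
        a = phylo.AA_ORDER * 3
        b = (phylo.AA_ORDER[1:] + phylo.AA_ORDER[0]) * 3
        assert phylo.jtt_distance(a, b, aligned=(a, b)) == phylo.D_MAX_DEFAULT

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = phylo.simulate_jtt_pair(0.5, 200, rng)
        assert (phylo.jtt_distance(a, b, aligned=(a, b))
                == pytest.approx(phylo.jtt_distance(b, a, aligned=(b, a)), abs=1e-4))

    def test_gap_columns_excluded(self):
        a = "MKVL-AEGHIRNDQSTWYFP"
        b = "MKVLWAEGHIRNDQSTWYFP"
        # the gapped column is dropped; the rest are identical
        assert phylo.jtt_distance("", "", aligned=(a, b)) == 0.0

    def test_few_columns_warns_but_returns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            d = phylo.jtt_distance("MKVLA", "MKVLA", aligned=("MKVLA", "MKVLA"))
        assert d == 0.0

    def test_simulation_recovery_at_moderate_divergence(self):
        rng = np.random.default_rng(9)
        estimates = []
        for _ in range(20):
            a, b = phylo.simulate_jtt_pair(0.3, 500, rng)
            estimates.append(phylo.jtt_distance(a, b, aligned=(a, b)))
        # unbiased and concentrated: the per-replicate sd at 500 sites is
        # ~0.027 (information bound), so the mean of 20 is tight
        assert abs(np.mean(estimates) - 0.3) <= 0.02
        assert np.std(estimates) <= 0.05

    def test_monotone_in_mismatch_count(self):
        base = "MKVLAEGHIRNDQSTWYFPC" * 5
        prev = -1.0
        for k in (0, 5, 10, 20, 40):
            other = list(base)
            for i in range(k):
                other[i] = "W" if other[i] != "W" else "Y"
            d = phylo.jtt_distance(base, "".join(other),
                                   aligned=(base, "".join(other)))
            assert d >= prev
            prev = d


def tree_path_lengths(tree):
    """Leaf-to-leaf path length matrix of a PhyloTree."""
    paths = {}

    def walk(node, dist_from_root):
        if node.is_leaf:
            paths[node.name] = dist_from_root
        for child in node.children:
            walk(child, dist_from_root + child.length)

    # root-to-leaf distances per subtree give additive paths on unrooted trees
    leaves = sorted(tree.leaf_names())
    out = {}
    for a in leaves:
        for b in leaves:
            if a < b:
                out[(a, b)] = None
    # brute force: distance via lowest common ancestor on the rooted form
    parent = {}

    def link(node):
        for child in node.children:
            parent[id(child)] = node
            link(child)

    link(tree.root)
    nodes_by_name = {leaf.name: leaf for leaf in tree.root.leaves()}

    def ancestors(node):
        chain = [node]
        while id(node) in parent:
            node = parent[id(node)]
            chain.append(node)
        return chain

    for a, b in out:
        chain_a = ancestors(nodes_by_name[a])
        chain_b = {id(n): n for n in ancestors(nodes_by_name[b])}
        lca = next(n for n in chain_a if id(n) in chain_b)
        d = 0.0
        for leaf in (nodes_by_name[a], nodes_by_name[b]):
            node = leaf
            while node is not lca:
                d += node.length
                node = parent[id(node)]
        out[(a, b)] = d
    return out


class TestNeighborJoining:
    def test_three_point_formula(self):
        dm = phylo.DistanceMatrix(["A", "B", "C"],
                                  np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        tree = phylo.neighbor_joining(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_two_taxa(self):
        dm = phylo.DistanceMatrix(["A", "B"], np.array([[0, 3.0], [3.0, 0]]))
        tree = phylo.neighbor_joining(dm)
        paths = tree_path_lengths(tree)
        assert paths[("A", "B")] == pytest.approx(3.0)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # unrooted tree: (A:1,B:2) -- 3 -- (C:4,D:5)
        taxa = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 8, 9],
                      [3, 0, 9, 10],
                      [8, 9, 0, 9],
                      [9, 10, 9, 0.0]])
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(taxa, d))
        paths = tree_path_lengths(tree)
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if a < b:
                    assert paths[(a, b)] == pytest.approx(d[i, j], abs=1e-9)
        # the {A,B}|{C,D} split, canonically the side without the anchor taxon
        assert frozenset("CD") in phylo.bipartitions(tree)

    def test_five_taxon_additivity(self):
        rng = np.random.default_rng(4)
        # random additive matrix from a random tree: build via random splits
        taxa = ["A", "B", "C", "D", "E"]
        # caterpillar tree ((A,B),C,(D,E)) with known branch lengths
        bl = {"A": 0.5, "B": 1.5, "C": 2.0, "D": 0.7, "E": 1.3,
              "AB": 0.9, "DE": 1.1}
        def dist(x, y):
            side = {"A": "AB", "B": "AB", "D": "DE", "E": "DE"}
            d = bl[x] + bl[y]
            if side.get(x) != side.get(y):
                d += bl.get(side.get(x, ""), 0.0) + bl.get(side.get(y, ""), 0.0)
            return d
        d = np.zeros((5, 5))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    d[i, j] = dist(a, b)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(taxa, d))
        paths = tree_path_lengths(tree)
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if a < b:
                    assert paths[(a, b)] == pytest.approx(d[i, j], abs=1e-9)


class TestBootstrap:
    def test_identical_sequences_do_not_crash(self):
        taxa = ["a", "b", "c", "d"]
        rows = ["MKVLAEGHIR"] * 4
        tree = phylo.bootstrap_support(taxa, rows, n_reps=10, seed=1)
        assert tree.leaf_names() == set(taxa)

    def test_strong_signal_gets_high_support(self):
        rng = np.random.default_rng(21)
        anc1, _ = phylo.simulate_jtt_pair(0.05, 300, rng)
        anc2, _ = phylo.simulate_jtt_pair(0.05, 300, rng)
        a = _evolve(anc1, 0.05, rng)
        b = _evolve(anc1, 0.05, rng)
        c = _evolve(anc2, 0.05, rng)
        d = _evolve(anc2, 0.05, rng)
        tree = phylo.bootstrap_support(["a", "b", "c", "d"], [a, b, c, d],
                                       n_reps=100, seed=5)
        supports = [n.support for n in _internal_nodes(tree) if n.support is not None]
        assert supports and min(supports) >= 0.95

    def test_same_seed_is_reproducible(self):
        rng = np.random.default_rng(2)
        rows = [phylo.simulate_jtt_pair(0.4, 120, rng)[1] for _ in range(4)]
        t1 = phylo.bootstrap_support(list("abcd"), rows, n_reps=30, seed=7)
        t2 = phylo.bootstrap_support(list("abcd"), rows, n_reps=30, seed=7)
        assert phylo.write_newick(t1) == phylo.write_newick(t2)

    def test_zero_reps_returns_tree_without_supports(self):
        rng = np.random.default_rng(2)
        rows = [phylo.simulate_jtt_pair(0.4, 80, rng)[1] for _ in range(4)]
        tree = phylo.bootstrap_support(list("abcd"), rows, n_reps=0)
        assert all(n.support is None for n in _internal_nodes(tree))


def _internal_nodes(tree):
    out = []

    def walk(node):
        if not node.is_leaf:
            out.append(node)
            for c in node.children:
                walk(c)

    walk(tree.root)
    return out


def _evolve(seq, t, rng):
    P = phylo.jtt_transition_matrix(t)
    idx = [phylo.AA_ORDER.index(ch) for ch in seq]
    return "".join(phylo.AA_ORDER[rng.choice(20, p=P[i] / P[i].sum())] for i in idx)


class TestNewick:
    def test_three_taxon_serialization(self):
        dm = phylo.DistanceMatrix(["A", "B", "C"],
                                  np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        tree = phylo.neighbor_joining(dm)
        assert phylo.write_newick(tree) == "(A:1.000000,B:1.000000,C:3.000000);"

    def test_round_trip_through_dendropy(self):
        rng = np.random.default_rng(6)
        rows = [phylo.simulate_jtt_pair(0.4, 150, rng)[1] for _ in range(5)]
        tree = phylo.bootstrap_support(list("abcde"), rows, n_reps=20, seed=3)
        text = phylo.write_newick(tree)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set("abcde")
        # branch lengths survive the round trip
        ours = sorted(round(leaf.length, 6) for leaf in tree.root.leaves())
        theirs = sorted(round(leaf.edge.length, 6)
                        for leaf in parsed.leaf_node_iter())
        assert ours == theirs

    def test_labels_with_spaces_are_quoted(self):
        root = phylo.TreeNode(children=[
            phylo.TreeNode(name="taxon one", length=1.0),
            phylo.TreeNode(name="b", length=2.0)])
        text = phylo.write_newick(phylo.PhyloTree(root, ["taxon one", "b"]))
        assert text.startswith("('taxon one':1.000000")
        parsed = dendropy.Tree.get(data=text, schema="newick")
        labels = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert "taxon one" in labels
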