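import dendropy
import numpy as np
import pytest

from karyo.errors import IncomparableArmsError, ValidationError
from karyo.phylogeny import (
    DistanceMatrix,
    arm_pool,
    distance_matrix,
    mst_network,
    nj_tree,
    write_dot,
    write_phylip,
)
from karyo.synthetic_data import evolve, generate_ancestor

from conftest import random_pair


def star_pool(seed=3, n_leaves=4):
    hub = generate_ancestor(18, 0.0, seed=seed, code="hubA1")
    seqs = [hub]
    for i in range(n_leaves):
        seqs.append(evolve(hub, 1, seed=seed + 10 + i, code=f"depA{i + 1}").derived)
    return seqs


def random_additive_matrix(rng, n_taxa):
    """Distance matrix of a random binary tree with positive branch lengths."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=__import__("random").Random(int(rng.integers(0, 2**31))),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = taxa[i]
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.integers(1, 6))
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    vals = np.zeros((n_taxa, n_taxa))
    tax = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                vals[i, j] = pdm.patristic_distance(tax[a], tax[b])
    return DistanceMatrix(tuple(labels), vals.astype(int)), tree


class TestDistanceMatrix:
    def test_single_sequence(self):
        anc, _, _ = random_pair(1, k=0)
        m = distance_matrix([anc])
        assert m.labels == ("ancA1",)
        assert m.values.shape == (1, 1) and m.values[0, 0] == 0

    def test_duplicated_sequence_identical_rows(self):
        anc, der, _ = random_pair(2, k=2)
        from karyo.band_model import ArmSequence

        twin = ArmSequence("cpyA1", der.arm, der.reference, der.order)
        m = distance_matrix([anc, der, twin])
        assert np.array_equal(m.values[1], m.values[2])
        assert m.values[1, 2] == 0

    def test_derivative_bounded_by_k(self):
        anc, der, log = random_pair(4, k=3)
        m = distance_matrix([anc, der])
        assert 0 < m.values[0, 1] <= 3

    def test_validation(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]]))  # asymmetric
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[1, 1], [1, 0]]))  # diagonal
        with pytest.raises(ValidationError):
            distance_matrix([])

    def test_mixed_arms_rejected(self):
        a = generate_ancestor(12, 0.0, seed=1, arm="A", code="xxxA1")
        e = generate_ancestor(12, 0.0, seed=1, arm="E", code="xxxE1")
        with pytest.raises(IncomparableArmsError):
            distance_matrix([a, e])


class TestMST:
    def test_two_labels_single_edge(self):
        anc, der, _ = random_pair(5, k=1)
        edges = mst_network(distance_matrix([anc, der]))
        assert edges == [("ancA1", "derA1", 1)]

    def test_star_hub_degree(self):
        seqs = star_pool()
        m = distance_matrix(seqs)
        edges = mst_network(m)
        deg = {}
        for a, b, _ in edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        assert deg["hubA1"] == 4

    def test_mst_weight_optimal_vs_path(self, rng):
        n = 6
        vals = rng.integers(1, 10, size=(n, n))
        vals = np.triu(vals, 1)
        vals = vals + vals.T
        m = DistanceMatrix(tuple(f"s{i}" for i in range(n)), vals)
        mst_w = sum(w for _, _, w in mst_network(m))
        path_w = sum(vals[i, i + 1] for i in range(n - 1))
        assert mst_w <= path_w

    def test_deterministic(self):
        seqs = star_pool()
        m = distance_matrix(seqs)
        assert mst_network(m) == mst_network(m)

    def test_requires_two_labels(self):
        anc, _, _ = random_pair(1, k=0)
        with pytest.raises(ValidationError):
            mst_network(distance_matrix([anc]))


class TestNJ:
    def test_requires_three_labels(self):
        anc, der, _ = random_pair(6, k=1)
        with pytest.raises(ValidationError):
            nj_tree(distance_matrix([anc, der]))

    def test_additive_four_taxon_recovery(self):
        # ((a:1,b:2):1,(c:3,d:4)); distances constructed by hand
        labels = ("a", "b", "c", "d")
        vals = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ]
        )
        m = DistanceMatrix(labels, vals)
        tree, newick = nj_tree(m)
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.patristic_distance(tax[a], tax[b]) == pytest.approx(vals[i, j])

    def test_ultrametric_three_taxon(self):
        m = DistanceMatrix(("a", "b", "c"), np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]]))
        tree, _ = nj_tree(m)
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        assert pdm.patristic_distance(tax["a"], tax["b"]) == pytest.approx(2)
        assert pdm.patristic_distance(tax["a"], tax["c"]) == pytest.approx(8)

    def test_identical_rows_zero_length_cherry(self):
        vals = np.array([[0, 0, 5], [0, 0, 5], [5, 5, 0]])
        m = DistanceMatrix(("a", "b", "c"), vals)
        tree, _ = nj_tree(m)
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        assert pdm.patristic_distance(tax["a"], tax["b"]) == pytest.approx(0)

    def test_topology_recovery_additive(self, rng):
        recovered = 0
        cases = 20
        for _ in range(cases):
            n_taxa = int(rng.integers(5, 9))
            m, true_tree = random_additive_matrix(rng, n_taxa)
            est, _ = nj_tree(m)
            est.migrate_taxon_namespace(true_tree.taxon_namespace)
            est.is_rooted = False
            true_tree.is_rooted = False
            est.update_bipartitions()
            true_tree.update_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(true_tree, est)
            recovered += rf == 0
        assert recovered == cases

    def test_newick_round_trip(self):
        seqs = star_pool()
        _, newick = nj_tree(distance_matrix(seqs))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == {s.code for s in seqs}


class TestWriters:
    def test_phylip_square(self):
        seqs = star_pool()
        m = distance_matrix(seqs)
        text = write_phylip(m)
        lines = text.strip().split("\n")
        assert lines[0] == str(m.n)
        assert len(lines) == m.n + 1

    def test_dot(self):
        edges = [("a", "b", 1), ("b", "c", 2)]
        dot = write_dot(edges)
        assert dot.startswith("graph mst {")
        assert '"a" -- "b" [label="1"];' in dot


def test_arm_pool_excludes_unmapped_and_stubs(study, registry):
    seqs = arm_pool(study, "E", registry)
    codes = {s.code for s in seqs}
    assert "allE1" in codes and "frmE1" in codes
    assert all(s.is_mapped for s in seqs)
    g_seqs = arm_pool(study, "G", registry)
    assert g_seqs == []  # arm G sequences are all unmapped in the example study
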