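"""Distances, neighbor joining, bootstrap, newick serialization."""

import math

import numpy as np
import pytest

import hemasm as hm
from hemasm.phylo import DistanceMatrix, Node, Tree
from hemasm.simulate import homolog_protein


def _additive_matrix_from_tree():
    """((A:2,B:3):1,(C:4,D:5)); path distances are additive by construction."""
    labels = ["A", "B", "C", "D"]
    d = {
        ("A", "B"): 5.0,
        ("A", "C"): 7.0,
        ("A", "D"): 8.0,
        ("B", "C"): 8.0,
        ("B", "D"): 9.0,
        ("C", "D"): 9.0,
    }
    m = np.zeros((4, 4))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                m[i, j] = m[j, i] = d[(a, b)]
    return DistanceMatrix(labels=labels, matrix=m)


class TestPoissonDistance:
    def test_known_value(self):
        assert hm.poisson_distance(0.10) == pytest.approx(0.10536, abs=1e-5)

    def test_monotone_in_p(self):
        grid = np.linspace(0, 0.95, 50)
        values = [hm.poisson_distance(p) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_saturation_rejected(self):
        with pytest.raises(ValueError):
            hm.poisson_distance(1.0)

    def test_identical_sequences_distance_zero(self, truth_one_species):
        p = truth_one_species.proteins["H1_sp1"]
        assert hm.pairwise_distance(p, p) == 0.0

    def test_pairwise_distance_symmetric(self, truth_one_species):
        a = truth_one_species.proteins["H1_sp1"]
        b = truth_one_species.proteins["H2_sp1"]
        assert hm.pairwise_distance(a, b) == pytest.approx(hm.pairwise_distance(b, a), abs=1e-12)


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        tree = hm.neighbor_joining(_additive_matrix_from_tree())
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        # Saitou-Nei lengths on an additive matrix reproduce the true branches
        lengths = {
            node.name: node.length for node in _iter_leaves(tree.root)
        }
        assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 4.0, "D": 5.0})

    def test_three_taxa_closed_form(self):
        m = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = hm.neighbor_joining(DistanceMatrix(labels=["A", "B", "C"], matrix=m))
        lengths = {node.name: node.length for node in _iter_leaves(tree.root)}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_matches_scikit_bio_on_random_additive_matrices(self):
        skbio_nj = pytest.importorskip("skbio.tree").nj
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 6
            labels = [f"t{i}" for i in range(n)]
            # random tree -> additive matrix via random leaf "coordinates"
            m = _random_additive_matrix(n, rng)
            ours = hm.neighbor_joining(DistanceMatrix(labels=labels, matrix=m))
            theirs = skbio_nj(SkbioDM(m, ids=labels))
            assert ours.bipartitions() == _skbio_bipartitions(theirs, labels)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 1.0, 2.0], [1.1, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["A", "B", "C"], matrix=m)

    def test_orthologs_group_by_paralog_not_species(self, scaled_truth):
        seqs = dict(scaled_truth.proteins)
        seqs["NpH"] = homolog_protein(scaled_truth, 0.30, seed=99)
        tree = hm.neighbor_joining(hm.distance_matrix(seqs))
        assert tree.find_clade({"H1_sp1", "H1_sp2"}) is not None
        assert tree.find_clade({"H2_sp1", "H2_sp2"}) is not None


class TestBootstrap:
    def test_duplicate_taxa_get_full_support(self):
        rng = np.random.default_rng(1)
        base = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(20, size=200))
        seqs = {"A1": base, "A2": base}
        # serial divergence (B from base, C from B) keeps distances tree-like
        parent = base
        for label in ("B", "C"):
            mutated = list(parent)
            for pos in rng.choice(200, size=40, replace=False):
                mutated[pos] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
            seqs[label] = parent = "".join(mutated)
        tree = hm.bootstrap_support(seqs, hm.BootstrapSpec(replicates=50, seed=2))
        clade = tree.find_clade({"A1", "A2"})
        assert clade is not None and clade.support == 100.0

    def test_same_seed_same_supports(self, scaled_truth):
        seqs = dict(scaled_truth.proteins)
        spec = hm.BootstrapSpec(replicates=20, seed=5)
        t1 = hm.bootstrap_support(seqs, spec)
        t2 = hm.bootstrap_support(seqs, spec)
        assert t1.to_newick() == t2.to_newick()

    def test_invalid_replicates_rejected(self):
        with pytest.raises(ValueError):
            hm.BootstrapSpec(replicates=0)


class TestNewick:
    def test_round_trip_preserves_topology_lengths_supports(self, scaled_truth):
        import dendropy

        seqs = dict(scaled_truth.proteins)
        seqs["NpH"] = homolog_protein(scaled_truth, 0.30, seed=99)
        tree = hm.bootstrap_support(
            seqs, hm.BootstrapSpec(replicates=25, seed=1), outgroup="NpH"
        )
        newick = tree.to_newick()
        parsed = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(seqs)
        # branch lengths survive the round trip
        ours = sorted(
            round(node.length, 6) for node in _iter_all(tree.root) if node is not tree.root
        )
        theirs = sorted(
            round(edge.length, 6)
            for edge in parsed.preorder_edge_iter()
            if edge.length is not None
        )
        assert ours == theirs
        supports = sorted(
            node.support for node in _iter_all(tree.root) if node.support is not None
        )
        parsed_supports = sorted(
            float(node.label)
            for node in parsed.preorder_internal_node_iter()
            if node.label is not None
        )
        assert supports == parsed_supports

    def test_outgroup_rooting_places_outgroup_at_root(self, scaled_truth):
        seqs = dict(scaled_truth.proteins)
        seqs["NpH"] = homolog_protein(scaled_truth, 0.30, seed=99)
        tree = hm.bootstrap_support(
            seqs, hm.BootstrapSpec(replicates=10, seed=1), outgroup="NpH"
        )
        names = [child.name for child in tree.root.children]
        assert "NpH" in names
        assert sorted(tree.leaves()) == sorted(seqs)


def _iter_leaves(node):
    if node.is_leaf():
        yield node
    for child in node.children:
        yield from _iter_leaves(child)


def _iter_all(node):
    yield node
    for child in node.children:
        yield from _iter_all(child)


def _random_additive_matrix(n: int, rng) -> np.ndarray:
    """Path-length matrix of a random binary tree with random branch lengths."""
    import itertools

    nodes = list(range(n))
    children: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    nxt = n
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        children[nxt] = [(a, float(rng.uniform(0.5, 3))), (b, float(rng.uniform(0.5, 3)))]
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        nxt += 1
    root = nodes[0]
    dist_to_leaf: dict[int, dict[int, float]] = {}

    def walk(v):
        if v < n:
            dist_to_leaf[v] = {v: 0.0}
            return
        dist_to_leaf[v] = {}
        for child, length in children[v]:
            walk(child)
            for leaf, d in dist_to_leaf[child].items():
                dist_to_leaf[v][leaf] = d + length

    walk(root)
    m = np.zeros((n, n))
    for v in range(n, nxt):
        for (c1, l1), (c2, l2) in itertools.combinations(children[v], 2):
            for leaf1, d1 in dist_to_leaf[c1].items():
                for leaf2, d2 in dist_to_leaf[c2].items():
                    m[leaf1, leaf2] = m[leaf2, leaf1] = d1 + l1 + d2 + l2
    return m


def _skbio_bipartitions(tree, labels) -> set[frozenset]:
    universe = set(labels)
    ref = min(universe)
    splits = set()
    for node in tree.non_tips():
        side = {tip.name for tip in node.tips()}
        if len(side) < 2 or len(universe - side) < 2:
            continue
        splits.add(frozenset(side if ref not in side else universe - side))
    return splits
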