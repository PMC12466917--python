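"""Distance matrices, neighbor joining, midpoint rooting, clade labels."""

import numpy as np
import pytest

from phagescreen.alignment import random_protein
from phagescreen.phylo import (
    DistanceMatrix,
    midpoint_root,
    neighbor_joining,
    pdistance_matrix,
    root_leaf_depths,
)
from phagescreen.synth import make_dfra_set


def _tree_distances(tree):
    """Leaf-to-leaf path lengths in the tree (dict keyed by frozenset)."""
    from phagescreen.phylo import _leaf_distances

    out = {}
    for leaf in tree.leaves:
        d = _leaf_distances(tree, leaf)
        for other in tree.leaves:
            if other != leaf:
                out[frozenset((leaf, other))] = d[other]
    return out


def _random_additive_matrix(n_taxa, rng):
    """Random binary tree with positive branch lengths -> additive matrix."""
    nodes = [(f"t{i}",) for i in range(n_taxa)]
    adjacency = {f"t{i}": {} for i in range(n_taxa)}
    components = [f"t{i}" for i in range(n_taxa)]
    nxt = 0
    while len(components) > 1:
        i, j = sorted(rng.choice(len(components), size=2, replace=False))
        a, b = components[i], components[j]
        u = f"n{nxt}"
        nxt += 1
        adjacency[u] = {}
        for child in (a, b):
            l = float(rng.uniform(0.5, 3.0))
            adjacency[u][child] = l
            adjacency[child][u] = l
        components = [c for c in components if c not in (a, b)] + [u]
    taxa = [f"t{i}" for i in range(n_taxa)]
    mat = np.zeros((n_taxa, n_taxa))
    for i, leaf in enumerate(taxa):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            node = stack.pop()
            for nb, l in adjacency[node].items():
                if nb not in dist:
                    dist[nb] = dist[node] + l
                    stack.append(nb)
        for j, other in enumerate(taxa):
            mat[i, j] = dist[other]
    np.fill_diagonal(mat, 0.0)
    mat = (mat + mat.T) / 2.0  # remove float asymmetry from path summation
    return DistanceMatrix(taxa=taxa, matrix=mat), adjacency


class TestPDistance:
    def test_identical_sequences_zero(self, rng):
        s = random_protein(60, rng)
        dm = pdistance_matrix({"a": s, "b": s, "c": s})
        assert np.allclose(dm.matrix, 0.0)

    def test_symmetry(self, rng):
        seqs = {f"s{i}": random_protein(60, rng) for i in range(4)}
        dm = pdistance_matrix(seqs)
        assert np.allclose(dm.matrix, dm.matrix.T)

    def test_ten_of_hundred_columns(self, rng):
        """Two 100-aa sequences differing at 10 substituted positions."""
        a = random_protein(100, rng)
        b = list(a)
        for pos in rng.choice(100, size=10, replace=False):
            aa = "ACDEFGHIKLMNPQRSTVWY"
            b[pos] = aa[(aa.index(b[pos]) + 1) % 20]
        seqs = {"a": a, "b": "".join(b), "c": random_protein(100, rng)}
        dm = pdistance_matrix(seqs)
        i, j = dm.taxa.index("a"), dm.taxa.index("b")
        assert dm.matrix[i, j] == pytest.approx(0.10, abs=1e-9)

    def test_too_few_sequences(self, rng):
        with pytest.raises(ValueError):
            pdistance_matrix({"a": "ACDEF" * 5, "b": "ACDEF" * 5})


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        """Matrix from ((A:1,B:2):1,(C:3,D:4)) recovers lengths exactly."""
        taxa = ["A", "B", "C", "D"]
        mat = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(taxa=taxa, matrix=mat))
        d = _tree_distances(tree)
        assert d[frozenset(("A", "B"))] == pytest.approx(3)
        assert d[frozenset(("C", "D"))] == pytest.approx(7)
        assert d[frozenset(("A", "C"))] == pytest.approx(5)
        assert d[frozenset(("B", "D"))] == pytest.approx(7)
        # cherry structure: A,B share a neighbor; C,D share a neighbor
        a_nb = next(iter(tree.adjacency["A"]))
        assert "B" in tree.adjacency[a_nb]

    def test_three_taxa_closed_form(self):
        taxa = ["x", "y", "z"]
        mat = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(taxa=taxa, matrix=mat))
        center = next(n for n in tree.adjacency if n not in taxa)
        assert tree.adjacency[center]["x"] == pytest.approx(1.0)
        assert tree.adjacency[center]["y"] == pytest.approx(3.0)
        assert tree.adjacency[center]["z"] == pytest.approx(5.0)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_random_additive_matrices_recovered(self, n_taxa, rng):
        """Additive input: NJ reproduces all leaf-to-leaf path lengths, which
        pins the generating topology."""
        for _ in range(10):
            dm, _ = _random_additive_matrix(n_taxa, rng)
            tree = neighbor_joining(dm)
            d = _tree_distances(tree)
            for i, a in enumerate(dm.taxa):
                for j, b in enumerate(dm.taxa):
                    if i < j:
                        assert d[frozenset((a, b))] == pytest.approx(dm.matrix[i, j])

    def test_taxon_order_permutation_isomorphic(self, rng):
        dm, _ = _random_additive_matrix(5, rng)
        perm = rng.permutation(5)
        dm2 = DistanceMatrix(
            taxa=[dm.taxa[i] for i in perm], matrix=dm.matrix[np.ix_(perm, perm)]
        )
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm2)
        assert _tree_distances(t1) == pytest.approx(_tree_distances(t2))

    def test_agrees_with_skbio_topology(self, rng):
        """Independent oracle: scikit-bio's NJ gives the same path metric."""
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkbioDM

        dm, _ = _random_additive_matrix(6, rng)
        ours = _tree_distances(neighbor_joining(dm))
        sk = skbio_tree.nj(SkbioDM(dm.matrix, ids=dm.taxa))
        for pair, dist in ours.items():
            a, b = sorted(pair)
            assert sk.find(a).distance(sk.find(b)) == pytest.approx(dist)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=["a", "b"], matrix=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=["a"], matrix=np.zeros((2, 2)))


class TestMidpointRoot:
    def test_two_leaf_midpoint(self):
        taxa = ["L", "R", "M"]
        # star with arm lengths L=3, R=1, M=2: longest path L-M = 5
        mat = np.array([[0, 4, 5], [4, 0, 3], [5, 3, 0]], dtype=float)
        tree = midpoint_root(neighbor_joining(DistanceMatrix(taxa=taxa, matrix=mat)))
        depths = root_leaf_depths(tree)
        deepest = max(depths.values())
        assert deepest == pytest.approx(2.5)

    def test_equidistant_deepest_leaves(self, rng):
        for _ in range(5):
            dm, _ = _random_additive_matrix(6, rng)
            tree = midpoint_root(neighbor_joining(dm))
            depths = root_leaf_depths(tree)
            by_clade = {"A": [], "B": []}
            for leaf, depth in depths.items():
                by_clade[tree.clades[leaf]].append(depth)
            assert max(by_clade["A"]) == pytest.approx(max(by_clade["B"]), abs=1e-9)

    def test_ultrametric_tree_root_depth(self, rng):
        # perfectly clock-like matrix: all leaves equidistant from the root
        taxa = ["a", "b", "c", "d"]
        mat = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float
        )
        tree = midpoint_root(neighbor_joining(DistanceMatrix(taxa=taxa, matrix=mat)))
        depths = root_leaf_depths(tree)
        assert max(depths.values()) == pytest.approx(3.0)
        assert depths["a"] == pytest.approx(depths["c"])

    def test_clades_cover_all_leaves(self, rng):
        dm, _ = _random_additive_matrix(6, rng)
        tree = midpoint_root(neighbor_joining(dm))
        assert set(tree.clades) == set(tree.leaves)
        assert min(tree.leaves) in {l for l, c in tree.clades.items() if c == "A"}

    def test_newick_parses_with_dendropy(self, rng):
        dendropy = pytest.importorskip("dendropy")
        dm, _ = _random_additive_matrix(5, rng)
        tree = midpoint_root(neighbor_joining(dm))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(tree.leaves)


class TestCladeRecovery:
    def test_two_family_split_recovered(self):
        """The A/B split at the midpoint root equals the generating family
        partition in >= 95% of seeded runs."""
        ok = 0
        runs = 20
        for seed in range(runs):
            seqs, clade_of = make_dfra_set(n_per_clade=5, seed=seed, length=120)
            tree = midpoint_root(neighbor_joining(pdistance_matrix(seqs)))
            sides = {"A": set(), "B": set()}
            for leaf, side in tree.clades.items():
                sides[side].add(clade_of[leaf])
            if all(len(v) == 1 for v in sides.values()):
                ok += 1
        assert ok / runs >= 0.95
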