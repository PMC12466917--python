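"""Desk-scale phylogeny: p-distances, neighbor joining, midpoint rooting.

Distances are 1 - identity_fraction from pairwise global alignments
(BLOSUM62, gaps 11/1). The tree is built with the Saitou–Nei neighbor
joining criterion (deterministic tie-break on the smallest taxon-index
pair); on an additive matrix this recovers the generating topology and
branch lengths exactly. Rooting places the root at the midpoint of the
longest leaf-to-leaf path, and the two root children define clades A and B,
with A containing the lexicographically smallest leaf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import ScoringScheme, global_identity, protein_scheme


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match taxon count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.matrix < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def to_phylip(self) -> str:
        lines = [str(len(self.taxa))]
        for name, row in zip(self.taxa, self.matrix):
            lines.append(name + "  " + "  ".join(f"{d:.6f}" for d in row))
        return "\n".join(lines) + "\n"


def pdistance_matrix(
    sequences: dict[str, str], scheme: ScoringScheme | None = None
) -> DistanceMatrix:
    """d(i,j) = 1 - identity_fraction of the pairwise global alignment."""
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    if scheme is None:
        scheme = protein_scheme()
    taxa = list(sequences)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(sequences[taxa[i]], sequences[taxa[j]], scheme)
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return DistanceMatrix(taxa=taxa, matrix=d)


@dataclass
class PhyloTree:
    """Tree as an adjacency map with non-negative branch lengths.

    Leaves are taxon names; internal nodes are integers. ``root`` is set
    after midpoint rooting.
    """

    adjacency: dict[object, dict[object, float]]
    leaves: list[str]
    root: object | None = None
    clades: dict[str, str] = field(default_factory=dict)  # leaf -> 'A' | 'B'
    negative_branches_clamped: int = 0

    def neighbors(self, node):
        return self.adjacency[node]

    def newick(self) -> str:
        """Newick string; requires a rooted tree."""
        if self.root is None:
            raise ValueError("tree must be rooted before Newick export")

        def render(node, parent) -> str:
            children = [n for n in self.adjacency[node] if n != parent]
            if not children:
                return f"{node}"
            inner = ",".join(
                f"{render(c, node)}:{self.adjacency[node][c]:.6f}" for c in children
            )
            return f"({inner})"

        return render(self.root, None) + ";"


def _join_lengths(d, i, j, r, n):
    if n > 2:
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
    else:
        li = 0.5 * d[i, j]
    return li, d[i, j] - li


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei NJ with smallest-index-pair tie-breaking.

    Negative branch-length estimates are clamped to zero (counted on the
    returned tree) with a warning.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    active: list[object] = list(dm.taxa)
    index = {t: k for k, t in enumerate(active)}  # insertion order for ties
    d = {(a, b): dm.matrix[i, j] for i, a in enumerate(dm.taxa) for j, b in enumerate(dm.taxa)}
    adjacency: dict[object, dict[object, float]] = {t: {} for t in dm.taxa}
    next_internal = 0
    clamped = 0

    def dist(a, b):
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, min(index[a], index[b]), max(index[a], index[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        la = 0.5 * dist(a, b) + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dist(a, b) - la
        if la < 0 or lb < 0:
            clamped += int(la < 0) + int(lb < 0)
            warnings.warn("negative NJ branch length clamped to 0", stacklevel=2)
            la, lb = max(la, 0.0), max(lb, 0.0)
        u = next_internal
        next_internal += 1
        adjacency[u] = {}
        adjacency[u][a] = la
        adjacency[a][u] = la
        adjacency[u][b] = lb
        adjacency[b][u] = lb
        for c in active:
            if c == a or c == b:
                continue
            d[(u, c)] = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
        active = [c for c in active if c != a and c != b] + [u]
        index[u] = max(index.values()) + 1

    a, b, c = active
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    lengths = [la, lb, lc]
    for k, l in enumerate(lengths):
        if l < 0:
            clamped += 1
            warnings.warn("negative NJ branch length clamped to 0", stacklevel=2)
            lengths[k] = 0.0
    u = next_internal
    adjacency[u] = {}
    for node, l in zip((a, b, c), lengths):
        adjacency[u][node] = l
        adjacency[node][u] = l
    return PhyloTree(
        adjacency=adjacency, leaves=list(dm.taxa), negative_branches_clamped=clamped
    )


def _leaf_distances(tree: PhyloTree, start) -> dict:
    """Weighted distances from ``start`` to every node (tree BFS)."""
    dist = {start: 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb, l in tree.adjacency[node].items():
            if nb not in dist:
                dist[nb] = dist[node] + l
                stack.append(nb)
    return dist


def _path(tree: PhyloTree, a, b) -> list:
    parent = {a: None}
    stack = [a]
    while stack:
        node = stack.pop()
        if node == b:
            break
        for nb in tree.adjacency[node]:
            if nb not in parent:
                parent[nb] = node
                stack.append(nb)
    path = [b]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path[::-1]


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path; label clades.

    Clade A contains the lexicographically smallest leaf among the two root
    subtrees. On a zero-length tree the root attaches at the first leaf's
    neighborhood and the tree is flagged via a warning.
    """
    if len(tree.leaves) < 2:
        raise ValueError("midpoint rooting needs >= 2 leaves")
    d0 = _leaf_distances(tree, tree.leaves[0])
    far1 = max(tree.leaves, key=lambda l: (d0[l], l))
    d1 = _leaf_distances(tree, far1)
    far2 = max((l for l in tree.leaves if l != far1), key=lambda l: (d1[l], l))
    total = d1[far2]
    path = _path(tree, far1, far2)
    adjacency = {n: dict(nbs) for n, nbs in tree.adjacency.items()}
    root = "__root__"
    if total == 0:
        warnings.warn("zero-length tree: root placed arbitrarily", stacklevel=2)
        anchor = path[0]
        adjacency[root] = {anchor: 0.0}
        adjacency[anchor][root] = 0.0
    else:
        half = total / 2.0
        acc = 0.0
        for u, v in zip(path, path[1:]):
            edge = adjacency[u][v]
            if acc + edge >= half - 1e-12:
                offset = half - acc
                del adjacency[u][v]
                del adjacency[v][u]
                adjacency[root] = {u: offset, v: edge - offset}
                adjacency[u][root] = offset
                adjacency[v][root] = edge - offset
                break
            acc += edge
    rooted = PhyloTree(
        adjacency=adjacency,
        leaves=list(tree.leaves),
        root=root,
        negative_branches_clamped=tree.negative_branches_clamped,
    )
    children = list(adjacency[root])
    sides = []
    for child in children:
        seen = {root, child}
        stack = [child]
        leaves = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str) and node in tree.leaves:
                leaves.add(node)
            for nb in adjacency[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        sides.append(leaves)
    if len(sides) == 1:
        sides.append(set())
    smallest = min(tree.leaves)
    a_side = 0 if smallest in sides[0] else 1
    for leaf in sides[a_side]:
        rooted.clades[leaf] = "A"
    for leaf in sides[1 - a_side]:
        rooted.clades[leaf] = "B"
    return rooted


def root_leaf_depths(tree: PhyloTree) -> dict[str, float]:
    if tree.root is None:
        raise ValueError("tree is not rooted")
    d = _leaf_distances(tree, tree.root)
    return {l: d[l] for l in tree.leaves}
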