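"""Distance-based orthology phylogenetics with bootstrap support.

The question the tree answers is orthology structure: after a gene
duplication that predates speciation, hemocyanin paralogs from two species
should group as ((H1_sp1, H1_sp2), (H2_sp1, H2_sp2)) rather than by species.
Distances are Poisson-corrected protein p-distances computed on a star
alignment (every sequence globally aligned to the longest one), trees are
built by canonical neighbor joining (Saitou-Nei), and support comes from
bootstrap resampling of alignment columns.  An outgroup label can root the
reported tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .protein import _align_indices


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < 0).any() or not np.isfinite(m).all():
            raise ValueError("distances must be finite and non-negative")
        self.matrix = m

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    root: Node

    def leaves(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each normalized to the side without the
        lexicographically smallest leaf."""
        taxa = set(self.leaves())
        ref = min(taxa)
        splits: set[frozenset] = set()
        for node in _iter_nodes(self.root):
            if node is self.root or node.is_leaf():
                continue
            side = set(node.leaves())
            if len(side) < 2 or len(taxa - side) < 2:
                continue
            splits.add(frozenset(side if ref not in side else taxa - side))
        return splits

    def find_clade(self, taxa) -> Node | None:
        want = frozenset(taxa)
        universe = frozenset(self.leaves())
        for node in _iter_nodes(self.root):
            if node.is_leaf() or node is self.root:
                continue
            side = frozenset(node.leaves())
            if side == want or universe - side == want:
                return node
        return None

    def to_newick(self) -> str:
        inner = ",".join(_newick(c) for c in self.root.children)
        label = "" if self.root.support is None else f"{self.root.support:g}"
        return f"({inner}){label};"


def _iter_nodes(node: Node):
    yield node
    for child in node.children:
        yield from _iter_nodes(child)


def _newick(node: Node) -> str:
    if node.is_leaf():
        return f"{node.name}:{node.length:.6f}"
    inner = ",".join(_newick(c) for c in node.children)
    label = "" if node.support is None else f"{node.support:g}"
    return f"({inner}){label}:{node.length:.6f}"


@dataclass(frozen=True)
class BootstrapSpec:
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


# ---------------------------------------------------------------------------
# distances


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p) for mismatch fraction p."""
    if not 0.0 <= p:
        raise ValueError("mismatch fraction must be >= 0")
    if p >= 1.0:
        raise ValueError("saturated distance (p >= 1)")
    return -math.log(1.0 - p)


def pairwise_distance(a: str, b: str) -> float:
    """Poisson-corrected distance from a global pairwise protein alignment.

    Mismatch fraction is computed over aligned non-gap columns only.
    """
    a_idx, b_idx = _align_indices(a, b)
    keep = (a_idx >= 0) & (b_idx >= 0)
    if not keep.any():
        raise ValueError("sequences do not align")
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)[a_idx[keep]]
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)[b_idx[keep]]
    return poisson_distance(float(np.mean(arr_a != arr_b)))


def star_alignment(sequences: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Align every sequence to the longest one (the star center).

    Returns sorted labels and a (taxa x center-length) byte matrix, 0 marking
    a gap.  This is a documented approximation of a full multiple alignment:
    columns are the center's residues; insertions relative to the center are
    dropped.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    labels = sorted(sequences)
    center = max(labels, key=lambda lab: (len(sequences[lab]), lab))
    center_seq = sequences[center]
    matrix = np.zeros((len(labels), len(center_seq)), dtype=np.uint8)
    for row, label in enumerate(labels):
        if label == center:
            matrix[row] = np.frombuffer(center_seq.encode(), dtype=np.uint8)
            continue
        q_idx, c_idx = _align_indices(sequences[label], center_seq)
        keep = (q_idx >= 0) & (c_idx >= 0)
        qarr = np.frombuffer(sequences[label].encode(), dtype=np.uint8)
        matrix[row, c_idx[keep]] = qarr[q_idx[keep]]
    return labels, matrix


def distance_matrix(
    sequences: dict[str, str], columns: np.ndarray | None = None, _star=None
) -> DistanceMatrix:
    """Poisson-corrected pairwise distances on the star alignment.

    Pairwise deletion: each pair is compared over the columns where both
    taxa have a residue, so lineage-specific segments (such as the FU-g
    insertion shared by the H2 orthologs) still contribute signal to the
    pairs that carry them.
    """
    labels, matrix = _star if _star is not None else star_alignment(sequences)
    if columns is not None:
        matrix = matrix[:, columns]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (matrix[i] > 0) & (matrix[j] > 0)
            ncols = int(both.sum())
            if ncols == 0:
                raise ValueError(f"no shared columns between {labels[i]} and {labels[j]}")
            p = float(np.mean(matrix[i, both] != matrix[j, both]))
            p = min(p, 1.0 - 1.0 / (2 * ncols))  # guard against saturation in resamples
            out[i, j] = out[j, i] = poisson_distance(p)
    return DistanceMatrix(labels=labels, matrix=out)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Canonical NJ (Q-minimization, Saitou-Nei branch lengths).

    Ties in Q are broken by lexicographic order of the joined clades' smallest
    leaf labels; negative branch lengths are clamped to zero with the deficit
    moved to the sibling branch.  The returned tree is unrooted (trifurcating
    root).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[Node] = [Node(name=label) for label in dm.labels]
    keys: list[str] = list(dm.labels)  # smallest leaf per active node
    d = dm.matrix.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _q, _key, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new_node = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [new_node]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # closed-form resolution of the final three branches
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length, b.length, c.length = (max(0.0, x) for x in (la, lb, lc))
    order = np.argsort(keys)
    return Tree(root=Node(children=[nodes[k] for k in order]))


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def root_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root on the branch leading to the outgroup leaf (split at its midpoint)."""
    import copy

    tree = copy.deepcopy(tree)
    parent: dict[int, Node] = {}
    for node in _iter_nodes(tree.root):
        for child in node.children:
            parent[id(child)] = node
    leaf = next(
        (n for n in _iter_nodes(tree.root) if n.is_leaf() and n.name == outgroup), None
    )
    if leaf is None:
        raise KeyError(f"outgroup {outgroup!r} not among leaves")

    def rehang(node: Node, exclude: Node) -> Node:
        """The tree as seen from ``node``, looking away from ``exclude``."""
        kids = [c for c in node.children if c is not exclude]
        up = parent.get(id(node))
        if up is not None and up is not exclude:
            up_node = rehang(up, node)
            up_node.length = node.length
            up_node.support = node.support
            kids = kids + [up_node]
        if len(kids) == 1 and node.name is None:
            # splice degree-2 node created at the old root
            only = kids[0]
            return Node(name=only.name, length=only.length, support=only.support, children=only.children)
        return Node(name=node.name if node.is_leaf() else None, children=kids)

    anchor = parent[id(leaf)]
    half = leaf.length / 2.0
    ingroup = rehang(anchor, leaf)
    ingroup.length = half
    ingroup.support = leaf.support
    return Tree(root=Node(children=[Node(name=outgroup, length=half), ingroup]))


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    sequences: dict[str, str], spec: BootstrapSpec | None = None, outgroup: str | None = None
) -> Tree:
    """NJ tree with column-resampling bootstrap supports (percent).

    Columns of the star alignment are resampled with replacement per
    replicate; each original internal bipartition's support is the percentage
    of replicate trees containing it.  Deterministic given the spec's seed.
    """
    spec = spec or BootstrapSpec()
    if len(sequences) < 4:
        raise ValueError("bootstrap support needs at least 4 taxa")
    star = star_alignment(sequences)
    tree = neighbor_joining(distance_matrix(sequences, _star=star))
    counts: dict[frozenset, int] = {split: 0 for split in tree.bipartitions()}
    rng = np.random.default_rng(spec.seed)
    ncols = star[1].shape[1]
    for _ in range(spec.replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep_tree = neighbor_joining(distance_matrix(sequences, columns=cols, _star=star))
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    taxa = set(tree.leaves())
    ref = min(taxa)
    for node in _iter_nodes(tree.root):
        if node.is_leaf() or node is tree.root:
            continue
        side = set(node.leaves())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        split = frozenset(side if ref not in side else taxa - side)
        if split in counts:
            node.support = 100.0 * counts[split] / spec.replicates
    if outgroup is not None:
        rooted = root_with_outgroup(tree, outgroup)
        return rooted
    return tree
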