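"""Distance-based phylogeny: p-distance, neighbor-joining, bootstrap.

The module consumes a ready multiple sequence alignment (equal-length rows)
and produces an unrooted NJ tree in Newick form, optionally with bootstrap
support (percentage of column-resampled replicate trees containing each
internal split of the full-data tree).  The distance model is the p-distance
(proportion of differing sites over pairwise-comparable columns) with an
optional Poisson correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match id list")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")


@dataclass
class TreeNode:
    """Rooted representation of an unrooted tree (root is a trifurcation for
    n >= 3).  ``children`` holds (child, branch_length) pairs."""

    name: str | None = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self, supports: dict[frozenset, float] | None = None) -> str:
        leaf_set = frozenset(self.leaves())

        def fmt(node, parent_set):
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{fmt(c, parent_set)}:{bl:.6g}" for c, bl in node.children
            )
            label = ""
            if supports is not None:
                side = frozenset(node.leaves())
                key = _canonical_split(side, leaf_set)
                if key in supports:
                    label = f"{supports[key]:g}"
            return f"({inner}){label}"

        return fmt(self, leaf_set) + ";"


@dataclass
class PhyloTree:
    root: TreeNode
    n_clamped_branches: int = 0
    supports: dict[frozenset, float] | None = None  # canonical split -> percent

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        return self.root.to_newick(self.supports)


def _canonical_split(side: frozenset, leaf_set: frozenset) -> frozenset:
    """Represent a bipartition by its lexicographically smaller side."""
    other = leaf_set - side
    return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))


def internal_splits(tree: PhyloTree | TreeNode) -> set[frozenset]:
    """Canonical bipartitions induced by internal edges (both sides >= 2)."""
    root = tree.root if isinstance(tree, PhyloTree) else tree
    leaf_set = frozenset(root.leaves())
    splits = set()

    def walk(node):
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 2 <= len(side) <= len(leaf_set) - 2:
                splits.add(_canonical_split(side, leaf_set))
            walk(child)

    walk(root)
    return splits


def p_distance(
    ids: list[str],
    seqs: list[str],
    gap_policy: str = "pairwise",
    poisson: bool = False,
) -> DistanceMatrix:
    """Proportion of differing residues over pairwise-comparable columns.

    Columns where either sequence of a pair carries a gap are excluded for
    that pair (``gap_policy="pairwise"``), or globally gap-containing columns
    are removed first (``"complete"``).  Raises for a pair with no comparable
    columns.
    """
    if len(set(map(len, seqs))) > 1:
        raise ValueError("alignment rows have unequal lengths")
    arr = np.array([list(s.upper()) for s in seqs])
    if gap_policy == "complete":
        keep = ~np.any(arr == "-", axis=0)
        arr = arr[:, keep]
    elif gap_policy != "pairwise":
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    n = len(ids)
    d = np.zeros((n, n))
    nongap = arr != "-"
    for i in range(n):
        for j in range(i + 1, n):
            ok = nongap[i] & nongap[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            p = float(np.sum(arr[i, ok] != arr[j, ok])) / m
            if poisson:
                if p >= 1.0:
                    raise ValueError(f"saturated distance between {ids[i]} and {ids[j]}")
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(ids), d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic lowest-index tie-break.

    Negative branch lengths are clamped to zero and counted.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    clamped = 0

    def clamp(x):
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    nodes = [TreeNode(name=i) for i in dm.ids]
    d = dm.d.copy()
    active = list(range(n))

    if n == 2:
        half = dm.d[0, 1] / 2.0
        root = TreeNode(children=[(nodes[0], clamp(half)), (nodes[1], clamp(half))])
        return PhyloTree(root, clamped)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        # distances from the new node to the remaining taxa
        new = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    if len(active) == 3:
        i, j, k = active
        # three-point formulas for the final star
        li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
        lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
        lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        root = TreeNode(
            children=[
                (nodes[i], clamp(li)),
                (nodes[j], clamp(lj)),
                (nodes[k], clamp(lk)),
            ]
        )
    else:  # two nodes left (n was even through joins)
        i, j = active
        half = d[i, j] / 2.0
        root = TreeNode(children=[(nodes[i], clamp(half)), (nodes[j], clamp(half))])
    return PhyloTree(root, clamped)


def path_length_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths; on an additive input, NJ reproduces the
    generating distances exactly."""
    leaves = sorted(tree.leaves())
    index = {name: i for i, name in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    # every leaf pair meets at exactly one node; accumulate per-node distances
    def pairs(node):
        below = {}
        if node.is_leaf:
            below[node.name] = 0.0
        for child, bl in node.children:
            sub = {k: v + bl for k, v in pairs(child).items()}
            for name_a, da in sub.items():
                for name_b, db in below.items():
                    i, j = index[name_a], index[name_b]
                    d[i, j] = d[j, i] = da + db
            below.update(sub)
        return below

    pairs(tree.root)
    return DistanceMatrix(leaves, d)


def bootstrap(
    ids: list[str],
    seqs: list[str],
    n_replicates: int = 100,
    seed: int = 0,
    gap_policy: str = "pairwise",
    poisson: bool = False,
) -> PhyloTree:
    """Column-resampling bootstrap; supports are % of replicate trees that
    contain each internal split of the full-data tree."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    full = neighbor_joining(p_distance(ids, seqs, gap_policy, poisson))
    target = internal_splits(full)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    length = len(seqs[0])
    arr = np.array([list(s) for s in seqs])
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        rep_seqs = ["".join(row) for row in arr[:, cols]]
        try:
            rep = neighbor_joining(p_distance(ids, rep_seqs, gap_policy, poisson))
        except ValueError:  # e.g. a replicate with no comparable columns
            continue
        rep_splits = internal_splits(rep)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    full.supports = {
        s: 100.0 * c / n_replicates for s, c in counts.items()
    }
    return full
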