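"""Distance-based trees and rhodopsin group assignment.

Classical neighbor joining (Saitou-Nei Q criterion) over identity-derived
distances, column-resampling bootstrap support, and nearest-group cluster
assignment. Trees are unrooted (one trifurcation at the final join),
branch-length estimates below zero are clamped to 0 with a flag, and Q-matrix
ties break lexicographically on taxon labels so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import FormatError, PairMatrix
from .msa_engine import Alignment


@dataclass
class TreeNode:
    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out


@dataclass
class Tree:
    """Unrooted tree rendered from a trifurcating top node."""

    root: TreeNode
    clamped_negative_branches: int = 0

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(sorted(self.root.leaf_labels()))

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf():
                return node.label
            inner = ",".join(f"{render(c)}:{bl:.6f}" for c, bl in node.children)
            sup = "" if node.support is None else f"{node.support:.3f}"
            return f"({inner}){sup}"

        return render(self.root) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the lexicographically first leaf."""
        all_leaves = set(self.root.leaf_labels())
        ref = min(all_leaves)
        out: set[frozenset] = set()
        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf():
                return {node.label}
            below: set[str] = set()
            for child, _ in node.children:
                side = walk(child)
                if 2 <= len(side) <= len(all_leaves) - 2:
                    canon = frozenset(all_leaves - side) if ref in side else frozenset(side)
                    out.add(canon)
                below |= side
            return below

        walk(self.root)
        return out

    def support_of(self, side: set[str]) -> Optional[float]:
        """Bootstrap support of the edge inducing the given bipartition side."""
        all_leaves = set(self.root.leaf_labels())
        target = frozenset(side) if min(all_leaves) not in side else frozenset(all_leaves - set(side))

        found: list[Optional[float]] = [None]

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf():
                return {node.label}
            below: set[str] = set()
            for child, _ in node.children:
                side_c = walk(child)
                canon = frozenset(side_c) if min(all_leaves) not in side_c else frozenset(all_leaves - side_c)
                if canon == target:
                    found[0] = child.support
                below |= side_c
            return below

        walk(self.root)
        return found[0]

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the leaf-to-leaf path."""
        def find(node: TreeNode, target: str, acc: float, path: list) -> Optional[list]:
            if node.is_leaf():
                return list(path) if node.label == target else None
            for child, bl in node.children:
                path.append((child, bl))
                r = find(child, target, acc + bl, path)
                if r is not None:
                    return r
                path.pop()
            return None

        pa = find(self.root, a, 0.0, [])
        pb = find(self.root, b, 0.0, [])
        if pa is None or pb is None:
            raise FormatError("leaf not in tree")
        ia = 0
        while ia < min(len(pa), len(pb)) and pa[ia][0] is pb[ia][0]:
            ia += 1
        return sum(bl for _, bl in pa[ia:]) + sum(bl for _, bl in pb[ia:])


def distance_from_identity(m: PairMatrix) -> PairMatrix:
    """d = (100 - identity) / 100, a [0, 1] dissimilarity with zero diagonal."""
    if m.metric != "identity":
        raise FormatError("distance conversion expects an identity matrix")
    values = (100.0 - m.values) / 100.0
    np.fill_diagonal(values, 0.0)
    return PairMatrix(labels=m.labels, values=values, metric="distance")


def triangle_violations(m: PairMatrix, tol: float = 1e-9) -> list[tuple[str, str, str]]:
    """Triples (i, j, k) with d(i,k) > d(i,j) + d(j,k) + tol, reported not hidden."""
    labs, d = m.labels, m.values
    n = len(labs)
    out = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i != j != k and i != k and d[i, k] > d[i, j] + d[j, k] + tol:
                    out.append((labs[i], labs[j], labs[k]))
    return out


def neighbor_joining(m: PairMatrix) -> Tree:
    """Classical neighbor joining on a distance matrix.

    On an additive matrix the leaf-to-leaf path lengths reproduce the input
    exactly. Negative branch-length estimates are clamped to 0 and counted
    on the returned tree.
    """
    if m.metric != "distance":
        raise FormatError("neighbor joining expects a distance matrix")
    n = len(m.labels)
    if n < 3:
        raise FormatError("neighbor joining needs at least 3 taxa")
    d = m.values.astype(float).copy()
    nodes = [TreeNode(label=lab) for lab in m.labels]
    keys = [(lab,) for lab in m.labels]  # sorted member tuples, for tie-breaks
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * d[i, j] - r[i] - r[j]
                key = (q, min(keys[i][0], keys[j][0]), max(keys[i][0], keys[j][0]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2 * (k - 2)))
        lj = clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2 * (k - 2))))
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        keep = [t for t in range(k) if t not in (i, j)]
        dn = np.array([0.5 * (d[i, t] + d[j, t] - d[i, j]) for t in keep])
        d = np.vstack([np.hstack([d[np.ix_(keep, keep)], dn[:, None]]),
                       np.hstack([dn, [0.0]])])
        new_key = tuple(sorted(keys[i] + keys[j]))
        nodes = [nodes[t] for t in keep] + [parent]
        keys = [keys[t] for t in keep] + [new_key]

    # final trifurcation: three-point formulas
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    b0 = clamp((d01 + d02 - d12) / 2)
    b1 = clamp((d01 + d12 - d02) / 2)
    b2 = clamp((d02 + d12 - d01) / 2)
    root = TreeNode(children=[(nodes[0], b0), (nodes[1], b1), (nodes[2], b2)])
    return Tree(root=root, clamped_negative_branches=clamped)


def _identity_matrix_from_alignment(aln: Alignment, denominator: str = "shorter") -> PairMatrix:
    from .similarity_metrics import build_matrix

    return build_matrix(aln, metric="identity", denominator=denominator)


def bootstrap_support(aln: Alignment, replicates: int = 100, seed: int = 0,
                      denominator: str = "shorter") -> Tree:
    """Column-resampling bootstrap over identity -> distance -> NJ.

    The point tree is built from the full alignment; each replicate resamples
    alignment columns with replacement and rebuilds the tree; an internal
    edge's support is the fraction of replicate trees containing its
    bipartition. Deterministic for a fixed seed.
    """
    if replicates < 1:
        raise FormatError("need at least one bootstrap replicate")
    if len(aln.rows) < 3:
        raise FormatError("bootstrap needs an alignment with at least 3 rows")
    point = neighbor_joining(distance_from_identity(
        _identity_matrix_from_alignment(aln, denominator)))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in point.bipartitions()}
    ncol = aln.column_count
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = tuple("".join(r[c] for c in cols) for r in aln.rows)
        # a resampled row may be all gaps; guard with FormatError propagation
        rep_aln = Alignment(ids=aln.ids, rows=rows)
        rep_tree = neighbor_joining(distance_from_identity(
            _identity_matrix_from_alignment(rep_aln, denominator)))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    def attach(node: TreeNode, all_leaves: set[str]) -> set[str]:
        if node.is_leaf():
            return {node.label}
        below: set[str] = set()
        for child, _ in node.children:
            side = attach(child, all_leaves)
            if 2 <= len(side) <= len(all_leaves) - 2:
                canon = frozenset(side) if min(all_leaves) not in side else frozenset(all_leaves - side)
                child.support = counts.get(canon, 0) / replicates
            below |= side
        return below

    attach(point.root, set(point.root.leaf_labels()))
    return point


def assign_cluster(query: str, references: dict[str, str], m: PairMatrix) -> tuple[str, float]:
    """Assign a query to the reference group with the smallest mean distance.

    ``references`` maps reference id -> group label. Returns (group, margin)
    where margin = runner-up mean minus winner mean; exact ties yield
    ("unassigned", 0.0).
    """
    if query in references:
        raise FormatError("query must not be among the references")
    if m.metric != "distance":
        m = distance_from_identity(m)
    groups: dict[str, list[float]] = {}
    for ref_id, group in references.items():
        groups.setdefault(group, []).append(m.get(query, ref_id))
    if not groups:
        raise FormatError("no reference groups given")
    means = sorted(((float(np.mean(v)), g) for g, v in groups.items()))
    if len(means) == 1:
        return means[0][1], float("inf")
    (m1, g1), (m2, _) = means[0], means[1]
    if m1 == m2:
        return "unassigned", 0.0
    return g1, m2 - m1
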