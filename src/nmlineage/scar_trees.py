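"""Distance-based clonal trees with bootstrap clade support.

Body structures are related by an (unknown) division history; a
neighbor-joining tree over the pairwise IWSS matrix summarizes it.  Support
for each internal edge comes from a standard phylogenetic bootstrap: scar
columns (the characters) are resampled with replacement, weights → distances
→ tree are recomputed, and the support of a reference edge is the number of
replicate trees containing the same unrooted bipartition — the clade
proportions displayed on the published trees (100 replicates by default).

Trees are held as unrooted :class:`skbio.TreeNode` objects with the usual
trifurcating-root convention; negative neighbor-joining branch lengths are
clamped to zero with a warning.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .scar_distance import DistanceMatrix, ScarWeights, iwss
from .scar_filtering import BinaryScarMatrix

logger = logging.getLogger(__name__)


@dataclass
class CladeTree:
    """Unrooted tree over sample labels with bootstrap supports per internal edge.

    ``supports`` maps a canonical bipartition (frozenset of leaf labels on the
    side not containing the lexicographically smallest label) to the number of
    bootstrap replicates containing it; ``n_boot`` is 0 for an un-bootstrapped
    tree.
    """

    tree: TreeNode
    supports: dict = field(default_factory=dict)
    n_boot: int = 0

    @property
    def leaf_names(self) -> list:
        return sorted(t.name for t in self.tree.tips())

    def bipartitions(self) -> set:
        """Non-trivial unrooted splits of the tree, canonicalized."""
        return tree_bipartitions(self.tree)

    def support(self, side) -> int | None:
        """Bootstrap support of the split separating ``side`` from the rest.

        ``side`` may be either side of the bipartition; returns ``None`` when
        the reference tree does not contain that split.
        """
        all_leaves = frozenset(t.name for t in self.tree.tips())
        return self.supports.get(_canonical(frozenset(side), all_leaves))


def _canonical(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Represent a split by the side not containing the smallest label."""
    ref = min(all_leaves)
    return frozenset(all_leaves - side) if ref in side else frozenset(side)


def tree_bipartitions(tree: TreeNode) -> set:
    """All non-trivial bipartitions induced by internal edges."""
    all_leaves = frozenset(t.name for t in tree.tips())
    n = len(all_leaves)
    parts = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 2:
            parts.add(_canonical(side, all_leaves))
    return parts


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> CladeTree:
    """Canonical Saitou–Nei neighbor joining.

    Deterministic: among ties of the Q criterion the smallest (i, j) pair in
    the input label order is joined.  Negative branch lengths are clamped to
    zero with a warning.  Requires n ≥ 3 taxa; n = 3 reduces to the
    three-point formulas directly.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError(f"neighbor joining needs at least 3 taxa, got {n}")

    D = dm.D.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    active = list(range(n))  # indices into D rows, stable input order

    clamped = False

    def _edge(length: float) -> float:
        nonlocal clamped
        if length < 0:
            clamped = True
            return 0.0
        return length

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # first minimum scanning i<j in input order
        best = (None, None)
        best_q = np.inf
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] < best_q - 1e-12:
                    best_q = Q[a, b]
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[a] - r[b]) / (2 * (m - 2))
        lj = d_ij - li
        parent = TreeNode()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _edge(li)
        child_j.length = _edge(lj)
        parent.extend([child_i, child_j])
        # new row reuses slot i
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - d_ij)
        nodes[i] = parent
        active.remove(j)

    # three-point join into a trifurcating root
    i, j, k = active
    d_ij, d_ik, d_jk = D[i, j], D[i, k], D[j, k]
    root = TreeNode()
    nodes[i].length = _edge(0.5 * (d_ij + d_ik - d_jk))
    nodes[j].length = _edge(0.5 * (d_ij + d_jk - d_ik))
    nodes[k].length = _edge(0.5 * (d_ik + d_jk - d_ij))
    root.extend([nodes[i], nodes[j], nodes[k]])

    if clamped:
        logger.warning("negative neighbor-joining branch lengths clamped to 0")
    return CladeTree(root)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _distance_from_presence(X: np.ndarray, labels: list, alpha: float) -> DistanceMatrix:
    """IWSS distance matrix straight from a 0/1 ndarray (columns may repeat)."""
    n, s = X.shape
    p = (X.sum(axis=0) + alpha) / (n + 2 * alpha)
    W = ScarWeights(
        scar_ids=list(range(s)), p=p, w=-np.log2(p), v=-np.log2(1 - p), alpha=alpha
    )
    Xb = X.astype(bool)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = iwss(Xb[i], Xb[j], W)
    return DistanceMatrix(labels, D)


def bootstrap_support(
    B: BinaryScarMatrix,
    n_boot: int = 100,
    seed: int | None = None,
    alpha: float = 0.5,
) -> CladeTree:
    """Reference NJ tree with bootstrap support on every internal edge.

    Each replicate resamples scar columns with replacement (same number of
    columns), recomputes weights, distances and the NJ tree, and counts how
    many replicate trees contain each reference bipartition.  Reproducible
    given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    labels = list(B.presence.index)
    X = B.presence.to_numpy().astype(np.int8)
    ref = nj_tree(_distance_from_presence(X, labels, alpha))
    ref_parts = ref.bipartitions()
    supports = {part: 0 for part in ref_parts}

    rng = np.random.default_rng(seed)
    n_scars = X.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_scars, size=n_scars)
        rep = nj_tree(_distance_from_presence(X[:, cols], labels, alpha))
        rep_parts = rep.bipartitions()
        for part in ref_parts & rep_parts:
            supports[part] += 1

    _annotate_supports(ref.tree, supports)
    return CladeTree(ref.tree, supports=supports, n_boot=n_boot)


def bipartition_frequencies(
    B: BinaryScarMatrix,
    n_boot: int = 100,
    seed: int | None = None,
    alpha: float = 0.5,
) -> dict:
    """Occurrence counts of every bipartition across bootstrap replicate trees.

    Unlike :func:`bootstrap_support`, which scores only the reference tree's
    edges, this tallies all splits the replicates produce — useful for
    comparing the support of competing groupings that may not coexist in one
    tree.
    """
    labels = list(B.presence.index)
    X = B.presence.to_numpy().astype(np.int8)
    rng = np.random.default_rng(seed)
    n_scars = X.shape[1]
    counts: dict = {}
    for _ in range(n_boot):
        cols = rng.integers(0, n_scars, size=n_scars)
        rep = nj_tree(_distance_from_presence(X[:, cols], labels, alpha))
        for part in rep.bipartitions():
            counts[part] = counts.get(part, 0) + 1
    return counts


def _annotate_supports(tree: TreeNode, supports: dict) -> None:
    all_leaves = frozenset(t.name for t in tree.tips())
    n = len(all_leaves)
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 2:
            key = _canonical(side, all_leaves)
            if key in supports:
                node.support = supports[key]


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _newick_str(node: TreeNode, as_proportion: bool, n_boot: int) -> str:
    if node.is_tip():
        label = node.name or ""
    else:
        children = ",".join(
            _newick_str(c, as_proportion, n_boot) for c in node.children
        )
        sup = getattr(node, "support", None)
        if sup is None:
            label = f"({children})"
        elif as_proportion and n_boot:
            label = f"({children}){sup / n_boot:g}"
        else:
            label = f"({children}){sup}"
    if node.length is not None:
        label += f":{node.length:.10g}"
    return label


def write_newick(
    clade_tree: CladeTree, path, support_as_proportion: bool = False
) -> None:
    """Serialize to Newick with supports as internal-node labels.

    The unrooted tree is written with the trifurcating-root convention; the
    root carries no length or label.
    """
    s = _newick_str(clade_tree.tree, support_as_proportion, clade_tree.n_boot) + ";\n"
    with open(path, "w") as fh:
        fh.write(s)


def read_newick(path, n_boot: int = 0) -> CladeTree:
    """Parse a Newick file; integer internal-node labels become supports."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    all_leaves = frozenset(t.name for t in tree.tips())
    n = len(all_leaves)
    supports = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip() or node.name is None:
            continue
        try:
            sup = int(float(node.name))
        except ValueError:
            continue
        node.support = sup
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 2:
            supports[_canonical(side, all_leaves)] = sup
    return CladeTree(tree, supports=supports, n_boot=n_boot)
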