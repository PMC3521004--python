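"""Distance-based phylogenetics: p-distances, neighbor joining, and the
congruence statistics (Robinson-Foulds distance, genus monophyly) used to
compare Csg protein trees with 16S rRNA trees.

Neighbor joining follows the Saitou-Nei Q-criterion with a deterministic
tie-break by label order, so identical inputs always give identical trees.
Additive distance matrices are recovered exactly (topology and branch
lengths). Negative branch-length estimates, which NJ can produce on noisy
matrices, are clamped to zero and flagged on the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import GAP_CHARS, Msa


@dataclass
class TreeNode:
    label: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """A (usually unrooted) tree; the root is a display anchor only."""

    root: TreeNode
    negative_branches_clamped: bool = False

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(node: TreeNode) -> None:
            if node.is_leaf():
                out.append(node)
            for c in node.children:
                rec(c)

        rec(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def to_newick(self) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_leaf():
                s = node.label or ""
            else:
                s = "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.label:
                    s += node.label
            if node.length is not None:
                s += f":{node.length:.10g}"
            return s

        return rec(self.root) + ";"

    def splits(self, nontrivial_only: bool = False) -> set[frozenset[str]]:
        """Bipartitions of the unrooted tree, each normalized to the side
        that excludes the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def below(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                side = frozenset([node.label])
            else:
                side = frozenset().union(*(below(c) for c in node.children))
            if node is not self.root:
                norm = side if ref not in side else all_leaves - side
                if norm and norm != all_leaves:
                    if not nontrivial_only or 2 <= len(norm) <= len(all_leaves) - 2:
                        splits.add(norm)
            return side

        below(self.root)
        return splits


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def p_distance(msa: Msa) -> DistanceMatrix:
    """Pairwise uncorrected distances: mismatches / compared columns,
    ignoring columns where either row carries a gap."""
    if len(msa.records) < 2:
        raise ValueError("p_distance requires >= 2 alignment rows")
    ids = msa.ids
    rows = [row for _, row in msa.records]
    arr = np.array([list(r) for r in rows])
    is_gap = np.isin(arr, list(GAP_CHARS))
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~is_gap[i] & ~is_gap[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"rows {ids[i]!r} and {ids[j]!r} share no comparable columns"
                )
            d[i, j] = d[j, i] = np.sum(arr[i][ok] != arr[j][ok]) / m
    return DistanceMatrix(ids, d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken by the sorted label pair, internal
    nodes inheriting the smallest leaf label beneath them for ordering.
    """
    labels = list(dm.labels)
    n = len(labels)
    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in labels}
    # sort key per active node: smallest original label beneath it
    keys: dict[str, str] = {lab: lab for lab in labels}
    D: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[frozenset((labels[i], labels[j]))] = float(dm.values[i, j])

    clamped = False

    def dist(a: str, b: str) -> float:
        return D[frozenset((a, b))]

    active = list(labels)
    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        best_pair = None
        ordered = sorted(active, key=lambda a: keys[a])
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = ordered[ii], ordered[jj]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                if best is None or q < best:
                    best = q
                    best_pair = (a, b)
        a, b = best_pair
        dab = dist(a, b)
        la = dab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        counter += 1
        new = f"@internal{counter}"
        node = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length = la
        nodes[b].length = lb
        nodes[new] = node
        keys[new] = min(keys[a], keys[b])
        for c in active:
            if c in (a, b):
                continue
            D[frozenset((new, c))] = (dist(a, c) + dist(b, c) - dab) / 2
        active = [c for c in active if c not in (a, b)] + [new]

    if len(active) == 1:
        return Tree(root=nodes[active[0]], negative_branches_clamped=clamped)
    if len(active) == 2:
        a, b = sorted(active, key=lambda x: keys[x])
        d = dist(a, b)
        nodes[a].length = d / 2
        nodes[b].length = d / 2
        root = TreeNode(children=[nodes[a], nodes[b]])
        return Tree(root=root, negative_branches_clamped=clamped)
    a, b, c = sorted(active, key=lambda x: keys[x])
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    if min(la, lb, lc) < 0:
        clamped = True
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root, negative_branches_clamped=clamped)


def tree_distances(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances induced by a tree."""
    leaves = sorted(tree.leaf_labels())
    idx = {lab: i for i, lab in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def rec(node: TreeNode) -> dict[str, float]:
        if node.is_leaf():
            return {node.label: 0.0}
        sub: list[dict[str, float]] = []
        for c in node.children:
            below = rec(c)
            sub.append({lab: dist + (c.length or 0.0) for lab, dist in below.items()})
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                for la, da in sub[i].items():
                    for lb, db in sub[j].items():
                        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
        merged: dict[str, float] = {}
        for s in sub:
            merged.update(s)
        return merged

    rec(tree.root)
    return DistanceMatrix(leaves, d)


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise ValueError(
            f"trees have different leaf sets ({sorted(l1 ^ l2)} not shared)"
        )
    s1 = t1.splits(nontrivial_only=True)
    s2 = t2.splits(nontrivial_only=True)
    return len(s1 ^ s2)


def genus_monophyly(
    tree: Tree, genus_of: dict[str, str]
) -> tuple[float, list[str]]:
    """Fraction of multi-member genera that form monophyletic groups.

    A genus is monophyletic when some edge of the unrooted tree separates
    exactly its leaves from all others. Returns the fraction over genera
    with >= 2 leaves plus the sorted list of violating genera.
    """
    leaves = set(tree.leaf_labels())
    missing = [l for l in leaves if l not in genus_of]
    if missing:
        raise ValueError(f"leaves without genus labels: {sorted(missing)[:5]}")
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    splits = tree.splits(nontrivial_only=False)
    by_genus: dict[str, set[str]] = {}
    for leaf in leaves:
        by_genus.setdefault(genus_of[leaf], set()).add(leaf)
    evaluated = {g: m for g, m in by_genus.items() if len(m) >= 2}
    if not evaluated:
        raise ValueError("no genus has >= 2 leaves")
    violators: list[str] = []
    for g, members in evaluated.items():
        side = frozenset(members)
        if side == all_leaves:
            continue
        norm = side if ref not in side else all_leaves - side
        if norm not in splits:
            violators.append(g)
    frac = 1.0 - len(violators) / len(evaluated)
    return frac, sorted(violators)


def read_newick(path: str | Path) -> Tree:
    """Parse a Newick file (via Bio.Phylo) into a :class:`Tree`."""
    from Bio import Phylo

    bp = Phylo.read(str(path), "newick")

    def conv(clade) -> TreeNode:
        node = TreeNode(
            label=clade.name,
            length=None if clade.branch_length is None else float(clade.branch_length),
        )
        node.children = [conv(c) for c in clade.clades]
        return node

    return Tree(root=conv(bp.root))
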