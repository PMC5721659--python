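"""Distance-based tree estimation: Jukes-Cantor distances, canonical
Saitou-Nei neighbor joining with deterministic tie-breaking, column
bootstrap, and Robinson-Foulds topology comparison.

This stage stands in for likelihood/Bayesian inference when the question
is purely topological (is the recovered topology invariant to data set and
filtering?), so trees carry branch lengths and bootstrap supports but no
model parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentMatrix

_UN = (b"A", b"C", b"G", b"T")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, zero diagonal; nan = saturated/missing

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.d).any())


@dataclass
class TreeNode:
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree (stored with an arbitrary internal root of degree 3+)."""

    root: TreeNode

    @property
    def taxa(self) -> list[str]:
        return sorted(n.name for n in self.root.leaves())

    def newick(self, with_support: bool = False) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.6g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if with_support and n.support is not None:
                label = f"{n.support:.3g}"
            return f"({inner}){label}:{n.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the frozenset of leaf names on
        the side not containing the alphabetically first taxon."""
        all_taxa = frozenset(self.taxa)
        anchor = min(all_taxa)
        out = set()

        def walk(n: TreeNode) -> frozenset:
            if n.is_leaf:
                return frozenset([n.name])
            below = frozenset().union(*(walk(c) for c in n.children))
            if 1 < len(below) < len(all_taxa) - 1:
                side = below if anchor not in below else all_taxa - below
                out.add(side)
            return below

        walk(self.root)
        return out

    def edges_with_clades(self):
        """(node, leafset-below) pairs for internal edges; used to attach supports."""
        all_taxa = frozenset(self.taxa)
        pairs = []

        def walk(n: TreeNode) -> frozenset:
            if n.is_leaf:
                return frozenset([n.name])
            below = frozenset().union(*(walk(c) for c in n.children))
            if 1 < len(below) < len(all_taxa) - 1:
                pairs.append((n, below))
            return below

        walk(self.root)
        return pairs


def jc_distance(aln: AlignmentMatrix) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances d = -(3/4) ln(1 - 4p/3).

    p is the mismatch fraction over comparable columns (both sequences
    unambiguous non-gap). A pair with p >= 3/4 is saturated and flagged
    nan; a pair with no comparable column is an error.
    """
    if aln.n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    ok = np.isin(aln.data, _UN)
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            m = int(comp.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {aln.taxa[i]} and {aln.taxa[j]}")
            p = int((comp & (aln.data[i] != aln.data[j])).sum()) / m
            if p >= 0.75:
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    return DistanceMatrix(list(aln.taxa), d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei NJ with the Q criterion.

    Ties in Q are broken by the lexicographically smallest (sorted) pair of
    cluster representative names, so the result is deterministic. Negative
    branch-length estimates are clamped to zero.
    """
    if len(dm.taxa) < 3:
        raise ValueError("NJ needs >= 3 taxa")
    if dm.has_missing:
        raise ValueError("distance matrix has missing/saturated entries")
    nodes = [TreeNode(name=t) for t in dm.taxa]
    reps = list(dm.taxa)  # lexicographic representative per active cluster
    d = dm.d.astype(float).copy()
    active = list(range(len(dm.taxa)))
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        vj = d[i, j] - vi
        ni, nj = nodes[i], nodes[j]
        ni.length = max(vi, 0.0)
        nj.length = max(vj, 0.0)
        new = TreeNode(children=[ni, nj])
        # distances from the new node
        k = len(nodes)
        newrow = np.full((1, d.shape[1] + 1), np.nan)
        d = np.vstack([np.hstack([d, np.full((d.shape[0], 1), np.nan)]), newrow])
        for mth in active:
            if mth in (i, j):
                continue
            d[k, mth] = d[mth, k] = 0.5 * (d[i, mth] + d[j, mth] - d[i, j])
        d[k, k] = 0.0
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        active = [a for a in active if a not in (i, j)] + [k]
    i, j, k = active
    # resolve the last three clusters around a single internal node
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        nodes[idx].length = max(v, 0.0)
    order = sorted((i, j, k), key=lambda a: reps[a])
    root = TreeNode(children=[nodes[a] for a in order])
    return PhyloTree(root=root)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    if t1.taxa != t2.taxa:
        raise ValueError("leaf sets differ")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2)


def bootstrap_support(aln: AlignmentMatrix, n_reps: int = 100, seed: int = 0) -> PhyloTree:
    """NJ tree on the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; each internal
    edge's support is the fraction of replicate NJ trees containing its
    bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(jc_distance(aln))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    anchor = min(tree.taxa)
    all_taxa = frozenset(tree.taxa)
    for _ in range(n_reps):
        idx = rng.integers(0, aln.n_columns, size=aln.n_columns)
        rep = aln.take_columns(idx)
        try:
            rep_tree = neighbor_joining(jc_distance(rep))
        except ValueError:
            continue  # saturated replicate
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    for node, below in tree.edges_with_clades():
        side = below if anchor not in below else all_taxa - below
        node.support = counts.get(frozenset(side), 0) / n_reps
    return tree


def parse_newick(text: str) -> PhyloTree:
    """Minimal newick reader (names, branch lengths, internal labels as support)."""
    pos = 0
    text = text.strip()

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        # name / label
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        label = text[start:pos]
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            node.length = float(text[start:pos])
        return node

    root = parse_node()
    return PhyloTree(root=root)
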