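"""Distance matrices, neighbor-joining trees, bootstrap supports, Newick I/O.

Distances are computed over the *full* core alignment (monomorphic columns
included) so branch lengths are substitutions per core site.  The built-in
tree engine is Saitou-Nei neighbor joining, which recovers any additive
distance matrix exactly; bootstrap supports come from column resampling of
the core alignment.  An export hook writes the core alignment in FASTA or
relaxed PHYLIP for external maximum-likelihood programs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import CoreAlignment

JC_SATURATION_CAP = 5.0


@dataclass
class DistanceMatrix:
    samples: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    saturated: bool = False  # any pair hit the Jukes-Cantor cap


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: TreeNode
    clamped_branches: int = 0  # negative NJ estimates clamped to zero

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(n: TreeNode) -> None:
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]


def distance_matrix(core: CoreAlignment, model: str = "jc") -> DistanceMatrix:
    """Pairwise p- or Jukes-Cantor distances per core site."""
    L = core.length
    if L == 0:
        raise ValueError("empty core alignment has no distances")
    k = len(core.samples)
    snp = core.snp_matrix()
    values = np.zeros((k, k), dtype=float)
    saturated = False
    for i in range(k):
        for j in range(i + 1, k):
            p = float((snp[i] != snp[j]).sum()) / L
            if model == "p":
                d = p
            elif model == "jc":
                if p >= 0.75:
                    d = JC_SATURATION_CAP
                    saturated = True
                else:
                    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            values[i, j] = values[j, i] = d
    return DistanceMatrix(samples=list(core.samples), values=values, saturated=saturated)


def nj_tree(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic first-minimum tie-breaks.

    Negative branch-length estimates are clamped to zero and counted on the
    returned tree.
    """
    n = len(D.samples)
    if n < 2:
        raise ValueError("need at least two samples")
    nodes: list[TreeNode] = [TreeNode(name=s) for s in D.samples]
    clamped = 0
    if n == 2:
        d = float(D.values[0, 1])
        half = max(d / 2.0, 0.0)
        for nd in nodes:
            nd.length = half
        return Tree(root=TreeNode(children=nodes), clamped_branches=0)

    dist = D.values.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
        return max(x, 0.0)  # also normalizes -0.0

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[ai].length = clamp(li)
        nodes[aj].length = clamp(lj)
        parent = TreeNode(children=[nodes[ai], nodes[aj]])
        # distances from the new node to the remaining ones
        new_row = np.zeros(dist.shape[0] + 1)
        for t, at in enumerate(active):
            if t in (i, j):
                continue
            new_row[at] = 0.5 * (sub[i, t] + sub[j, t] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
    nodes[a].length = clamp(0.5 * (dab + dac - dbc))
    nodes[b].length = clamp(0.5 * (dab + dbc - dac))
    nodes[c].length = clamp(0.5 * (dac + dbc - dab))
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root, clamped_branches=clamped)


# ---------------------------------------------------------------------------
# bipartitions and supports


def bipartitions(tree: Tree) -> dict[frozenset, TreeNode]:
    """Non-trivial bipartitions keyed by the smaller-side normalization."""
    all_leaves = frozenset(tree.leaf_names())

    out: dict[frozenset, TreeNode] = {}

    def walk(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            key = below if sorted(below) < sorted(other) else other
            out[key] = node
        return below

    walk(tree.root)
    return out


def robinson_foulds(a: Tree, b: Tree) -> int:
    """Unweighted RF distance (symmetric difference of bipartition sets)."""
    if sorted(a.leaf_names()) != sorted(b.leaf_names()):
        raise ValueError("trees have different leaf sets")
    pa, pb = set(bipartitions(a)), set(bipartitions(b))
    return len(pa ^ pb)


def bootstrap_support(
    core: CoreAlignment,
    n_reps: int = 100,
    seed: int = 42,
    model: str = "jc",
) -> Tree:
    """Point NJ tree with internal edges annotated by bootstrap percentages.

    Replicates resample full-core columns with replacement; each internal
    edge's support is the percentage of replicates containing the same leaf
    bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = nj_tree(distance_matrix(core, model))
    parts = bipartitions(point)
    if not parts:
        return point
    counts = {key: 0 for key in parts}
    rng = np.random.default_rng(seed)
    L = core.length
    k = len(core.samples)
    snp = core.snp_matrix()
    diffs = {}
    for i in range(k):
        for j in range(i + 1, k):
            diffs[(i, j)] = snp[i] != snp[j]
    snp_idx = core.snp_index
    for _ in range(n_reps):
        w = np.bincount(rng.integers(0, L, L), minlength=L)
        w_snp = w[snp_idx] if len(snp_idx) else np.zeros(0, dtype=int)
        values = np.zeros((k, k), dtype=float)
        for (i, j), diff in diffs.items():
            p = float((diff * w_snp).sum()) / L
            if model == "p":
                d = p
            else:
                d = JC_SATURATION_CAP if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
            values[i, j] = values[j, i] = d
        rep = nj_tree(DistanceMatrix(samples=list(core.samples), values=values))
        for key in bipartitions(rep):
            if key in counts:
                counts[key] += 1
    for key, node in parts.items():
        node.support = 100.0 * counts[key] / n_reps
    return point


# ---------------------------------------------------------------------------
# Newick I/O


def _fmt_length(x: float) -> str:
    return f"{x:.6g}"


def write_newick(tree: Tree) -> str:
    def emit(node: TreeNode, top: bool = False) -> str:
        if node.is_leaf:
            return f"{node.name}:{_fmt_length(node.length)}"
        inner = ",".join(emit(c) for c in node.children)
        label = ""
        if node.support is not None:
            label = _fmt_length(node.support)
        if top:
            return f"({inner}){label}"
        return f"({inner}){label}:{_fmt_length(node.length)}"

    return emit(tree.root, top=True) + ";"


def read_newick(text: str) -> Tree:
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character {s[pos]!r} at {pos}")
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if node.is_leaf:
            node.name = label or None
        elif label:
            try:
                node.support = float(label)
            except ValueError:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters after position {pos}")
    tree = Tree(root=root)
    names = tree.leaf_names()
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels")
    if any(n is None for n in names):
        raise ValueError("unlabeled leaf")
    return tree


def reroot_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Re-root for display on the edge leading to ``outgroup``.

    The outgroup's branch is split in half by the new root.  Supports are
    carried on the nodes they were computed for; this is a presentation aid
    and does not change any bipartition.
    """
    # flatten to an undirected graph of fresh integer-indexed nodes
    index: dict[int, int] = {}
    meta: list[tuple[Optional[str], Optional[float]]] = []  # (name, support)
    edges: list[tuple[int, int, float]] = []

    def reg(node: TreeNode) -> int:
        if id(node) not in index:
            index[id(node)] = len(meta)
            meta.append((node.name, node.support))
        return index[id(node)]

    def walk(node: TreeNode) -> None:
        u = reg(node)
        for c in node.children:
            v = reg(c)
            edges.append((u, v, c.length))
            walk(c)

    walk(tree.root)
    target_idx = next(
        (index[id(l)] for l in tree.leaves() if l.name == outgroup), None
    )
    if target_idx is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(meta))}
    for u, v, ln in edges:
        adj[u].append((v, ln))
        adj[v].append((u, ln))
    (neighbor, blen), = adj[target_idx]  # a leaf has exactly one edge

    def build(u: int, came_from: int, length: float) -> TreeNode:
        name, support = meta[u]
        node = TreeNode(name=name, support=support, length=length)
        for v, ln in adj[u]:
            if v != came_from:
                node.children.append(build(v, u, ln))
        # drop degree-2 pass-through of the old root
        if len(node.children) == 1 and node.name is None:
            child = node.children[0]
            child.length += node.length
            return child
        return node

    root = TreeNode()
    root.children = [
        build(target_idx, neighbor, blen / 2.0),
        build(neighbor, target_idx, blen / 2.0),
    ]
    return Tree(root=root, clamped_branches=tree.clamped_branches)


def write_phylip(core: CoreAlignment, path) -> None:
    """Relaxed PHYLIP export of the full core alignment."""
    from ._seq import decode

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f" {len(core.samples)} {core.length}\n")
        for i, s in enumerate(core.samples):
            fh.write(f"{s}  {decode(core.matrix[i])}\n")
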