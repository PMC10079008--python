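"""Distance-based phylogeny: p/Poisson distances, neighbor joining with
deterministic tie-breaking, column-bootstrap supports, Robinson–Foulds.

The tree is used here to verify orthology — does the rescued gene cluster
where the species phylogeny says it should — so topology-level inference
with bootstrap supports is the deliverable; no likelihood model is fit.
Trees are unrooted, represented with a trifurcating root node.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .align import MSA

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    name: str | None = None
    branch_length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


def _fmt_bl(x: float) -> str:
    return np.format_float_positional(x, precision=6, unique=False,
                                      fractional=False)


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root) with branch lengths and optional
    per-clade bootstrap supports in [0, 100]."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        names = []
        for leaf in self.root.leaves():
            if leaf.name is None or leaf.name == "":
                raise ValueError("tree contains an unnamed leaf")
            names.append(leaf.name)
        return names

    def to_newick(self) -> str:
        names = self.leaf_names
        if len(names) != len(set(names)):
            raise ValueError("duplicate leaf names")

        def render(node: TreeNode, top: bool = False) -> str:
            if node.is_leaf():
                body = node.name
            else:
                inner = ",".join(render(ch) for ch in node.children)
                label = ""
                if node.support is not None:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{_fmt_bl(node.branch_length)}"

        return render(self.root, top=True) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each encoded as the leaf set on the side away
        from the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode, at_root: bool) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(ch, False) for ch in node.children))
            if not at_root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                splits.add(side)
            return below

        walk(self.root, True)
        return splits


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal and taxon labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(self.matrix)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.matrix < 0).any():
            raise ValueError("distances must be non-negative")


def pairwise_distances(msa: "MSA", model: str = "p") -> DistanceMatrix:
    """p or Poisson-corrected distances over columns where neither row has a
    gap.

    p = mismatches / compared columns; poisson: d = -ln(1 - p).  A pair with
    zero comparable columns, or p = 1 under the Poisson model, is an error.
    """
    if model not in ("p", "poisson"):
        raise ValueError("model must be 'p' or 'poisson'")
    ids = msa.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 rows")
    mat = np.array([np.frombuffer(row.encode(), dtype=np.uint8)
                    for row in msa.rows])
    gap = mat == ord("-")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            total = int(ok.sum())
            if total == 0:
                raise ValueError(f"no comparable columns for {ids[i]!r}/{ids[j]!r}")
            p = float((mat[i, ok] != mat[j, ok]).sum()) / total
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance 1.0 between {ids[i]!r}/{ids[j]!r}: "
                        "Poisson correction undefined"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=list(ids), matrix=d)


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing the Q-criterion; ties are broken by
    lexicographic order of the joined clusters' smallest leaf names.  Negative
    branch lengths are clamped to zero (logged).  Returns an unrooted tree.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: dict[int, TreeNode] = {i: TreeNode(name=lab) for i, lab in enumerate(dist.labels)}
    keys: dict[int, str] = {i: lab for i, lab in enumerate(dist.labels)}
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dist.matrix[i, j])

    def d(a: int, b: int) -> float:
        return 0.0 if a == b else D[(min(a, b), max(a, b))]

    def clamp(x: float) -> float:
        if x < 0:
            logger.info("nj_tree: clamping negative branch length %.4g to 0", x)
            return 0.0
        return x

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        r = len(active)
        row_sums = {a: sum(d(a, b) for b in active) for a in active}
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                q = (r - 2) * d(a, b) - row_sums[a] - row_sums[b]
                tie = tuple(sorted((keys[a], keys[b])))
                cand = (q, tie, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        la = 0.5 * d(a, b) + (row_sums[a] - row_sums[b]) / (2 * (r - 2))
        lb = d(a, b) - la
        na, nb = nodes[a], nodes[b]
        na.branch_length = clamp(la)
        nb.branch_length = clamp(lb)
        u = TreeNode(children=[na, nb])
        nodes[next_id] = u
        keys[next_id] = min(keys[a], keys[b])
        for c in active:
            if c in (a, b):
                continue
            D[(min(c, next_id), max(c, next_id))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1

    a, b, c = sorted(active, key=lambda x: keys[x])
    la = clamp(0.5 * (d(a, b) + d(a, c) - d(b, c)))
    lb = clamp(0.5 * (d(a, b) + d(b, c) - d(a, c)))
    lc = clamp(0.5 * (d(a, c) + d(b, c) - d(a, b)))
    for node_id, bl in ((a, la), (b, lb), (c, lc)):
        nodes[node_id].branch_length = bl
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root)


def bootstrap_supports(msa: "MSA", n_replicates: int = 500, seed: int = 0,
                       model: str = "poisson") -> PhyloTree:
    """NJ tree from the full alignment with column-bootstrap supports.

    Columns are resampled with replacement per replicate; the support of each
    internal edge of the original tree is the percent of replicate trees
    containing that bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_tree(pairwise_distances(msa, model))
    target_splits = tree.bipartitions()
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    n_cols = len(msa.rows[0])
    from .align import MSA as _MSA  # local import: avoids a module cycle
    for _ in range(n_replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(row[i] for i in idx) for row in msa.rows]
        rep = _MSA(ids=list(msa.ids), rows=rep_rows, validate=False)
        rep_splits = nj_tree(pairwise_distances(rep, model)).bipartitions()
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1

    all_leaves = frozenset(tree.leaf_names)
    anchor = min(all_leaves)

    def annotate(node: TreeNode, at_root: bool) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(annotate(ch, False) for ch in node.children))
        if not at_root and 2 <= len(below) <= len(all_leaves) - 2:
            side = below if anchor not in below else all_leaves - below
            node.support = 100.0 * counts[side] / n_replicates
        return below

    annotate(tree.root, True)
    return tree


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson–Foulds distance: bipartitions present in exactly one tree."""
    if set(t1.leaf_names) != set(t2.leaf_names):
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def path_length_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (the additive distances the tree encodes)."""
    leaves = tree.root.leaves()
    labels = [lf.name for lf in leaves]
    parent: dict[int, TreeNode | None] = {id(tree.root): None}

    def index(node: TreeNode) -> None:
        for ch in node.children:
            parent[id(ch)] = node
            index(ch)

    index(tree.root)

    def depth_chain(node: TreeNode) -> dict[int, float]:
        chain = {}
        total = 0.0
        cur: TreeNode | None = node
        while cur is not None:
            chain[id(cur)] = total
            total += cur.branch_length
            cur = parent[id(cur)]
        return chain

    chains = [depth_chain(lf) for lf in leaves]
    n = len(leaves)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = chains[i], chains[j]
            best = None
            cur: TreeNode | None = leaves[j]
            total = 0.0
            while cur is not None:
                if id(cur) in ci:
                    best = ci[id(cur)] + cj[id(cur)]
                    break
                cur = parent[id(cur)]
            mat[i, j] = mat[j, i] = best
    return DistanceMatrix(labels=labels, matrix=mat)


def random_unrooted_tree(labels: list[str], seed: int = 0,
                         bl_range: tuple[float, float] = (0.05, 0.2)) -> PhyloTree:
    """Random unrooted binary topology over the labels with uniform branch
    lengths — a test/benchmark generator for additive-distance recovery."""
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    rng = np.random.default_rng(seed)
    root = TreeNode(children=[TreeNode(name=l) for l in labels[:3]])
    edges: list[tuple[TreeNode, TreeNode]] = [(root, ch) for ch in root.children]
    for label in labels[3:]:
        parent_node, child = edges[rng.integers(len(edges))]
        mid = TreeNode(children=[child, TreeNode(name=label)])
        parent_node.children[parent_node.children.index(child)] = mid
        edges = []

        def collect(node: TreeNode) -> None:
            for ch in node.children:
                edges.append((node, ch))
                collect(ch)

        collect(root)

    def assign(node: TreeNode) -> None:
        for ch in node.children:
            ch.branch_length = float(rng.uniform(*bl_range))
            assign(ch)

    assign(root)
    return PhyloTree(root=root)
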