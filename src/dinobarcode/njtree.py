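"""Neighbour joining on uncorrected distances, plus group annotation.

Classic Saitou–Nei agglomeration: at each step join the pair (i, j)
minimising the Q-criterion

    Q(i, j) = (N - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),

with branch lengths from the standard three-point formulas.  Ties are
broken by the smallest (i, j) index pair and negative estimated branch
lengths are clamped to zero (the raw estimate is retained on the node),
so identical matrices always produce identical Newick strings.

The unrooted tree is represented rooted at a trifurcating internal node
(the final three-way join); for n = 2 the trivial two-leaf tree splits
the single distance evenly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceError, DistanceMatrix

__all__ = ["TreeNode", "Tree", "neighbor_joining", "annotate_groups", "MonophylyReport"]


@dataclass
class TreeNode:
    name: str = ""
    length: float | None = None
    #: branch-length estimate before clamping (differs from length only
    #: when the NJ formula produced a negative value)
    raw_length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    #: label attached by annotate_groups when this clade is a barcode group
    group_label: str | None = None

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

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Tree:
    root: TreeNode

    @property
    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def n_edges(self) -> int:
        return sum(1 for node in self.root.walk() if node is not self.root)

    def newick(self, precision: int = 6) -> str:
        from .seqio import newick_string

        return newick_string(self, precision=precision)

    def bipartitions(self) -> dict[frozenset[str], float]:
        """Map each edge's under-root leaf set to its branch length."""
        out: dict[frozenset[str], float] = {}
        for node in self.root.walk():
            if node is self.root:
                continue
            out[node.leaf_names()] = node.length if node.length is not None else 0.0
        return out


def _clamped(node: TreeNode, raw: float) -> TreeNode:
    node.raw_length = float(raw)
    node.length = max(0.0, float(raw))
    return node


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Build the NJ tree for a distance matrix (n >= 2)."""
    n = len(dm)
    if n < 2:
        raise DistanceError("neighbour joining needs at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=sid) for sid in dm.ids]
    if n == 2:
        d = float(dm.values[0, 1])
        _clamped(nodes[0], d / 2)
        _clamped(nodes[1], d / 2)
        return Tree(root=TreeNode(children=nodes))

    D = dm.values.astype(float).copy()
    active = list(range(n))
    children: dict[int, TreeNode] = dict(enumerate(nodes))
    next_id = n
    # grow D lazily: keep a dict-of-dict for merged nodes
    dist: dict[int, dict[int, float]] = {
        i: {j: float(D[i, j]) for j in active if j != i} for i in active
    }

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i][j] for j in active if j != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m - 1):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[i][j] - r[i] - r[j]
                if q < best_q - 1e-15:  # strict improvement; first pair wins ties
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = dist[i][j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode(
            children=[_clamped(children[i], li), _clamped(children[j], lj)]
        )
        u = next_id
        next_id += 1
        dist[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = (dist[i][k] + dist[j][k] - dij) / 2
            dist[u][k] = duk
            dist[k][u] = duk
        active = [k for k in active if k not in (i, j)] + [u]
        children[u] = parent
        del dist[i], dist[j]
        for k in list(dist):
            dist[k].pop(i, None)
            dist[k].pop(j, None)

    a, b, c = active
    la = (dist[a][b] + dist[a][c] - dist[b][c]) / 2
    lb = (dist[a][b] + dist[b][c] - dist[a][c]) / 2
    lc = (dist[a][c] + dist[b][c] - dist[a][b]) / 2
    root = TreeNode(
        children=[
            _clamped(children[a], la),
            _clamped(children[b], lb),
            _clamped(children[c], lc),
        ]
    )
    tree = Tree(root=root)
    if tree.leaf_names != frozenset(dm.ids):
        raise AssertionError("NJ lost or duplicated leaves")  # pragma: no cover
    return tree


@dataclass
class MonophylyReport:
    group_id: int
    label: str
    n_members: int
    n_on_tree: int
    monophyletic: bool


def annotate_groups(tree: Tree, groups) -> list[MonophylyReport]:
    """Tag barcode groups on the tree and test each for monophyly.

    A group is monophyletic on the unrooted tree when its member set
    equals one side of some edge's bipartition (or the whole leaf set /
    a single leaf).  Members absent from the tree are warned about and
    ignored for the test.
    """
    import warnings

    all_leaves = tree.leaf_names
    clades = {node.leaf_names(): node for node in tree.root.walk()}
    reports: list[MonophylyReport] = []
    for g in groups:
        members = frozenset(g.members)
        on_tree = members & all_leaves
        if members - all_leaves:
            warnings.warn(
                f"group {g.assigned_label!r}: members not on the tree: "
                f"{sorted(members - all_leaves)}",
                stacklevel=2,
            )
        if not on_tree:
            reports.append(MonophylyReport(g.group_id, g.assigned_label, len(members), 0, False))
            continue
        mono = (
            on_tree in clades
            or (all_leaves - on_tree) in clades
            or on_tree == all_leaves
        )
        if on_tree in clades:
            clades[on_tree].group_label = g.assigned_label
        reports.append(
            MonophylyReport(g.group_id, g.assigned_label, len(members), len(on_tree), bool(mono))
        )
    return reports


def monophyly_frame(reports: list[MonophylyReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])
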