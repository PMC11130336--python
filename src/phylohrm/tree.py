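"""Rooted time-calibrated phylogenies as flat arrays.

Newick reading/writing is delegated to dendropy (quoted labels, ``[]``
comments and polytomies are handled there); the :class:`Phylogeny`
container keeps parent/children maps and branch lengths in numpy arrays
so that likelihood pruning can be vectorized over whole levels of the
tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "parse_newick", "write_newick", "find_mrca"]


class NewickParseError(ValueError):
    """Raised for malformed newick input or invalid tree structure."""


@dataclass
class Phylogeny:
    """A rooted phylogeny with branch lengths in time units (Myr).

    Node ids are integers ``0..n_nodes-1``; the root is ``root``.
    ``parent[i]`` is ``-1`` for the root.  ``length[i]`` is the length of
    the branch above node ``i`` (0 for the root).  Tips are nodes with no
    children; every tip carries a unique non-empty label.  Polytomies and
    zero-length branches are allowed.
    """

    parent: np.ndarray
    children: list[list[int]]
    length: np.ndarray
    labels: list[str | None]
    root: int

    # derived, filled in __post_init__
    postorder: np.ndarray = field(default=None, repr=False)
    tip_ids: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._validate()
        self.postorder = self._compute_postorder()
        self.tip_ids = np.array(
            [i for i in range(self.n_nodes) if not self.children[i]], dtype=int
        )
        self._label_to_id = {self.labels[i]: int(i) for i in self.tip_ids}
        self._levels = None

    # -- invariants -------------------------------------------------------
    def _validate(self) -> None:
        n = self.n_nodes
        roots = [i for i in range(n) if self.parent[i] == -1]
        if roots != [self.root]:
            raise NewickParseError(f"tree must have exactly one root, found {roots}")
        if not np.all(np.isfinite(self.length)) or np.any(self.length < 0):
            bad = int(np.argmin(self.length))
            raise NewickParseError(
                f"branch lengths must be finite and >= 0 (node {bad}: {self.length[bad]})"
            )
        tips = [i for i in range(n) if not self.children[i]]
        seen: dict[str, int] = {}
        for i in tips:
            lab = self.labels[i]
            if not lab:
                raise NewickParseError(f"tip {i} has an empty label")
            if lab in seen:
                raise NewickParseError(f"duplicate tip label {lab!r}")
            seen[lab] = i

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def tip_id(self, label: str) -> int:
        try:
            return self._label_to_id[label]
        except KeyError:
            raise KeyError(f"unknown tip label {label!r}") from None

    # -- traversals -------------------------------------------------------
    def _compute_postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:  # reverse-preorder trick: children pushed in order
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return np.array(order[::-1], dtype=int)

    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def levels(self) -> list[np.ndarray]:
        """Group nodes by height (max edge count to a descendant tip).

        All children of a node in level ``h`` live in levels ``< h``, so
        each level can be processed as one vectorized batch during
        pruning.
        """
        if self._levels is None:
            height = np.zeros(self.n_nodes, dtype=int)
            for v in self.postorder:
                for c in self.children[v]:
                    height[v] = max(height[v], height[c] + 1)
            groups: dict[int, list[int]] = {}
            for v in range(self.n_nodes):
                groups.setdefault(int(height[v]), []).append(v)
            self._levels = [np.array(groups[h], dtype=int) for h in sorted(groups)]
        return self._levels

    def node_depths(self) -> np.ndarray:
        """Time from the root to each node (root depth 0)."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.length[v]
        return depth

    def subtree_nodes(self, node: int) -> np.ndarray:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return np.array(out, dtype=int)

    def subtree_tip_labels(self, node: int) -> list[str]:
        return [self.labels[v] for v in self.subtree_nodes(node) if self.is_tip(v)]

    def mrca(self, tip_labels) -> int:
        return find_mrca(self, tip_labels)

    def total_length(self) -> float:
        return float(self.length.sum())

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            length=self.length.copy(),
            labels=list(self.labels),
            root=self.root,
        )


def _from_dendropy(dtree: dendropy.Tree, default_length: float) -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    length = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    labels: list[str | None] = [None] * n
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            el = nd.edge.length
            if el is None:
                el = default_length
            if el < 0:
                raise NewickParseError(
                    f"negative branch length {el} above "
                    f"{nd.taxon.label if nd.taxon else 'an internal node'}"
                )
            length[i] = el
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    return Phylogeny(parent=parent, children=children, length=length, labels=labels, root=0)


def parse_newick(source: str, *, default_length: float = 1.0) -> Phylogeny:
    """Parse a newick string or file path into a :class:`Phylogeny`.

    Quoted labels, comments in ``[]`` and polytomies are accepted.
    Missing branch lengths default to ``default_length``.  Duplicate tip
    labels, negative lengths and malformed newick raise
    :class:`NewickParseError` naming the offending token.
    """
    text = source
    if "(" not in source and ";" not in source:
        with open(source) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return _from_dendropy(dtree, default_length)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "()[]{}:;, \t'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Phylogeny, precision: int = 10) -> str:
    """Serialize to newick with ``precision`` significant digits on lengths.

    A single tip ``A`` of length 1 is written as ``(A:1);``; output
    round-trips through :func:`parse_newick`.
    """

    def render(v: int) -> str:
        if tree.is_tip(v):
            body = _quote_label(tree.labels[v])
        else:
            body = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
            if tree.labels[v]:
                body += _quote_label(tree.labels[v])
        if v != tree.root:
            body += f":{tree.length[v]:.{precision}g}"
        return body

    if tree.is_tip(tree.root):
        return f"({_quote_label(tree.labels[tree.root])}:{tree.length[tree.root]:.{precision}g});"
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, tree.n_nodes + 100))
    try:
        return render(tree.root) + ";"
    finally:
        sys.setrecursionlimit(old)


def find_mrca(tree: Phylogeny, tip_labels) -> int:
    """Most recent common ancestor of a set of tips (a single tip is its
    own MRCA)."""
    ids = [tree.tip_id(lab) for lab in tip_labels]
    if not ids:
        raise ValueError("empty tip set")
    paths = []
    for v in ids:
        path = [v]
        while tree.parent[path[-1]] != -1:
            path.append(int(tree.parent[path[-1]]))
        paths.append(path[::-1])  # root .. tip
    mrca = tree.root
    for cols in zip(*paths):
        if len(set(cols)) == 1:
            mrca = cols[0]
        else:
            break
    return int(mrca)
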