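"""Rooted cell-type hierarchies: parsing, adjacency encoding, ancestry queries.

The label space of the diffusion model is the set of all nodes of a rooted
tree whose leaves are specific cell types and whose internal nodes are
broader groupings.  For a strictly binary tree with ``n`` leaves the tree has
``2n - 1`` nodes in total; arbitrary arity is accepted and all downstream
logic uses ``node_count`` rather than the binary-tree arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class TreeFormatError(ValueError):
    """Raised for malformed or ambiguous tree input."""


@dataclass(frozen=True)
class CellTypeTree:
    """A rooted cell-type tree with a stable node ordering.

    Nodes are ordered leaves first (in input order), then internal nodes in
    postorder, so the root is always last.  This ordering is the row/column
    convention for every matrix over tree nodes.
    """

    nodes: tuple[str, ...]
    parent_of: dict[str, str | None]
    leaf_names: tuple[str, ...]
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.nodes)})
        self._validate()

    # -- construction -----------------------------------------------------

    @staticmethod
    def from_parent_map(parent_of: dict[str, str | None], leaf_order: list[str] | None = None) -> "CellTypeTree":
        roots = [n for n, p in parent_of.items() if p is None]
        if len(roots) != 1:
            raise TreeFormatError(f"tree must have exactly one root, found {len(roots)}")
        children: dict[str, list[str]] = {n: [] for n in parent_of}
        for n, p in parent_of.items():
            if p is not None:
                if p not in parent_of:
                    raise TreeFormatError(f"parent {p!r} of {n!r} is not a node")
                children[p].append(n)
        leaves = [n for n in parent_of if not children[n]]
        if leaf_order is not None:
            if set(leaf_order) != set(leaves):
                raise TreeFormatError("leaf_order does not match the leaves of the tree")
            leaves = list(leaf_order)
        internal: list[str] = []
        seen: set[str] = set()

        def post(node: str) -> None:
            if node in seen:
                raise TreeFormatError(f"cycle detected at node {node!r}")
            seen.add(node)
            for ch in children[node]:
                post(ch)
            if children[node]:
                internal.append(node)

        post(roots[0])
        if len(seen) != len(parent_of):
            raise TreeFormatError("tree contains nodes unreachable from the root")
        return CellTypeTree(
            nodes=tuple(leaves) + tuple(internal),
            parent_of=dict(parent_of),
            leaf_names=tuple(leaves),
        )

    def _validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise TreeFormatError("duplicate node names")
        roots = [n for n in self.nodes if self.parent_of.get(n) is None]
        if len(roots) != 1:
            raise TreeFormatError("tree must have exactly one root")
        if self.nodes[-1] != roots[0] and len(self.nodes) > 1:
            raise TreeFormatError("root must be the last node in the ordering")
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise TreeFormatError("duplicate leaf names")

    # -- basic queries -----------------------------------------------------

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def root(self) -> str:
        return self.nodes[-1]

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown tree node {node!r}") from None

    def children_of(self, node: str) -> list[str]:
        # parent_of insertion order preserves the input child order
        self.index(node)
        return [n for n, p in self.parent_of.items() if p == node]

    def internal_nodes(self) -> tuple[str, ...]:
        return self.nodes[self.n_leaves:]

    def ancestors(self, node: str) -> list[str]:
        """Strict ancestors of ``node``, nearest first, ending at the root."""
        self.index(node)
        out = []
        p = self.parent_of.get(node)
        while p is not None:
            out.append(p)
            p = self.parent_of.get(p)
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` lies strictly on the path from ``b`` to the root."""
        self.index(a)
        return a in self.ancestors(b)

    # -- adjacency ---------------------------------------------------------

    def adjacency(self) -> np.ndarray:
        """Binary symmetric adjacency over tree nodes (1 per parent-child edge)."""
        m = self.node_count
        A = np.zeros((m, m), dtype=float)
        for n, p in self.parent_of.items():
            if p is not None:
                i, j = self.index(n), self.index(p)
                A[i, j] = A[j, i] = 1.0
        return A


def encode_tree_adjacency(tree: CellTypeTree) -> np.ndarray:
    """Symmetric binary adjacency matrix of the tree, zero diagonal."""
    return tree.adjacency()


def decode_tree_adjacency(A: np.ndarray, nodes: list[str], root: str) -> dict[str, str | None]:
    """Recover the parent map from an adjacency matrix and a designated root.

    Inverse of :func:`encode_tree_adjacency`; used for round-trip checks.
    """
    idx = {n: i for i, n in enumerate(nodes)}
    parent: dict[str, str | None] = {root: None}
    stack = [root]
    while stack:
        cur = stack.pop()
        for other in nodes:
            if other not in parent and A[idx[cur], idx[other]]:
                parent[other] = cur
                stack.append(other)
    if len(parent) != len(nodes):
        raise TreeFormatError("adjacency matrix is not a connected tree")
    return parent


# ---------------------------------------------------------------------------
# parsing


def _name_internal(children_names: list[str]) -> str:
    return "+".join(children_names)


def parse_newick(text: str) -> CellTypeTree:
    """Parse a rooted Newick string into a :class:`CellTypeTree`.

    Leaf names are mandatory; internal names are honoured when present and
    otherwise generated deterministically by joining the ordered child names
    with ``+``.  Branch lengths are ignored.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=False)
    except Exception as exc:  # dendropy raises several error types
        raise TreeFormatError(f"could not parse Newick input: {exc}") from exc

    parent: dict[str, str | None] = {}
    leaves: list[str] = []
    names: dict[int, str] = {}

    def label(nd) -> str | None:
        if nd.taxon is not None and nd.taxon.label:
            return nd.taxon.label
        return nd.label or None

    def walk(nd) -> str:
        kids = nd.child_nodes()
        if not kids:
            name = label(nd)
            if name is None:
                raise TreeFormatError("leaf without a name")
            if name in parent:
                raise TreeFormatError(f"duplicate leaf name {name!r}")
            leaves.append(name)
            names[id(nd)] = name
            return name
        child_names = [walk(k) for k in kids]
        name = label(nd) or _name_internal(child_names)
        if name in parent or name in child_names:
            raise TreeFormatError(f"duplicate node name {name!r}")
        names[id(nd)] = name
        parent[name] = None
        for cn in child_names:
            parent[cn] = name
        return name

    root = dtree.seed_node
    # collapse unary chains at the root such as "(A);" down to the single child
    while len(root.child_nodes()) == 1:
        root = root.child_nodes()[0]
    root_name = walk(root)
    if not leaves:
        raise TreeFormatError("tree has no leaves")
    for leaf in leaves:
        parent.setdefault(leaf, None)
    parent[root_name] = None
    return CellTypeTree.from_parent_map(parent, leaf_order=leaves)


def parse_json_tree(source: str | dict) -> CellTypeTree:
    """Parse the ``{"name": ..., "children": [...]}`` dialect."""
    obj = json.loads(source) if isinstance(source, str) else source
    parent: dict[str, str | None] = {}
    leaves: list[str] = []

    def walk(node: dict) -> str:
        kids = node.get("children") or []
        if not kids:
            name = node.get("name")
            if not name:
                raise TreeFormatError("leaf without a name")
            if name in parent:
                raise TreeFormatError(f"duplicate leaf name {name!r}")
            leaves.append(name)
            return name
        child_names = [walk(k) for k in kids]
        name = node.get("name") or _name_internal(child_names)
        if name in parent:
            raise TreeFormatError(f"duplicate node name {name!r}")
        parent[name] = None
        for cn in child_names:
            parent[cn] = name
        return name

    walk(obj)
    for leaf in leaves:
        parent.setdefault(leaf, None)
    return CellTypeTree.from_parent_map(parent, leaf_order=leaves)


def parse_tree(source: str) -> CellTypeTree:
    """Parse a tree in Newick or JSON dialect (auto-detected)."""
    stripped = source.strip()
    if stripped.startswith("{"):
        return parse_json_tree(stripped)
    return parse_newick(stripped)


def star_tree(leaf_names: list[str], root_name: str = "root") -> CellTypeTree:
    """A flat tree: every leaf is a direct child of the root.

    This is the non-hierarchical comparison model: labels diffuse to leaves
    only, with no intermediate groupings.
    """
    if len(leaf_names) != len(set(leaf_names)):
        raise TreeFormatError("duplicate leaf names")
    if len(leaf_names) == 1 and leaf_names[0] == root_name:
        return CellTypeTree(nodes=(root_name,), parent_of={root_name: None}, leaf_names=(root_name,))
    parent: dict[str, str | None] = {name: root_name for name in leaf_names}
    parent[root_name] = None
    return CellTypeTree.from_parent_map(parent, leaf_order=list(leaf_names))


def balanced_binary_tree(leaf_names: list[str]) -> CellTypeTree:
    """Balanced binary hierarchy over the given leaves (recursive halving)."""
    if len(leaf_names) != len(set(leaf_names)):
        raise TreeFormatError("duplicate leaf names")
    parent: dict[str, str | None] = {}

    def build(names: list[str]) -> str:
        if len(names) == 1:
            parent.setdefault(names[0], None)
            return names[0]
        mid = (len(names) + 1) // 2
        left = build(names[:mid])
        right = build(names[mid:])
        name = _name_internal([left, right])
        parent[name] = None
        parent[left] = name
        parent[right] = name
        return name

    build(list(leaf_names))
    return CellTypeTree.from_parent_map(parent, leaf_order=list(leaf_names))


def caterpillar_tree(leaf_names: list[str]) -> CellTypeTree:
    """Maximally unbalanced (caterpillar) binary hierarchy."""
    if len(leaf_names) < 1:
        raise TreeFormatError("need at least one leaf")
    parent: dict[str, str | None] = {leaf_names[0]: None}
    spine = leaf_names[0]
    for name in leaf_names[1:]:
        joint = _name_internal([spine, name])
        parent[joint] = None
        parent[spine] = joint
        parent[name] = joint
        spine = joint
    return CellTypeTree.from_parent_map(parent, leaf_order=list(leaf_names))


def random_binary_tree(leaf_names: list[str], seed: int) -> CellTypeTree:
    """Random binary topology via seeded pairwise joins."""
    rng = np.random.default_rng(seed)
    if len(leaf_names) < 1:
        raise TreeFormatError("need at least one leaf")
    parent: dict[str, str | None] = {n: None for n in leaf_names}
    active = list(leaf_names)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        joint = _name_internal([a, b])
        parent[joint] = None
        parent[a] = joint
        parent[b] = joint
        active = [n for k, n in enumerate(active) if k not in (i, j)] + [joint]
    return CellTypeTree.from_parent_map(parent, leaf_order=list(leaf_names))
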