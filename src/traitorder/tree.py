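"""Rooted phylogenies with *ordered* children.

The statistic at the heart of this package is computed from the left-to-right
order in which tips appear when a tree is written in Newick notation.  That
order is carried by the ordered child lists of the internal nodes, and it is
changed -- without changing the topology -- by *rotating* nodes, i.e. reversing
their child lists.  The :class:`Tree` here therefore keeps child order as a
first-class citizen, unlike containers that treat trees as unordered.

Parsing of Newick/NEXUS is delegated to dendropy; writing is done here so that
rotation states can be applied exactly.  Branch lengths are in whatever time
unit the input tree uses (My for typical dated supertrees); no conversion is
performed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "NotUltrametricError",
    "Node",
    "Tree",
    "RotationState",
    "parse_newick",
    "read_tree",
    "write_newick",
    "tip_order",
    "crown_age",
    "is_ultrametric",
    "check_ultrametric",
    "resolve_polytomies",
    "subtree",
    "prune_tips",
]

#: below this relative spread in tip depths a tree is silently ultrametric
ULTRAMETRIC_RTOL = 1e-6
#: between ULTRAMETRIC_RTOL and this, warn but proceed (dated supertrees carry
#: rounding noise in published branch lengths)
ULTRAMETRIC_WARN_RTOL = 1e-3


class TreeError(ValueError):
    """Invalid tree structure or tree/data mismatch."""


class NewickParseError(TreeError):
    """Malformed Newick/NEXUS input."""


class NotUltrametricError(TreeError):
    """Operation requires an ultrametric tree (all tips equidistant from root)."""


class Node:
    """A tree node: optional label, branch length to parent, ordered children."""

    __slots__ = ("label", "length", "children", "parent", "id")

    def __init__(self, label=None, length=None, children=None):
        self.label: Optional[str] = label
        self.length: Optional[float] = length
        self.children: list[Node] = list(children) if children else []
        self.parent: Optional[Node] = None
        self.id: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node id={self.id} {kind} label={self.label!r} length={self.length}>"


@dataclass(frozen=True)
class RotationState:
    """Which internal nodes have their child order reversed.

    Applying the same state twice restores the original tip order (reversal is
    an involution), and composing two states is the symmetric difference of
    their flipped sets.
    """

    flipped: frozenset = field(default_factory=frozenset)

    @classmethod
    def identity(cls) -> "RotationState":
        return cls(frozenset())

    @classmethod
    def of(cls, node_ids: Iterable[int]) -> "RotationState":
        return cls(frozenset(node_ids))

    def is_flipped(self, node_id: int) -> bool:
        return node_id in self.flipped

    def compose(self, other: "RotationState") -> "RotationState":
        return RotationState(self.flipped ^ other.flipped)

    def __len__(self) -> int:
        return len(self.flipped)


class Tree:
    """Rooted tree with ordered children and stable node ids.

    Node ids are assigned in preorder at construction and preserved by
    :meth:`copy`, :meth:`apply_rotation` and :func:`subtree`, so a
    :class:`RotationState` keyed by ids remains meaningful across those
    operations.
    """

    def __init__(self, root: Node, _assign_ids: bool = True):
        self.root = root
        if _assign_ids:
            for i, node in enumerate(self._preorder(root)):
                node.id = i
        for node in self._preorder(root):
            for child in node.children:
                child.parent = node
        self.root.parent = None
        self._validate()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _preorder(root: Node) -> Iterator[Node]:
        stack = [root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def _validate(self) -> None:
        labels = [t.label for t in self.tips]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeError("every tip must carry a non-empty label")
        seen: set[str] = set()
        for lbl in labels:
            if lbl in seen:
                raise TreeError(f"duplicate tip label: {lbl!r}")
            seen.add(lbl)
        for node in self.nodes:
            if node is not self.root and node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length {node.length} at node {node.id}")
            if len(node.children) == 1:
                raise TreeError(f"unifurcation at node {node.id}; suppress it first")

    # -- basic accessors ------------------------------------------------------

    @property
    def nodes(self) -> list[Node]:
        """All nodes in preorder."""
        return list(self._preorder(self.root))

    @property
    def tips(self) -> list[Node]:
        """Leaves in left-to-right order."""
        return [n for n in self.nodes if n.is_leaf]

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes if not n.is_leaf]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def node(self, node_id: int) -> Node:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(f"no node with id {node_id}")

    @property
    def is_bifurcating(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes)

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.nodes if n is not self.root)

    def depths(self) -> dict[int, float]:
        """Time from the root to every node (root at 0)."""
        if not self.has_branch_lengths():
            raise TreeError("tree has missing branch lengths")
        out = {self.root.id: 0.0}
        for node in self.nodes:
            if node is self.root:
                continue
            out[node.id] = out[node.parent.id] + node.length
        return out

    def tip_depths(self) -> dict[str, float]:
        d = self.depths()
        return {t.label: d[t.id] for t in self.tips}

    # -- order / rotation -----------------------------------------------------

    def tip_order(self, rotation: Optional[RotationState] = None) -> list[str]:
        """Left-to-right tip labels, optionally under a rotation state."""
        if rotation is None:
            return [t.label for t in self.tips]
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.label)
                continue
            children = node.children
            if rotation.is_flipped(node.id):
                children = list(reversed(children))
            stack.extend(reversed(children))
        return out

    def copy(self) -> "Tree":
        return Tree(self._clone(self.root), _assign_ids=False)

    @staticmethod
    def _clone(node: Node) -> Node:
        new = Node(node.label, node.length)
        new.id = node.id
        new.children = [Tree._clone(c) for c in node.children]
        return new

    def apply_rotation(self, rotation: RotationState) -> "Tree":
        """Return a new tree with child lists reversed at the flagged nodes."""
        known = {n.id for n in self.internal_nodes}
        unknown = rotation.flipped - known
        if unknown:
            raise TreeError(f"rotation refers to unknown internal node ids: {sorted(unknown)}")
        root = self._clone(self.root)
        new = Tree(root, _assign_ids=False)
        for node in new.nodes:
            if rotation.is_flipped(node.id):
                node.children.reverse()
        return new

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Tree n_tips={self.n_tips}>"


# -- Newick / NEXUS I/O -------------------------------------------------------


def _from_dendropy(dtree: "dendropy.Tree") -> Tree:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        else:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return Tree(convert(dtree.seed_node))


def parse_newick(text: str) -> Tree:
    """Parse a single rooted Newick string, preserving literal child order.

    Quoted labels, internal node labels and square-bracket comments are
    accepted.  Malformed input raises :class:`NewickParseError` carrying the
    position reported by the underlying reader; duplicate tip labels raise
    :class:`TreeError`.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_tree(path, schema: str = "newick") -> Tree:
    """Read the first tree from a Newick or NEXUS file (translate tables honored)."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path),
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise NewickParseError(f"could not read {path}: {exc}") from exc
    return _from_dendropy(dtree)


_NEEDS_QUOTE = re.compile(r"[\s(),:;\[\]']")


def _format_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(
    tree: Tree,
    rotation: Optional[RotationState] = None,
    include_lengths: bool = True,
) -> str:
    """Write a tree as Newick; tip order reflects the rotation if given."""

    def render(node: Node) -> str:
        if node.is_leaf:
            s = _format_label(node.label)
        else:
            children = node.children
            if rotation is not None and rotation.is_flipped(node.id):
                children = list(reversed(children))
            s = "(" + ",".join(render(c) for c in children) + ")"
            if node.label:
                s += _format_label(node.label)
        if include_lengths and node.length is not None and node is not tree.root:
            s += f":{node.length:.12g}"
        return s

    return render(tree.root) + ";"


# -- temporal bookkeeping -----------------------------------------------------


def tip_order(tree: Tree) -> list[str]:
    """Left-to-right leaf sequence implied by the ordered child lists."""
    return tree.tip_order()


def crown_age(tree: Tree) -> float:
    """Maximum root-to-tip path length (the crown age for ultrametric trees)."""
    if tree.n_tips < 2:
        raise TreeError("crown age needs at least 2 tips")
    return max(tree.tip_depths().values())


def is_ultrametric(tree: Tree, rel_tol: float = ULTRAMETRIC_RTOL) -> bool:
    """True iff all tip depths agree within ``rel_tol`` x crown age."""
    depths = list(tree.tip_depths().values())
    age = max(depths)
    if age == 0:
        return True
    return (age - min(depths)) <= rel_tol * age


def check_ultrametric(tree: Tree, what: str = "this operation") -> None:
    """Raise beyond the warn tolerance; warn in the rounding-noise band."""
    if is_ultrametric(tree, ULTRAMETRIC_RTOL):
        return
    if is_ultrametric(tree, ULTRAMETRIC_WARN_RTOL):
        warnings.warn(
            f"tree is only approximately ultrametric (tip depth spread between "
            f"{ULTRAMETRIC_RTOL:g} and {ULTRAMETRIC_WARN_RTOL:g} of crown age); "
            f"proceeding with {what}",
            stacklevel=3,
        )
        return
    raise NotUltrametricError(f"{what} requires an ultrametric tree")


# -- editing ------------------------------------------------------------------


def resolve_polytomies(tree: Tree, seed: int) -> Tree:
    """Randomly resolve multifurcations into bifurcations (seeded).

    Introduced internal branches have zero length, so depths and crown age are
    unchanged.  Already bifurcating trees are returned as an identical copy.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    root = Tree._clone(tree.root)

    def resolve(node: Node) -> None:
        for child in node.children:
            resolve(child)
        while len(node.children) > 2:
            i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
            a = node.children[i]
            b = node.children[j]
            joined = Node(length=0.0, children=[a, b])
            rest = [c for k, c in enumerate(node.children) if k not in (i, j)]
            node.children = rest[:i] + [joined] + rest[i:]

    resolve(root)
    return Tree(root)


def subtree(tree: Tree, node_id: int) -> Tree:
    """The clade rooted at ``node_id`` as a standalone tree (ids preserved)."""
    node = tree.node(node_id)
    if node.is_leaf:
        raise TreeError("subtree must be rooted at an internal node")
    root = Tree._clone(node)
    root.length = None
    return Tree(root, _assign_ids=False)


def prune_tips(tree: Tree, drop: Iterable[str]) -> Tree:
    """Remove the named tips, suppressing resulting unifurcations.

    Branch lengths of suppressed nodes are summed into the retained child so
    root-to-tip distances of surviving tips are preserved.
    """
    drop = set(drop)
    missing = drop - {t.label for t in tree.tips}
    if missing:
        raise TreeError(f"cannot prune tips not in tree: {sorted(missing)}")

    def rebuild(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.label in drop:
                return None
            new = Node(node.label, node.length)
            new.id = node.id
            return new
        kids = [rebuild(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if node.length is not None and child.length is not None:
                child.length = child.length + node.length
            elif node.length is not None:
                child.length = node.length
            return child
        new = Node(node.label, node.length)
        new.id = node.id
        new.children = kids
        return new

    root = rebuild(tree.root)
    if root is None or root.is_leaf:
        raise TreeError("pruning left fewer than 2 tips")
    root.length = None
    return Tree(root, _assign_ids=False)
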