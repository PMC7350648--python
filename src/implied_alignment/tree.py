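"""Rooted strictly-binary guide trees and leaf decoration.

The implied alignment is defined on a *rooted, strictly binary* tree: the
bracketing of the tree fixes the order in which the non-associative pairwise
alignment is applied, so rooting is required to be explicit and polytomies
are rejected rather than silently resolved.  Child order (left/right) is
preserved as written, although the result is invariant to transposing it.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterator, Mapping, Sequence

import dendropy

from .alphabet import BOTH, Alphabet, TaggedElement
from .pairwise import Context

__all__ = ["Node", "DecoratedTree", "parse_newick", "decorate_leaves", "lift"]


class Node:
    """One node of a decorated tree.

    Decorations are filled in by the traversal passes: ``prelim`` and
    ``cost`` by the post-order pass, ``final`` by the pre-order pass.
    """

    __slots__ = (
        "name",
        "left",
        "right",
        "parent",
        "prelim",
        "cost",
        "final",
        "sequence",
    )

    def __init__(self, name: str | None = None) -> None:
        self.name = name
        self.left: Node | None = None
        self.right: Node | None = None
        self.parent: Node | None = None
        self.prelim: Context | None = None
        self.cost: int | float | None = None
        self.final: Context | None = None
        self.sequence: list[int] | None = None  # leaf residue masks

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.name!r})" if self.name else "Node(<internal>)"


class DecoratedTree:
    """A rooted strictly binary tree with per-node alignment decorations."""

    def __init__(self, root: Node) -> None:
        self.root = root
        self._leaves = [n for n in self.postorder() if n.is_leaf]
        names = [n.name for n in self._leaves]
        if any(name is None for name in names):
            raise ValueError("every leaf must be named")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")

    @property
    def leaves(self) -> list[Node]:
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def postorder(self) -> Iterator[Node]:
        """Iterative post-order traversal (children before parent)."""
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                stack.append((node.right, False))  # type: ignore[arg-type]
                stack.append((node.left, False))  # type: ignore[arg-type]

    def preorder(self) -> Iterator[Node]:
        """Iterative pre-order traversal (parent first, left before right)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)  # type: ignore[arg-type]
                stack.append(node.left)  # type: ignore[arg-type]

    def to_newick(self) -> str:
        """Serialize topology and leaf names (decorations are not written)."""
        parts: list[str] = []

        def emit(node: Node) -> None:
            if node.is_leaf:
                parts.append(node.name)  # type: ignore[arg-type]
            else:
                parts.append("(")
                emit(node.left)  # type: ignore[arg-type]
                parts.append(",")
                emit(node.right)  # type: ignore[arg-type]
                parts.append(")")

        emit(self.root)
        parts.append(";")
        return "".join(parts)


def parse_newick(text: str) -> DecoratedTree:
    """Parse a rooted strictly binary Newick tree.

    Branch lengths and internal-node labels are parsed and ignored.
    Polytomies (including an unrooted trifurcating root) are rejected:
    rooting changes the implied alignment and must be explicit.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"Newick syntax error: {exc}") from None

    def convert(dnode) -> Node:
        children = dnode.child_nodes()
        if not children:
            if dnode.taxon is None or not dnode.taxon.label:
                raise ValueError("Newick tree contains an unnamed leaf")
            return Node(dnode.taxon.label)
        if len(children) != 2:
            raise ValueError(
                f"tree must be strictly binary; found a node with "
                f"{len(children)} children (re-root or resolve polytomies "
                f"explicitly)"
            )
        node = Node()
        node.left = convert(children[0])
        node.right = convert(children[1])
        node.left.parent = node
        node.right.parent = node
        return node

    root = convert(dtree.seed_node)
    if root.is_leaf:
        raise ValueError("tree must have at least two leaves")
    return DecoratedTree(root)


def lift(sequence: Sequence[int]) -> Context:
    """Lift a raw residue-set sequence into an initial context.

    Each residue set X becomes ``BOTH(X, X)``: a leaf has no subtree
    asymmetry and the element's effective set must be X itself.
    """
    return [TaggedElement(BOTH, m, m) for m in sequence]


def decorate_leaves(
    tree: DecoratedTree,
    sequences: Mapping[str, Sequence[int]],
    alphabet: Alphabet,
) -> DecoratedTree:
    """Bind sequences to leaves and initialize leaf decorations.

    Every leaf receives cost 0 and a preliminary context lifted from its raw
    sequence.  Leaf names of the tree and the sequence mapping must match
    exactly.
    """
    tree_names = {leaf.name for leaf in tree.leaves}
    seq_names = set(sequences)
    missing = sorted(tree_names - seq_names)
    if missing:
        raise ValueError(f"tree leaves without a sequence: {missing}")
    extra = sorted(seq_names - tree_names)
    if extra:
        raise ValueError(f"sequences without a tree leaf: {extra}")
    full = alphabet.full_mask
    for leaf in tree.leaves:
        seq = list(sequences[leaf.name])  # type: ignore[index]
        if any(not (0 < m <= full) for m in seq):
            raise ValueError(
                f"sequence for leaf {leaf.name!r} contains a residue set "
                f"outside the alphabet"
            )
        if not seq:
            warnings.warn(
                f"leaf {leaf.name!r} has an empty sequence; its row will "
                "be all gaps",
                stacklevel=2,
            )
        leaf.sequence = seq
        leaf.prelim = lift(seq)
        leaf.cost = 0
        leaf.final = None
    return tree
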