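"""The two traversal passes that produce the implied alignment.

Post-order pass: every internal node is decorated with the tagged pairwise
alignment of its two children's preliminary contexts, and with the
accumulated subtree cost.  At the root, the context summarizes the whole
leaf set and the cost is the tree cost.

Pre-order pass: the root's preliminary context becomes its final alignment;
every other node's final alignment is derived from its parent by a "sliding
zip" — a single linear scan of the parent's final alignment that propagates
ancestral gaps downward and maps the child's preliminary-context elements to
their columns using the provenance tags.  All final alignments end up with
the same length (the root context length a), which is what makes the rows a
genuine multiple sequence alignment.

Both traversals are iterative, so arbitrarily deep (caterpillar) trees do
not overflow the call stack.
"""

from __future__ import annotations

from typing import Sequence

from .alphabet import BOTH, GAPPED, GAPPED_ELEMENT, LEFT, RIGHT, TaggedElement
from .metric import TransitionMetric
from .pairwise import Context, align_tagged
from .tree import DecoratedTree, Node

__all__ = ["postorder_decorate", "sliding_zip", "preorder_finalize"]


def postorder_decorate(
    tree: DecoratedTree, metric: TransitionMetric
) -> DecoratedTree:
    """Assign preliminary contexts and costs, leaves to root.

    Each internal node receives the alignment of its children's contexts
    and the sum of both children's costs plus the local alignment cost.
    Leaves must already be decorated (see ``decorate_leaves``).
    """
    for node in tree.postorder():
        if node.is_leaf:
            if node.prelim is None or node.cost is None:
                raise ValueError(
                    f"leaf {node.name!r} is not decorated with a sequence"
                )
            continue
        l, r = node.left, node.right
        assert l is not None and r is not None
        local_cost, alignment = align_tagged(l.prelim, r.prelim, metric)
        node.prelim = alignment
        node.cost = l.cost + r.cost + local_cost
    return tree


def sliding_zip(
    parent_final: Sequence[TaggedElement],
    parent_prelim: Sequence[TaggedElement],
    child_prelim: Sequence[TaggedElement],
    child_side: str,
) -> Context:
    """Derive a child's final alignment from its parent's decorations.

    One element of the parent's final alignment is consumed and one element
    of the child's final alignment is emitted per step; the cursors into the
    two preliminary contexts slide forward as dictated by the case logic:

    * Case 0 — parent-final element is GAPPED: the gap was introduced
      elsewhere in the tree; emit GAPPED, consume nothing else.
    * Case 1 — child context exhausted: only a gap can be emitted; the
      parent context element (non-gap, from the sister side) is consumed.
    * Case 2 — parent-final element is BOTH: the child was aligned with its
      sister here; consume one element of each context and emit the child's.
    * Case 3 — parent-final element is LEFT and the child is the left child:
      the element originated in this subtree; consume both, emit the
      child's element.
    * Case 4 — mirror of Case 3 for RIGHT/right.
    * Case 5 — otherwise (an element that originated in the sister
      subtree): consume the parent context element and emit GAPPED.

    ``child_side`` is ``"left"`` or ``"right"``.
    """
    if child_side not in ("left", "right"):
        raise ValueError(f"child_side must be 'left' or 'right': {child_side!r}")
    if not (len(parent_final) >= len(parent_prelim) >= len(child_prelim)):
        raise ValueError(
            "length precondition violated: |parent final| >= "
            "|parent prelim| >= |child prelim| required, got "
            f"{len(parent_final)}, {len(parent_prelim)}, {len(child_prelim)}"
        )
    own_tag = LEFT if child_side == "left" else RIGHT
    np_len = len(parent_prelim)
    nc_len = len(child_prelim)
    out: Context = []
    append = out.append
    j = 0  # cursor into parent_prelim
    l = 0  # cursor into child_prelim
    for e in parent_final:
        tag = e.tag
        if tag == GAPPED:  # Case 0
            append(GAPPED_ELEMENT)
            continue
        if j >= np_len:
            raise ValueError(
                "parent preliminary context exhausted before its final "
                "alignment; the decorations are inconsistent"
            )
        if l >= nc_len:  # Case 1
            j += 1
            append(GAPPED_ELEMENT)
        elif tag == BOTH:  # Case 2
            j += 1
            append(child_prelim[l])
            l += 1
        elif tag == own_tag and parent_prelim[j] == e:  # Cases 3 and 4
            j += 1
            append(child_prelim[l])
            l += 1
        else:  # Case 5
            j += 1
            append(GAPPED_ELEMENT)
    if j != np_len or l != nc_len:
        raise ValueError(
            "sliding zip did not consume its inputs exactly "
            f"(parent context {j}/{np_len}, child context {l}/{nc_len}); "
            "the decorations are inconsistent"
        )
    return out


def preorder_finalize(tree: DecoratedTree) -> DecoratedTree:
    """Assign final alignments, root to leaves.

    The root's final alignment is its preliminary context; every other node
    is zipped against its parent.  On return all nodes carry final
    alignments of one common length.
    """
    root = tree.root
    if root.prelim is None:
        raise ValueError("post-order decorations missing; run "
                         "postorder_decorate first")
    for node in tree.preorder():
        if node is root:
            node.final = list(node.prelim)
            continue
        parent = node.parent
        assert parent is not None and parent.final is not None
        side = "left" if parent.left is node else "right"
        node.final = sliding_zip(
            parent.final, parent.prelim, node.prelim, side
        )
    return tree
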