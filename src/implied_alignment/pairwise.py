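"""Commutative tagged pairwise alignment.

This is the binary alignment function applied at every internal node of the
guide tree.  It is a Needleman–Wunsch alignment over tagged-element strings
with one twist: the traceback records, for every output element, whether it
consumed an element of the first argument only (``LEFT``), the second only
(``RIGHT``), or one of each (``BOTH``).  Those provenance tags are what later
lets the pre-order pass derive final alignments by a linear zip instead of
re-aligning.

Commutativity is enforced by a deterministic operand assignment: the longer
string goes to the matrix columns (the lexically smaller one on equal
length), and if that puts the first argument on the columns the tags of the
result are swapped back, so ``LEFT`` always means "originated from the first
argument".
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .alphabet import (
    BOTH,
    GAPPED,
    LEFT,
    RIGHT,
    TaggedElement,
)
from .metric import TransitionMetric, effective_set

__all__ = [
    "AlignmentResult",
    "Context",
    "align_tagged",
    "alignment_oracle",
    "canonicalize_pair",
    "effective_masks",
]

Context = list[TaggedElement]

#: Combined-length ceiling for the exhaustive oracle.
_ORACLE_LIMIT = 16

# Matrices beyond this many cells are stored as int32 to halve memory.
_INT32_CELLS = 4_000_000


class AlignmentResult(NamedTuple):
    cost: int | float
    alignment: Context


def effective_masks(
    context: Sequence[TaggedElement], metric: TransitionMetric
) -> list[int]:
    """Effective symbol-subset bitmask of every element of a context."""
    return [effective_set(e, metric) for e in context]


def _check_no_gapped(context: Sequence[TaggedElement], name: str) -> None:
    if any(e.tag == GAPPED for e in context):
        raise ValueError(
            f"{name} operand contains a GAPPED element; GAPPED elements "
            "only arise in final alignments, never in alignment inputs"
        )


def canonicalize_pair(
    s1: Sequence[TaggedElement],
    s2: Sequence[TaggedElement],
    metric: TransitionMetric,
) -> tuple[Context, Context, bool, bool]:
    """Deterministically assign operands to matrix rows and columns.

    Returns ``(row_string, col_string, swapped, trivial)``.  The longer
    operand goes to the columns; on equal length the lexically first operand
    (elementwise comparison of effective-set bitmasks) goes to the columns.
    ``swapped`` is True iff ``s1`` was *not* assigned to the rows, in which
    case the caller must exchange LEFT/RIGHT tags of the traceback result.
    ``trivial`` flags operands with identical effective-set sequences, whose
    alignment is all-diagonal at zero cost.
    """
    if len(s1) > len(s2):
        return list(s2), list(s1), True, False
    if len(s2) > len(s1):
        return list(s1), list(s2), False, False
    e1 = effective_masks(s1, metric)
    e2 = effective_masks(s2, metric)
    if e1 == e2:
        # orientation is immaterial: the all-diagonal result is symmetric
        return list(s1), list(s2), False, True
    if e1 < e2:
        return list(s2), list(s1), True, False
    return list(s1), list(s2), False, False


def align_tagged(
    s1: Sequence[TaggedElement],
    s2: Sequence[TaggedElement],
    metric: TransitionMetric,
) -> AlignmentResult:
    """Align two tagged strings, tagging each output element's provenance.

    The cost is the minimum over all monotone alignments of the summed
    subset costs (diagonal steps pay σ between the two effective sets,
    indel steps pay σ against the gap).  Ties in the traceback are broken
    diagonal > leftward > upward, so results are deterministic.
    """
    _check_no_gapped(s1, "first")
    _check_no_gapped(s2, "second")
    row, col, swapped, trivial = canonicalize_pair(s1, s2, metric)
    if trivial:
        eff = effective_masks(row, metric)
        zero = 0 if metric.is_integral else 0.0
        return AlignmentResult(
            zero, [TaggedElement(BOTH, m, m) for m in eff]
        )

    row_eff = np.array(effective_masks(row, metric), dtype=np.intp)
    col_eff = np.array(effective_masks(col, metric), dtype=np.intp)
    table = metric._subset_cost
    gap = metric.alphabet.gap_mask
    nrow, ncol = len(row_eff), len(col_eff)

    del_costs = table[row_eff, gap] if nrow else np.array([])
    ins_costs = table[col_eff, gap] if ncol else np.array([])

    cells = (nrow + 1) * (ncol + 1)
    if metric.is_integral:
        dtype = np.int32 if cells > _INT32_CELLS else np.int64
    else:
        dtype = np.float64
    dp = np.empty((nrow + 1, ncol + 1), dtype=dtype)
    prefix = np.zeros(ncol + 1, dtype=dtype)
    if ncol:
        np.cumsum(ins_costs, out=prefix[1:])
    dp[0] = prefix
    # Row recurrence: candidate cost from above/diagonal, then the in-row
    # leftward dependency resolved as a running minimum over cumulative
    # insertion costs (exact in integer arithmetic).
    cand = np.empty(ncol + 1, dtype=dtype)
    for i in range(1, nrow + 1):
        prev = dp[i - 1]
        d = del_costs[i - 1]
        cand[0] = prev[0] + d
        if ncol:
            sub = table[row_eff[i - 1], col_eff]
            np.minimum(prev[:-1] + sub, prev[1:] + d, out=cand[1:])
        dp[i] = prefix + np.minimum.accumulate(cand - prefix)

    cost = dp[nrow, ncol]
    cost = int(cost) if metric.is_integral else float(cost)

    tol = metric.tol
    out: Context = []
    i, j = nrow, ncol
    while i > 0 or j > 0:
        here = dp[i, j]
        if (
            i > 0
            and j > 0
            and abs(
                here
                - (dp[i - 1, j - 1] + table[row_eff[i - 1], col_eff[j - 1]])
            )
            <= tol
        ):
            out.append(
                TaggedElement(
                    BOTH, int(row_eff[i - 1]), int(col_eff[j - 1])
                )
            )
            i -= 1
            j -= 1
        elif j > 0 and abs(here - (dp[i, j - 1] + ins_costs[j - 1])) <= tol:
            out.append(TaggedElement(RIGHT, int(col_eff[j - 1])))
            j -= 1
        else:
            out.append(TaggedElement(LEFT, int(row_eff[i - 1])))
            i -= 1
    out.reverse()

    if swapped:
        out = [_swap_sides(e) for e in out]
    return AlignmentResult(cost, out)


def _swap_sides(e: TaggedElement) -> TaggedElement:
    """Exchange LEFT/RIGHT tags and reverse BOTH payload order."""
    tag = e.tag
    if tag == BOTH:
        return TaggedElement(BOTH, e.second, e.first)
    if tag == LEFT:
        return TaggedElement(RIGHT, e.first)
    if tag == RIGHT:
        return TaggedElement(LEFT, e.first)
    return e


def alignment_oracle(
    s1: Sequence[TaggedElement],
    s2: Sequence[TaggedElement],
    metric: TransitionMetric,
) -> int | float:
    """Exact minimum alignment cost by exhaustive path enumeration.

    Recursively explores every monotone alignment path without memoization;
    usable only for tiny inputs (combined length <= 16).  Serves as an
    independent reference for :func:`align_tagged`.
    """
    _check_no_gapped(s1, "first")
    _check_no_gapped(s2, "second")
    if len(s1) + len(s2) > _ORACLE_LIMIT:
        raise ValueError(
            f"inputs too long for exhaustive enumeration "
            f"(combined length {len(s1) + len(s2)} > {_ORACLE_LIMIT})"
        )
    a = effective_masks(s1, metric)
    b = effective_masks(s2, metric)
    gap = metric.alphabet.gap_mask
    cost = metric.subset_cost
    la, lb = len(a), len(b)

    def go(i: int, j: int):
        if i == la and j == lb:
            return 0
        best = None
        if i < la and j < lb:
            best = cost(a[i], b[j]) + go(i + 1, j + 1)
        if i < la:
            c = cost(a[i], gap) + go(i + 1, j)
            best = c if best is None else min(best, c)
        if j < lb:
            c = cost(b[j], gap) + go(i, j + 1)
            best = c if best is None else min(best, c)
        return best

    return go(0, 0)
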