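"""Transition cost matrices and their expansion to symbol subsets.

A transition metric σ gives the pairwise cost between single symbols of the
alphabet (gap included, so indel costs live in the gap row/column).  The
aligner needs σ on *nonempty subsets* of symbols: the cost of matching two
subsets is the cheapest pairwise cost between their members, and the median
of two subsets is the set of intermediate symbols minimizing the summed
distance to both sides (Sankoff-style).  Both expansions are precomputed as
dense tables over subset bitmasks, which keeps the dynamic-programming inner
loops to plain table lookups.

Only symmetry and nonnegativity are required of σ; a triangle-inequality
violation is reported as a warning, not an error.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np

from .alphabet import (
    BOTH,
    GAPPED,
    LEFT,
    RIGHT,
    Alphabet,
    TaggedElement,
)

__all__ = [
    "TransitionMetric",
    "TcmFormatError",
    "load_tcm",
    "read_tcm",
    "subset_cost_median",
    "effective_set",
    "sigma0",
    "sigma1",
    "sigma3",
]

#: Equality tolerance used for fractional cost matrices.
FLOAT_TOL = 1e-9


class TcmFormatError(ValueError):
    """A transition-cost-matrix file violates the format or σ's axioms."""


class TransitionMetric:
    """Symmetric nonnegative cost matrix σ over an alphabet (gap included).

    Parameters
    ----------
    alphabet
        The ordered alphabet; the matrix rows/columns follow its order.
    costs
        Square array of costs.  Integer matrices are kept in exact integer
        arithmetic; fractional ones in floating point with equality
        tolerance :data:`FLOAT_TOL`.
    """

    def __init__(self, alphabet: Alphabet, costs: np.ndarray) -> None:
        costs = np.asarray(costs)
        n = len(alphabet)
        if costs.shape != (n, n):
            raise TcmFormatError(
                f"cost matrix shape {costs.shape} does not match "
                f"alphabet size {n} (matrix must be square over the alphabet)"
            )
        if np.issubdtype(costs.dtype, np.integer) or np.all(
            costs == np.floor(costs)
        ):
            costs = costs.astype(np.int64)
            self.is_integral = True
            self.tol = 0
        else:
            costs = costs.astype(np.float64)
            self.is_integral = False
            self.tol = FLOAT_TOL
        if np.any(costs < 0):
            raise TcmFormatError("cost matrix has a negative entry")
        if np.any(np.abs(np.diagonal(costs)) > self.tol):
            raise TcmFormatError("cost matrix diagonal must be zero")
        if np.any(np.abs(costs - costs.T) > self.tol):
            raise TcmFormatError("cost matrix must be symmetric")
        self.alphabet = alphabet
        self.costs = costs
        self._check_triangle()
        self._build_subset_tables()

    def _check_triangle(self) -> None:
        c = self.costs
        # sigma(a,b) <= sigma(a,z) + sigma(z,b) for all intermediates z
        through = (c[:, :, None] + c[None, :, :]).min(axis=1)
        if np.any(c > through + self.tol):
            warnings.warn(
                "transition matrix violates the triangle inequality; "
                "the aligner only requires symmetry and nonnegativity",
                stacklevel=3,
            )

    def _build_subset_tables(self) -> None:
        n = len(self.alphabet)
        if n > 12:
            raise TcmFormatError(
                f"alphabet of size {n} too large for dense subset tables"
            )
        full = (1 << n) - 1
        # min_to[mask, z] = min over members a of mask of sigma(a, z)
        min_to = np.empty((full + 1, n), dtype=self.costs.dtype)
        min_to[0] = self.costs.max() if full else 0  # row 0 never used
        for mask in range(1, full + 1):
            low = mask & -mask
            rest = mask ^ low
            row = self.costs[low.bit_length() - 1]
            min_to[mask] = row if rest == 0 else np.minimum(min_to[rest], row)
        # subset cost: cheapest pairwise transition between the two sets
        cost = np.empty((full + 1, full + 1), dtype=self.costs.dtype)
        for x in range(1, full + 1):
            zs = [z for z in range(n) if x >> z & 1]
            cost[x, 1:] = min_to[1:, zs].min(axis=1)
        # median: symbols minimizing summed distance through an intermediate
        bits = 1 << np.arange(n, dtype=np.int64)
        median = np.zeros((full + 1, full + 1), dtype=np.int64)
        for x in range(1, full + 1):
            score = min_to[x][None, :] + min_to[1:]
            best = score.min(axis=1)
            sel = score <= best[:, None] + self.tol
            median[x, 1:] = sel @ bits
        self._subset_cost = cost
        self._subset_median = median

    # -- queries ---------------------------------------------------------

    def symbol_cost(self, a: str, b: str):
        """Raw matrix entry σ(a, b) for single symbols."""
        i, j = self.alphabet.index(a), self.alphabet.index(b)
        c = self.costs[i, j]
        return int(c) if self.is_integral else float(c)

    def subset_cost(self, x: int, y: int):
        self._validate_masks(x, y)
        c = self._subset_cost[x, y]
        return int(c) if self.is_integral else float(c)

    def subset_median(self, x: int, y: int) -> int:
        self._validate_masks(x, y)
        return int(self._subset_median[x, y])

    def _validate_masks(self, x: int, y: int) -> None:
        full = self.alphabet.full_mask
        if not (0 < x <= full and 0 < y <= full):
            raise ValueError(
                f"symbol-set masks must be nonempty subsets of the alphabet; "
                f"got {x!r}, {y!r}"
            )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TransitionMetric(alphabet={''.join(self.alphabet.symbols)!r}, "
            f"integral={self.is_integral})"
        )


def subset_cost_median(
    x: int, y: int, metric: TransitionMetric
) -> tuple[int | float, int]:
    """Cheapest transition cost and Sankoff median of two symbol subsets.

    The cost is ``min over (a in x, b in y) of sigma(a, b)``; the median is
    the set of all symbols z minimizing ``min_{a in x} sigma(a, z) +
    min_{b in y} sigma(z, b)``.  Commutative by construction.
    """
    return metric.subset_cost(x, y), metric.subset_median(x, y)


def effective_set(
    e: TaggedElement, metric: TransitionMetric, *, exclude_gap: bool = True
) -> int:
    """Project a tagged element to the symbol subset it contributes.

    ``BOTH`` elements contribute the median of their two sides; ``LEFT`` and
    ``RIGHT`` elements contribute their single payload with the gap symbol
    removed (an indel-derived element must not align at zero cost against
    another indel; pass ``exclude_gap=False`` for the gap-inclusive
    direct-optimization-median variant); ``GAPPED`` contributes the gap.
    """
    tag = e.tag
    if tag == BOTH:
        m = metric.subset_median(e.first, e.second)
    elif tag == LEFT or tag == RIGHT:
        m = e.first
    else:  # GAPPED
        return metric.alphabet.gap_mask
    if exclude_gap:
        stripped = m & ~metric.alphabet.gap_mask
        if stripped:
            return stripped
    return m


# -- TCM file format -----------------------------------------------------


def load_tcm(text: str) -> TransitionMetric:
    """Parse transition-cost-matrix file content.

    Line 1 is a whitespace-separated symbol list whose *last* entry is the
    gap character; the remaining lines form a square matrix of nonnegative
    numbers in the same symbol order.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TcmFormatError("empty TCM file")
    symbols = lines[0].split()
    if len(symbols) < 3:
        raise TcmFormatError(
            f"TCM alphabet needs at least 3 symbols including the gap, "
            f"got {len(symbols)}"
        )
    if len(set(symbols)) != len(symbols):
        raise TcmFormatError("TCM symbol line contains duplicate symbols")
    rows = []
    for ln in lines[1:]:
        try:
            rows.append([float(tok) for tok in ln.split()])
        except ValueError as exc:
            raise TcmFormatError(f"non-numeric matrix entry: {exc}") from None
    n = len(symbols)
    if len(rows) != n or any(len(r) != n for r in rows):
        raise TcmFormatError(
            f"TCM matrix must be {n}x{n} to match the symbol line"
        )
    alphabet = Alphabet(tuple(symbols), gap=symbols[-1])
    return TransitionMetric(alphabet, np.array(rows))


def read_tcm(path) -> TransitionMetric:
    """Load a transition metric from a TCM file on disk."""
    with open(path, encoding="utf-8") as fh:
        return load_tcm(fh.read())


def _builtin(name: str) -> TransitionMetric:
    text = (
        resources.files("implied_alignment")
        .joinpath(f"data/{name}.tcm")
        .read_text(encoding="utf-8")
    )
    return load_tcm(text)


def sigma0() -> TransitionMetric:
    """Substitution-preferring nucleotide metric: mismatch 1, indel 2."""
    return _builtin("sigma0")


def sigma1() -> TransitionMetric:
    """Indel-preferring nucleotide metric: mismatch 3, indel 1."""
    return _builtin("sigma1")


def sigma3() -> TransitionMetric:
    """Discrete nucleotide metric: every change, indels included, costs 1."""
    return _builtin("sigma3")
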