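"""Pathological datasets and empirical complexity measurement.

The generator builds balanced binary trees from quartets whose four leaves
are the homopolymers A^k, C^k, G^k, T^k.  Under a substitution-preferring
metric (mismatch 1, indel 2) every pairwise alignment is all-substitution,
the alignment never grows beyond k columns and the pre-order pass does the
minimum possible work (m = a/k = 1).  Under an indel-preferring metric
(mismatch 3, indel 1) the homopolymers refuse to align and the alignment
approaches the concatenation of the inputs (m = n on a quartet), driving
the pre-order toward its quadratic worst case.

With a four-symbol alphabet, strings on different quartets cannot be kept
entirely unalignable: identical arrangements would make sibling subtree
contexts equal, collapsing every join to a zero-cost aligned column block.
Degenerate mode therefore varies the homopolymer arrangement per quartet by
a fixed deterministic schedule chosen to keep sibling contexts maximally
misaligned, so the alignment length keeps growing with the leaf count.

The scaling harness times the pre-order phase alone (the post-order pass is
the well-understood pairwise-alignment workload) and fits ordinary least
squares on binary logs: log2(runtime) = b0 + b1*log2(n) + b2*log2(k).  An
exponent near 1 indicates linear scaling in that dimension, near 2
quadratic.
"""

from __future__ import annotations

import time
import warnings
from io import StringIO
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm
from Bio import SeqIO

from .io import parse_fasta, write_fasta
from .metric import TransitionMetric, sigma0, sigma1
from .tree import DecoratedTree, Node, decorate_leaves, parse_newick
from .traversal import postorder_decorate, preorder_finalize

__all__ = [
    "ScalingRecord",
    "LogLogFit",
    "generate_pathological",
    "degrade_dataset",
    "run_scaling_study",
    "fit_loglog",
    "compute_m",
]


class ScalingRecord(NamedTuple):
    n: int
    k: int
    runtime_ms: float


class LogLogFit(NamedTuple):
    beta0: float
    beta1: float  # exponent of the leaf count n
    beta2: float  # exponent of the string length k
    adj_r2: float


#: Homopolymer arrangement per quartet in degenerate mode.  Because the
#: tagged alignment is commutative, a quartet's context depends only on how
#: its four homopolymers are *paired*, and {A,C,G,T} admits exactly three
#: pairings; the schedule cycles through all three.  On a power-of-two
#: quartet count a period-3 type sequence guarantees that the two subtrees
#: under any join never carry identical type sequences (3 does not divide
#: 2^j), so no join collapses to a fully aligned zero-cost block.
_DEGENERATE_ARRANGEMENTS: tuple[tuple[str, str, str, str], ...] = (
    ("A", "C", "G", "T"),
    ("A", "G", "C", "T"),
    ("A", "T", "C", "G"),
)

_PERFECT_ARRANGEMENT = ("A", "C", "G", "T")


def _quartet_arrangement(index: int, mode: str) -> tuple[str, str, str, str]:
    if mode == "perfect":
        return _PERFECT_ARRANGEMENT
    return _DEGENERATE_ARRANGEMENTS[index % len(_DEGENERATE_ARRANGEMENTS)]


def generate_pathological(
    k: int, n: int, mode: str, seed: int | None = None
) -> tuple[str, str, str]:
    """Build the pathological dataset: (newick text, fasta text, tcm name).

    ``n`` must be a power of two >= 4; the tree is a balanced join of n/4
    quartets, each quartet carrying the four length-``k`` homopolymers.
    ``mode`` selects the intended regime: ``"perfect"`` pairs with the
    substitution-preferring metric (returned as ``"sigma0"``) and
    ``"degenerate"`` with the indel-preferring one (``"sigma1"``).
    ``seed``, if given, shuffles leaf-name assignment (the structure is
    otherwise fully deterministic).
    """
    if mode not in ("perfect", "degenerate"):
        raise ValueError(f"mode must be 'perfect' or 'degenerate': {mode!r}")
    if k < 1:
        raise ValueError(f"string length k must be >= 1, got {k}")
    if n < 4 or n & (n - 1):
        raise ValueError(f"leaf count n must be a power of two >= 4, got {n}")

    labels = [f"t{i + 1}" for i in range(n)]
    if seed is not None:
        rng = np.random.default_rng(seed)
        labels = [labels[i] for i in rng.permutation(n)]

    n_quartets = n // 4
    records: list[tuple[str, str]] = []
    subtrees: list[str] = []
    for q in range(n_quartets):
        arr = _quartet_arrangement(q, mode)
        names = labels[4 * q : 4 * q + 4]
        for name, sym in zip(names, arr):
            records.append((name, sym * k))
        subtrees.append(
            f"(({names[0]},{names[1]}),({names[2]},{names[3]}))"
        )
    while len(subtrees) > 1:
        subtrees = [
            f"({subtrees[i]},{subtrees[i + 1]})"
            for i in range(0, len(subtrees), 2)
        ]
    newick = subtrees[0] + ";"
    fasta = write_fasta(records)
    tcm = "sigma0" if mode == "perfect" else "sigma1"
    return newick, fasta, tcm


# -- dataset degradation (halving / central truncation) ------------------


def _prune_to(node: Node, keep: set[str]) -> Node | None:
    """Restrict a subtree to leaves in ``keep``, suppressing unary nodes."""
    if node.is_leaf:
        return Node(node.name) if node.name in keep else None
    left = _prune_to(node.left, keep)
    right = _prune_to(node.right, keep)
    if left is None:
        return right
    if right is None:
        return left
    out = Node()
    out.left, out.right = left, right
    left.parent = right.parent = out
    return out


def degrade_dataset(
    aligned_fasta: str,
    newick: str,
    halvings: int,
    gap: str = "-",
) -> list[tuple[str, str]]:
    """Produce progressively halved instances of an aligned dataset.

    Each halving keeps every other leaf (in tree order, pruning the tree
    and suppressing degree-2 nodes) and truncates the alignment to the
    central slice of half the current length, then strips all gaps from
    the slice.  Returns one (newick text, fasta text) instance per level,
    largest first — nested inputs of doubling size for scaling runs.
    """
    rows = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(StringIO(aligned_fasta), "fasta")
    }
    if not rows:
        raise ValueError("empty aligned FASTA")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must all have equal length")
    tree = parse_newick(newick)
    tree_names = [leaf.name for leaf in tree.leaves]
    if set(tree_names) != set(rows):
        raise ValueError("tree leaf names do not match alignment rows")

    instances: list[tuple[str, str]] = []
    kept = tree_names
    length = lengths.pop()
    for _ in range(halvings):
        kept = kept[::2]
        length = length // 2
        if len(kept) < 2 or length < 1:
            raise ValueError(
                "halving exhausted the dataset (fewer than 2 leaves or "
                "empty slice)"
            )
        root = _prune_to(tree.root, set(kept))
        if root is None or root.is_leaf:
            raise ValueError("pruning removed the whole tree")
        sub = DecoratedTree(root)
        start = (len(next(iter(rows.values()))) - length) // 2
        out_rows = []
        for name in kept:
            sliced = rows[name][start : start + length].replace(gap, "")
            if not sliced:
                warnings.warn(
                    f"leaf {name!r} became an empty string after "
                    "truncation and degapping",
                    stacklevel=2,
                )
            out_rows.append((name, sliced))
        instances.append((sub.to_newick(), write_fasta(out_rows)))
    return instances


# -- timing harness and scaling fit --------------------------------------

_METRICS = {"perfect": sigma0, "degenerate": sigma1}


def _prepare(k: int, n: int, mode: str) -> tuple[DecoratedTree, TransitionMetric]:
    newick, fasta, _ = generate_pathological(k, n, mode)
    metric = _METRICS[mode]()
    tree = parse_newick(newick)
    decorate_leaves(tree, parse_fasta(fasta, metric.alphabet), metric.alphabet)
    postorder_decorate(tree, metric)
    return tree, metric


def run_scaling_study(
    grid: Iterable[tuple[int, int]],
    mode: str,
    repeats: int = 3,
    seed: int | None = None,
) -> list[ScalingRecord]:
    """Time the pre-order phase on generated datasets over a (k, n) grid.

    For every grid point the dataset is generated and the post-order pass
    run once (untimed); the pre-order pass is then timed as the median of
    ``repeats`` runs on a monotonic clock, after one discarded warm-up run.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    records = []
    for k, n in grid:
        tree, _ = _prepare(k, n, mode)
        preorder_finalize(tree)  # warm-up, discarded
        samples = []
        for _ in range(repeats):
            t0 = time.perf_counter_ns()
            preorder_finalize(tree)
            samples.append(time.perf_counter_ns() - t0)
        runtime_ms = float(np.median(samples)) / 1e6
        records.append(ScalingRecord(n=n, k=k, runtime_ms=runtime_ms))
    return records


def fit_loglog(records: Sequence[ScalingRecord]) -> LogLogFit:
    """Ordinary least squares on binary logs of runtime, n and k.

    Solves log2(runtime) = b0 + b1*log2(n) + b2*log2(k) + error.  Requires
    at least three observations spanning at least two distinct n and two
    distinct k; exact (adjusted R-squared 1) on noiseless power-law data.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to fit three coefficients")
    ns = {r.n for r in records}
    ks = {r.k for r in records}
    if len(ns) < 2 or len(ks) < 2:
        raise ValueError(
            "rank-deficient design: records must span at least two distinct "
            "n and two distinct k"
        )
    if any(r.runtime_ms <= 0 for r in records):
        raise ValueError("runtimes must be positive")
    y = np.log2([r.runtime_ms for r in records])
    x = sm.add_constant(
        np.column_stack(
            [np.log2([r.n for r in records]), np.log2([r.k for r in records])]
        )
    )
    fit = sm.OLS(y, x).fit()
    if fit.df_resid > 0:
        adj = float(fit.rsquared_adj)
    else:
        # exactly determined system: a perfect fit by construction
        adj = 1.0 if float(np.abs(fit.resid).max()) < 1e-9 else float("nan")
    b0, b1, b2 = (float(v) for v in fit.params)
    return LogLogFit(beta0=b0, beta1=b1, beta2=b2, adj_r2=adj)


def compute_m(tree: DecoratedTree) -> float:
    """Alignment-length ratio m = a / k after the post-order pass.

    ``a`` is the root preliminary-context length and ``k`` the longest leaf
    input length; 1 <= m <= n for nonempty inputs.
    """
    if tree.root.prelim is None:
        raise ValueError("post-order decorations missing")
    if not tree.leaves:
        raise ValueError("tree has no leaves")
    k = max(len(leaf.sequence or ()) for leaf in tree.leaves)
    if k == 0:
        raise ValueError("all leaf sequences are empty; m is undefined")
    return len(tree.root.prelim) / k
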