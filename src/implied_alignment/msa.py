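"""Rendering final alignments as a multiple sequence alignment.

Once the pre-order pass has decorated every node with an equal-length final
alignment, each leaf row renders one character per column: GAPPED elements
become the gap character and residue elements render their symbol set
(singletons as the symbol itself, ambiguous sets as an IUPAC code on
nucleotide alphabets or as ``[AG]``-style set notation otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .alphabet import GAPPED, TaggedElement
from .io import iupac_code_for, parse_fasta, write_fasta
from .metric import TransitionMetric, effective_set, load_tcm
from .tree import DecoratedTree, decorate_leaves, parse_newick
from .traversal import postorder_decorate, preorder_finalize

__all__ = [
    "RenderPolicy",
    "render_element",
    "render_leaf_msa",
    "render_internal_msa",
    "run_pipeline",
    "verify_alignment",
    "PipelineResult",
]


@dataclass(frozen=True)
class RenderPolicy:
    """How to spell ambiguous residue sets and whether to emit inner nodes.

    ``ambiguity`` is ``"iupac"`` (nucleotide ambiguity letters) or ``"sets"``
    (``[AG]`` notation).  GAPPED always renders as the gap character.
    """

    ambiguity: str = "iupac"
    internal_nodes: bool = False

    def __post_init__(self) -> None:
        if self.ambiguity not in ("iupac", "sets"):
            raise ValueError(f"unknown ambiguity policy {self.ambiguity!r}")


def default_policy(metric: TransitionMetric) -> RenderPolicy:
    """IUPAC rendering for 4-letter nucleotide alphabets, sets otherwise."""
    residues = set(metric.alphabet.symbols) - {metric.alphabet.gap}
    iupac = residues == {"A", "C", "G", "T"}
    return RenderPolicy(ambiguity="iupac" if iupac else "sets")


def render_element(
    e: TaggedElement, metric: TransitionMetric, policy: RenderPolicy
) -> str:
    if e.tag == GAPPED:
        return metric.alphabet.gap
    symbols = metric.alphabet.unmask(effective_set(e, metric))
    if len(symbols) == 1:
        return symbols[0]
    if policy.ambiguity == "iupac":
        code = iupac_code_for(frozenset(symbols))
        if code is not None:
            return code
    return "[" + "".join(symbols) + "]"


def render_leaf_msa(
    tree: DecoratedTree,
    metric: TransitionMetric,
    policy: RenderPolicy | None = None,
    order: list[str] | None = None,
) -> list[tuple[str, str]]:
    """Render one aligned row per leaf, all of the common length.

    ``order`` fixes the row order (e.g. input FASTA order); by default rows
    follow the tree's left-to-right leaf order.
    """
    if policy is None:
        policy = default_policy(metric)
    rows: dict[str, str] = {}
    for leaf in tree.leaves:
        if leaf.final is None:
            raise ValueError(
                f"leaf {leaf.name!r} has no final alignment; run "
                "preorder_finalize first"
            )
        rows[leaf.name] = "".join(
            render_element(e, metric, policy) for e in leaf.final
        )
    names = order if order is not None else [l.name for l in tree.leaves]
    return [(name, rows[name]) for name in names]


def render_internal_msa(
    tree: DecoratedTree,
    metric: TransitionMetric,
    policy: RenderPolicy | None = None,
) -> list[tuple[str, str]]:
    """Render internal-node rows (root first, then pre-order)."""
    if policy is None:
        policy = default_policy(metric)
    rows = []
    for i, node in enumerate(tree.preorder()):
        if node.is_leaf:
            continue
        name = "root" if node is tree.root else f"node{i}"
        rows.append(
            (
                name,
                "".join(
                    render_element(e, metric, policy) for e in node.final
                ),
            )
        )
    return rows


class PipelineResult(NamedTuple):
    msa_fasta: str
    tree_cost: int | float
    m: float
    alignment_length: int
    rows: list[tuple[str, str]]
    tree: DecoratedTree
    metric: TransitionMetric


def run_pipeline(
    fasta_text: str,
    newick_text: str,
    tcm: str | TransitionMetric,
    *,
    degap: bool = False,
    keep_gap_symbol: bool = False,
    policy: RenderPolicy | None = None,
) -> PipelineResult:
    """Parse inputs, run both traversals and render the leaf MSA.

    Returns the aligned FASTA (rows in input FASTA order), the tree cost,
    and the length ratio m = a / k where a is the alignment length and k the
    longest input sequence length.  Deterministic for fixed inputs.
    """
    metric = tcm if isinstance(tcm, TransitionMetric) else load_tcm(tcm)
    sequences = parse_fasta(
        fasta_text,
        metric.alphabet,
        degap=degap,
        keep_gap_symbol=keep_gap_symbol,
    )
    tree = parse_newick(newick_text)
    decorate_leaves(tree, sequences, metric.alphabet)
    postorder_decorate(tree, metric)
    preorder_finalize(tree)
    rows = render_leaf_msa(tree, metric, policy, order=list(sequences))
    a = len(tree.root.prelim)
    k = max((len(s) for s in sequences.values()), default=0)
    m = a / k if k else float("nan")
    return PipelineResult(
        msa_fasta=write_fasta(rows),
        tree_cost=tree.root.cost,
        m=m,
        alignment_length=a,
        rows=rows,
        tree=tree,
        metric=metric,
    )


def verify_alignment(result: PipelineResult) -> list[str]:
    """Check the structural invariants of a computed implied alignment.

    Returns a list of human-readable violations (empty when all hold):
    equal row lengths, per-row gap-stripping recovery of the inputs, no
    all-gap column, and conservation of the root cost as the sum of the
    local pairwise alignment costs.
    """
    from .pairwise import align_tagged  # local to avoid cycle at import

    tree, metric = result.tree, result.metric
    problems: list[str] = []
    a = result.alignment_length
    for node in tree.preorder():
        if node.final is not None and len(node.final) != a:
            problems.append(
                f"final alignment of {node!r} has length {len(node.final)}, "
                f"expected {a}"
            )
    for leaf in tree.leaves:
        recovered = [e for e in leaf.final if e.tag != GAPPED]
        if recovered != leaf.prelim:
            problems.append(
                f"degapping leaf {leaf.name!r} does not recover its input"
            )
    if a and tree.leaves:
        for col in range(a):
            if all(l.final[col].tag == GAPPED for l in tree.leaves):
                problems.append(f"column {col} is all-gap across leaf rows")
                break
    local_sum = 0
    for node in tree.postorder():
        if not node.is_leaf:
            cost, _ = align_tagged(node.left.prelim, node.right.prelim, metric)
            local_sum += cost
    if abs(local_sum - tree.root.cost) > metric.tol:
        problems.append(
            f"root cost {tree.root.cost} != sum of local alignment "
            f"costs {local_sum}"
        )
    return problems
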