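# Methods

## Model

The package computes the multiple sequence alignment implied by a rooted,
strictly binary guide tree under a commutative pairwise alignment function
⊗. Leaves carry strings over an alphabet Σ (|Σ| ≥ 3 including the gap
symbol); internal nodes are decorated in two passes.

**Post-order (leaves → root).** Each leaf's string is lifted into a
*preliminary context*: a string of tagged elements, one per residue set X,
stored as `BOTH(X, X)` with cost 0. The lift representation is a design
choice; it is the unique form whose effective set is X itself and carries
no spurious subtree asymmetry. Each internal node's context is the tagged
alignment of its children's contexts, and its cost is the children's costs
plus the local alignment cost. The root context summarizes the whole leaf
set; its length is the alignment length a, and the root cost is the tree
cost.

**Tagged pairwise alignment ⊗.** A Needleman–Wunsch alignment over tagged
strings. Every element projects to an *effective set* — a nonempty subset
of Σ:

* `BOTH(x, y)` → the Sankoff median: all symbols z minimizing
  min_{a∈x} σ(a,z) + min_{b∈y} σ(z,b). The gap participates as an
  ordinary intermediate, so under strongly indel-favoring matrices a
  median can contain (or be) the gap symbol.
* `LEFT(x)` / `RIGHT(x)` → x with the gap symbol removed (unless that
  would empty the set). Stripping the gap is deliberate: an
  indel-derived element that retained a gap state would align against
  another indel at zero cost, and the degenerate worst case (a = n·k on
  a quartet) could never arise. A gap-inclusive variant is available via
  `effective_set(..., exclude_gap=False)` but is not used by the
  pipeline.
* `GAPPED` → {gap} (only ever present in final alignments).

DP costs are the subset expansion of σ: a diagonal step pays the cheapest
pairwise transition between the two effective sets, an indel step pays the
transition to {gap}. The traceback tags diagonal steps `BOTH`, row-only
steps `LEFT`, column-only steps `RIGHT`.

**Commutativity.** The operands are assigned deterministically: the longer
string to the matrix columns; on equal length the lexically first string
(elementwise numeric comparison of effective-set bitmasks) to the columns;
if that places the first argument on the columns, tags are swapped after
traceback so `LEFT` always means "from the first argument". Strings with
identical effective-set sequences short-circuit to an all-`BOTH`,
zero-cost alignment. Because the DP sees only effective sets, the result
is invariant under retagging of the inputs, which is what makes the whole
implied alignment invariant to transposing children (verified on random
trees). ⊗ is *not* associative: different bracketings (trees) may give
different MSAs, which is precisely why the alignment is "implied by" the
tree.

**Pre-order (root → leaves), the sliding zip.** The root's final alignment
is its own context. Every other node's final alignment is derived from its
parent in one linear scan: for each parent-final element, exactly one
child-final element is emitted —

| case | condition | action |
|---|---|---|
| 0 | parent-final element `GAPPED` | emit `GAPPED` |
| 1 | child context exhausted | consume parent-context element, emit `GAPPED` |
| 2 | parent-final element `BOTH` | consume one element of each context, emit the child's |
| 3 | element `LEFT` and child is the left child | consume both, emit the child's |
| 4 | element `RIGHT` and child is the right child | consume both, emit the child's |
| 5 | otherwise (element from the sister subtree) | consume parent-context element, emit `GAPPED` |

Cases are tested in this order; the first match wins. Case 1's consumption
rule (one parent-context element per non-gap parent-final element) is not
forced by the case description itself but is the unique choice that leaves
both cursors exactly exhausted at the end, which the implementation
asserts. Case 0 consumes no context element: preliminary contexts never
contain `GAPPED`. All final alignments have length a; deleting `GAPPED`
elements from a leaf's final alignment recovers its input exactly.

**Complexity.** Post-order: one O(|l|·|r|) matrix per internal node (the
full-matrix engine; no banding). Pre-order: Θ(a) per node, Θ(a·n) total —
Ω(k·n) when m = a/k = 1 and O(k·n²) when m ≈ n.

## Parameters

* **σ (TCM file)** — symmetric, nonnegative, zero diagonal; indel cost is
  the gap row. Shipped matrices: σ0 (mismatch 1, indel 2,
  substitution-preferring), σ1 (mismatch 3, indel 1, indel-preferring),
  σ3 (all changes cost 1). A triangle-inequality violation (σ1 has one:
  A→C direct 3, via gap 2) is a warning, not an error — the algorithm
  needs only symmetry and nonnegativity. Integer matrices are processed
  in exact integer arithmetic; fractional ones in floating point with
  tolerance 1e-9.
* **Traceback tie-break** — diagonal > leftward > upward, fixed. Implied
  alignments are not unique among co-optimal tracebacks; the fixed order
  makes output deterministic and byte-stable across runs.
* **Rendering** — IUPAC codes for ambiguous sets on 4-letter nucleotide
  alphabets, `[AG]` set notation otherwise; `GAPPED` always renders as
  the gap character.

## Synthetic data

`generate_pathological(k, n, mode)` builds the two scaling regimes: a
balanced binary tree over n/4 quartets whose leaves are the homopolymers
A^k, C^k, G^k, T^k.

* **perfect** mode pairs with σ0: every pairwise alignment is
  all-substitution, a = k, m = 1 at every size — the best case.
* **degenerate** mode pairs with σ1: within a quartet nothing aligns and
  a = 4k (m = n = 4), the worst case.

Beyond one quartet the worst case is not sustainable with a four-symbol
alphabet: since ⊗ is commutative, a quartet's context depends only on how
its homopolymers are paired, and {A,C,G,T} admits exactly three pairings,
so identical arrangements would make sibling subtrees align wholesale at
zero cost (constant a). The generator therefore cycles the three pairings
with period 3, which provably keeps sibling type sequences distinct at
every join of a power-of-two quartet count and maximizes growth among the
deterministic schedules examined (identical, 2-cycle, 4-rotation,
square-free ternary, random ternary). Even so, growth saturates — any
4-block context eventually embeds in a long context as a subsequence — so
a is Θ(k) asymptotically (a/k ≈ 4, 5, 6, 8, 10, 11, 12 at
n = 4…256) and the measured pre-order n-exponent on the study grid is
≈ 1.3, between the linear best case and the quadratic worst case. The
quartet (n = 4) realizes the true worst case exactly.

The generator emulates adversarial structure, not biology: real data have
unequal lengths, partial similarity and ambiguity codes (covered by the
random-tree property tests instead), so passing scaling bands here says
nothing about absolute speed on real sequences, only about how work grows
with problem size.

## Scaling study

`run_scaling_study` times the *pre-order phase only* (the post-order is
the standard pairwise-alignment workload) on a monotonic clock: one
warm-up run discarded, then the median of `repeats` runs (default 3).
`fit_loglog` fits log2(runtime) = β0 + β1·log2(n) + β2·log2(k) by OLS
(statsmodels) and reports adjusted R²; with exactly three observations
the system is exactly determined and adjusted R² is reported as 1 for a
perfect fit. The default study grid is k ∈ {16…256}, n ∈ {4…64}
(geometric steps), sized so the full two-mode study runs in seconds.

## Degenerate inputs and edge cases

* Empty leaf sequences are accepted with a warning; the row renders as
  all gaps. m is undefined (error) only if *all* leaves are empty.
* Gap characters in input FASTA are an error unless `degap=True`
  (strip) or `keep_gap_symbol=True` (treat as a literal residue, for
  alphabets where "-" is an ordinary symbol).
* Polytomies, unnamed or duplicate leaves, and leaf/sequence set
  mismatches are hard errors with specific messages; branch lengths and
  internal labels are ignored.
* `degrade_dataset` reproduces the halving protocol for pre-aligned
  data: every other leaf is kept (tree pruned, degree-2 nodes
  suppressed), the alignment is cut to its central half and degapped;
  rows that become empty are flagged with a warning.

## Known limitations

* Affine or logarithmic gap costs are out of scope; σ is memoryless.
* The pairwise engine is the full Θ(|l|·|r|)-space matrix; Ukkonen-style
  banding and linear-space traceback are not implemented.
* The degenerate generator cannot force m = n beyond a single quartet
  (alphabet-limited, see above), so empirical worst-case exponents on
  large trees undershoot the theoretical O(k·n²) bound.
* Implied alignments are heuristic: neither optimal nor unique for the
  underlying tree-alignment problem; rebracketing the tree may change
  the MSA.
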