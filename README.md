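# implied-alignment

Multiple sequence alignment implied by a guide tree, via provenance-tagged
pairwise alignment and a linear-time "sliding zip" pre-order pass.

## The problem

Given unaligned sequences at the leaves of a rooted, strictly binary tree
𝒯 (n leaves, longest sequence length k) and a symmetric transition cost
matrix σ over the alphabet Σ ∪ {gap}, the *implied alignment* is the MSA
induced by applying a commutative pairwise alignment function ⊗ along the
tree: the bracketing of 𝒯 fixes the order of the non-associative alignment
operations, so the alignment is a property of the tree, not of the
sequences alone. This is the alignment notion used by direct-optimization
phylogenetics (POY-style tree search), and it doubles as a stand-alone,
tree-aware MSA method.

The classical way to extract that MSA back-propagates gaps and costs
O(k²·n²) time. This package instead tags every element produced by ⊗ with
two bits of provenance — `BOTH` (aligned across the two subtrees), `LEFT`
or `RIGHT` (originated in one subtree), `GAPPED` (introduced elsewhere in
the tree) — during a post-order pass, and then derives all final, equal-
length alignments in a pre-order pass by a single linear zip per node:
O(k·n²) worst case and Ω(k·n) when the sequences are similar, which is the
common case for molecular data.

Concretely, ⊗ is a Needleman–Wunsch alignment over strings of tagged
elements: each element projects to a nonempty symbol subset (ambiguity
sets are first-class; the median of a `BOTH` pair is the Sankoff set of
cost-minimizing intermediate symbols), the DP matrix is filled with
subset-expanded σ costs, and the traceback emits tags. A deterministic
operand assignment (longer string to the columns, lexically first on
ties) makes ⊗ commutative, which in turn makes the implied alignment
invariant to transposing the children of any node.

## Worked example

```python
from implied_alignment import run_pipeline, sigma0

fasta = ">a\nACGT\n>b\nACT\n>c\nAGGT\n>d\nACGT\n"
result = run_pipeline(fasta, "((a,b),(c,d));", sigma0())
print(result.msa_fasta, end="")
print("cost:", result.tree_cost, " m:", f"{result.m:.4f}")
```

prints

```
>a
ACGT
>b
AC-T
>c
AGGT
>d
ACGT
cost: 3  m: 1.0000
```

The cost (3) is the summed cost of the three pairwise alignments performed
along the tree under σ0 (mismatch 1, indel 2): one indel column for `b`
(cost 2 at the `(a,b)` cherry) and one G/C mismatch column (cost 1 at the
`(c,d)` cherry). `m = a/k` is the alignment length divided by the longest input
length; m = 1 means the alignment is as compact as possible, while
m = n is the fully degenerate staircase. The `examples/` scripts walk
through alignment, the two pathological regimes, and the scaling study.

The same pipeline is available from the shell:

```sh
implied-align align --sequences in.fasta --tree in.newick \
    --tcm sigma0.tcm --output out.fasta --verify
implied-align generate --k 64 --n 16 --mode degenerate --out-prefix path
implied-align bench --grid "k=16..256x2,n=4..64x2" --mode perfect --csv s.csv
implied-align fit --csv s.csv
```

TCM files are plain text: a symbol line ending with the gap character,
then the square cost matrix (`implied_alignment/data/*.tcm` ship the
substitution-preferring σ0, indel-preferring σ1 and discrete σ3 matrices).

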