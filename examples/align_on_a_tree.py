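"""Align four sequences along a guide tree and inspect the result.

The guide tree fixes the bracketing of the pairwise alignment operations;
the implied alignment is the MSA those operations induce.
"""

from implied_alignment import run_pipeline, sigma0, verify_alignment

fasta = """\
>a
ACGT
>b
ACT
>c
AGGT
>d
ACGT
"""
tree = "((a,b),(c,d));"

result = run_pipeline(fasta, tree, sigma0())

print(result.msa_fasta)
print(f"tree cost          : {result.tree_cost}")
print(f"alignment length a : {result.alignment_length}")
print(f"m = a / k          : {result.m:.4f}")
print(f"invariant problems : {verify_alignment(result) or 'none'}")

# The tree cost is the summed cost of every pairwise alignment performed
# along the tree (here with mismatch 1, indel 2); m close to 1 means the
# alignment stayed near the length of the longest input.
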