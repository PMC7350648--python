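"""The two extremes of implied-alignment behavior on homopolymer quartets.

A quartet of homopolymers A^k, C^k, G^k, T^k aligns column-for-column when
substitutions are cheaper than indels (m = a/k = 1, the best case) and
refuses to align entirely when indels are cheaper (a = 4k, m = n = 4, the
worst case).
"""

from implied_alignment import (
    generate_pathological,
    run_pipeline,
    sigma0,
    sigma1,
)

k = 8
for mode, metric in (("perfect", sigma0()), ("degenerate", sigma1())):
    newick, fasta, tcm_name = generate_pathological(k, 4, mode)
    result = run_pipeline(fasta, newick, metric)
    print(f"mode={mode} (metric {tcm_name}, k={k})")
    for name, row in result.rows:
        print(f"  {name}: {row}")
    print(f"  cost={result.tree_cost}  a={result.alignment_length}"
          f"  m={result.m:.4f}\n")

# Perfect mode prints a gap-free k-column alignment (m = 1); degenerate
# mode prints a 4k-column staircase with one homopolymer block per row
# (m = 4), the maximally gapped alignment a quartet admits.
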