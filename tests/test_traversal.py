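"""Post-order decoration, the sliding zip, and pre-order finalization."""

import random

import pytest

from implied_alignment import (
    BOTH,
    GAPPED,
    GAPPED_ELEMENT,
    LEFT,
    RIGHT,
    TaggedElement,
    align_tagged,
    alignment_oracle,
    decorate_leaves,
    parse_fasta,
    parse_newick,
    postorder_decorate,
    preorder_finalize,
    render_leaf_msa,
    run_pipeline,
    sliding_zip,
)

from .conftest import flip_random_children, lift_str, random_instance


def build(newick, fasta, metric):
    tree = parse_newick(newick)
    decorate_leaves(tree, parse_fasta(fasta, metric.alphabet), metric.alphabet)
    return postorder_decorate(tree, metric)


class TestPostorder:
    def test_identical_leaves_cost_nothing(self, s0):
        tree = build("((a,b),(c,d));", ">a\nAA\n>b\nAA\n>c\nAA\n>d\nAA\n", s0)
        for node in tree.postorder():
            assert node.cost == 0
        assert len(tree.root.prelim) == 2
        assert all(e.tag == BOTH for e in tree.root.prelim)

    def test_cherry_root_cost_is_the_substitution_cost(self, s0):
        tree = build("(a,b);", ">a\nA\n>b\nC\n", s0)
        assert tree.root.cost == 1

    def test_homopolymer_quartet_under_indel_preferring_metric(self, s1):
        # every pairwise alignment is all-indel: cost 2+2+4, length 4
        tree = build("((a,b),(c,d));", ">a\nA\n>b\nC\n>c\nG\n>d\nT\n", s1)
        assert tree.root.cost == 8
        assert len(tree.root.prelim) == 4

    def test_internal_costs_accumulate_local_oracle_costs(self, s1):
        tree = build("((a,b),(c,d));", ">a\nAC\n>b\nAG\n>c\nT\n>d\nGT\n", s1)
        total = 0
        for node in tree.postorder():
            if not node.is_leaf:
                total += alignment_oracle(
                    node.left.prelim, node.right.prelim, s1
                )
        assert tree.root.cost == total

    def test_no_gapped_elements_in_any_context(self, s1):
        tree = build("((a,b),(c,d));", ">a\nACG\n>b\nT\n>c\nGG\n>d\nAT\n", s1)
        for node in tree.postorder():
            assert all(e.tag != GAPPED for e in node.prelim)

    def test_undecorated_leaf_rejected(self, s0):
        tree = parse_newick("(a,b);")
        with pytest.raises(ValueError, match="not decorated"):
            postorder_decorate(tree, s0)


class TestSlidingZip:
    def A(self, s0):
        return s0.alphabet.mask("A")

    def test_case0_parent_gap_propagates(self):
        assert sliding_zip([GAPPED_ELEMENT], [], [], "left") == [
            GAPPED_ELEMENT
        ]

    def test_case2_aligned_with_sister_emits_child_element(self, s0):
        x = s0.alphabet.mask("A")
        parent = [TaggedElement(BOTH, x, x)]
        child_el = TaggedElement(BOTH, x, x)
        for side in ("left", "right"):
            assert sliding_zip(parent, parent, [child_el], side) == [child_el]

    def test_case3_left_element_goes_to_left_child(self, s0):
        x = s0.alphabet.mask("A")
        parent = [TaggedElement(LEFT, x)]
        child_el = TaggedElement(BOTH, x, x)
        assert sliding_zip(parent, parent, [child_el], "left") == [child_el]

    def test_case5_left_element_gaps_the_right_child(self, s0):
        x = s0.alphabet.mask("A")
        parent = [TaggedElement(LEFT, x)]
        assert sliding_zip(parent, parent, [], "right") == [GAPPED_ELEMENT]

    def test_case4_right_element_goes_to_right_child(self, s0):
        x = s0.alphabet.mask("G")
        parent = [TaggedElement(RIGHT, x)]
        child_el = TaggedElement(BOTH, x, x)
        assert sliding_zip(parent, parent, [child_el], "right") == [child_el]

    def test_case1_exhausted_child_pads_with_gaps(self, s0):
        x = s0.alphabet.mask("A")
        parent = [TaggedElement(BOTH, x, x), TaggedElement(RIGHT, x)]
        child_el = TaggedElement(BOTH, x, x)
        out = sliding_zip(parent, parent, [child_el], "left")
        assert out == [child_el, GAPPED_ELEMENT]

    def test_length_precondition_enforced(self, s0):
        x = s0.alphabet.mask("A")
        el = TaggedElement(BOTH, x, x)
        with pytest.raises(ValueError, match="precondition"):
            sliding_zip([el], [el, el], [el], "left")
        with pytest.raises(ValueError, match="left.*right"):
            sliding_zip([el], [el], [el], "up")


class TestPreorder:
    def test_two_leaf_tree_renders_the_pairwise_alignment(self, s0):
        result = run_pipeline(">x\nAC\n>y\nA\n", "(x,y);", s0)
        assert result.rows == [("x", "AC"), ("y", "A-")]

    def test_identical_quartet_is_gap_free(self, s0):
        result = run_pipeline(
            ">a\nA\n>b\nA\n>c\nA\n>d\nA\n", "((a,b),(c,d));", s0
        )
        assert [r for _, r in result.rows] == ["A"] * 4
        assert result.alignment_length == 1

    def test_homopolymer_quartet_rows_have_one_residue_each(self, s1):
        result = run_pipeline(
            ">a\nA\n>b\nC\n>c\nG\n>d\nT\n", "((a,b),(c,d));", s1
        )
        assert result.alignment_length == 4
        for _, row in result.rows:
            assert len(row) == 4
            assert sum(c != "-" for c in row) == 1
        # every column holds exactly one residue: a degenerate alignment
        cols = list(zip(*[row for _, row in result.rows]))
        assert all(sum(c != "-" for c in col) == 1 for col in cols)

    def test_requires_postorder_decorations(self, s0):
        tree = parse_newick("(a,b);")
        with pytest.raises(ValueError, match="post-order"):
            preorder_finalize(tree)


def check_invariants(result, sequences):
    """Structural invariants every implied alignment must satisfy."""
    rows = dict(result.rows)
    a = result.alignment_length
    lengths = {len(r) for r in rows.values()}
    assert lengths == {a}
    k = max(len(s) for s in sequences.values())
    total = sum(len(s) for s in sequences.values())
    assert k <= a <= total
    for name, seq in sequences.items():
        assert rows[name].replace("-", "") == seq
    if a:
        assert all(
            any(row[i] != "-" for row in rows.values()) for i in range(a)
        )


class TestTreeProperties:
    def test_random_trees_satisfy_structural_invariants(self, s0, s1, s3):
        rng = random.Random(1234)
        metrics = [s0, s1, s3]
        for _ in range(25):
            n = rng.randint(2, 12)
            newick, fasta = random_instance(rng, n, max_len=12)
            metric = rng.choice(metrics)
            result = run_pipeline(fasta, newick, metric)
            seqs = {
                name: seq
                for name, seq in (
                    block.split("\n")[:2]
                    for block in fasta.strip().split(">")[1:]
                )
            }
            check_invariants(result, seqs)

    def test_label_invariance_under_child_transposition(self, s0, s1):
        rng = random.Random(99)
        for metric in (s0, s1):
            for _ in range(10):
                newick, fasta = random_instance(rng, rng.randint(3, 10), 10)
                base = dict(run_pipeline(fasta, newick, metric).rows)
                flipped = flip_random_children(newick, rng)
                assert dict(run_pipeline(fasta, flipped, metric).rows) == base

    def test_rebracketing_may_differ_but_stays_valid(self, s1):
        fasta = ">A\nACG\n>B\nGT\n>C\nAC\n>D\nTT\n"
        seqs = {"A": "ACG", "B": "GT", "C": "AC", "D": "TT"}
        for newick in ("((A,(B,C)),D);", "((A,B),(C,D));"):
            check_invariants(run_pipeline(fasta, newick, s1), seqs)

    def test_root_cost_equals_sum_of_local_alignment_costs(self, s1):
        rng = random.Random(5)
        newick, fasta = random_instance(rng, 8, 10)
        tree = build(newick, fasta, s1)
        local = sum(
            align_tagged(n.left.prelim, n.right.prelim, s1).cost
            for n in tree.postorder()
            if not n.is_leaf
        )
        assert tree.root.cost == local

    def test_final_alignment_degap_recovers_prelim(self, s1):
        rng = random.Random(77)
        newick, fasta = random_instance(rng, 9, 15)
        tree = build(newick, fasta, s1)
        preorder_finalize(tree)
        a = len(tree.root.prelim)
        for node in tree.preorder():
            assert len(node.final) == a
            assert [e for e in node.final if e.tag != GAPPED] == node.prelim
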