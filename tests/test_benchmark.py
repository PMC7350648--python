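"""Pathological generator, dataset degradation and the scaling fit."""

from io import StringIO

import numpy as np
import pytest
from Bio import SeqIO

from implied_alignment import (
    ScalingRecord,
    compute_m,
    decorate_leaves,
    degrade_dataset,
    fit_loglog,
    generate_pathological,
    parse_fasta,
    parse_newick,
    postorder_decorate,
    run_scaling_study,
    sigma0,
    sigma1,
)


def read_rows(fasta):
    return {r.id: str(r.seq) for r in SeqIO.parse(StringIO(fasta), "fasta")}


class TestGenerator:
    def test_smallest_tree_is_a_quartet_of_single_symbols(self):
        newick, fasta, tcm = generate_pathological(1, 4, "perfect")
        assert newick == "((t1,t2),(t3,t4));"
        assert read_rows(fasta) == {"t1": "A", "t2": "C", "t3": "G", "t4": "T"}
        assert tcm == "sigma0"

    def test_symbols_repeat_k_times(self):
        _, fasta, _ = generate_pathological(2, 4, "perfect")
        assert read_rows(fasta) == {
            "t1": "AA", "t2": "CC", "t3": "GG", "t4": "TT"
        }

    def test_larger_trees_are_balanced_joins_of_quartets(self):
        newick, fasta, tcm = generate_pathological(1, 8, "degenerate")
        tree = parse_newick(newick)
        assert tree.n_leaves == 8
        # balanced: both root subtrees hold one quartet
        assert len(read_rows(fasta)) == 8
        assert tcm == "sigma1"

    def test_each_quartet_holds_all_four_homopolymers(self):
        _, fasta, _ = generate_pathological(3, 16, "degenerate")
        rows = read_rows(fasta)
        for q in range(4):
            block = {rows[f"t{4 * q + i + 1}"] for i in range(4)}
            assert block == {"AAA", "CCC", "GGG", "TTT"}

    @pytest.mark.parametrize("n", [2, 5, 12])
    def test_invalid_leaf_counts_rejected(self, n):
        with pytest.raises(ValueError, match="power of two"):
            generate_pathological(1, n, "perfect")

    def test_invalid_k_and_mode_rejected(self):
        with pytest.raises(ValueError, match="k"):
            generate_pathological(0, 4, "perfect")
        with pytest.raises(ValueError, match="mode"):
            generate_pathological(1, 4, "typical")

    def test_seed_shuffles_names_but_not_structure(self):
        n1, f1, _ = generate_pathological(2, 8, "perfect", seed=3)
        n2, f2, _ = generate_pathological(2, 8, "perfect")
        assert sorted(read_rows(f1).values()) == sorted(read_rows(f2).values())
        assert parse_newick(n1).n_leaves == 8


class TestComputeM:
    def prepared(self, k, n, mode, metric):
        newick, fasta, _ = generate_pathological(k, n, mode)
        tree = parse_newick(newick)
        decorate_leaves(
            tree, parse_fasta(fasta, metric.alphabet), metric.alphabet
        )
        return postorder_decorate(tree, metric)

    @pytest.mark.parametrize("k", [1, 16, 64])
    def test_perfect_quartet_reaches_the_best_case(self, s0, k):
        assert compute_m(self.prepared(k, 4, "perfect", s0)) == 1.0

    def test_degenerate_quartet_reaches_the_worst_case(self, s1):
        assert compute_m(self.prepared(1, 4, "degenerate", s1)) == 4.0

    def test_two_identical_leaves(self, s0):
        tree = parse_newick("(x,y);")
        seqs = parse_fasta(">x\nACG\n>y\nACG\n", s0.alphabet)
        decorate_leaves(tree, seqs, s0.alphabet)
        postorder_decorate(tree, s0)
        assert compute_m(tree) == 1.0


class TestDegrade:
    def make_alignment(self):
        names = [f"t{i}" for i in range(8)]
        rows = [(n, "AC-GTAC-") for n in names]
        newick = "(((t0,t1),(t2,t3)),((t4,t5),(t6,t7)));"
        fasta = "".join(f">{n}\n{s}\n" for n, s in rows)
        return fasta, newick

    def test_one_halving_takes_central_slice_and_degaps(self):
        fasta, newick = self.make_alignment()
        (inst,) = degrade_dataset(fasta, newick, 1)
        sub_newick, sub_fasta = inst
        rows = read_rows(sub_fasta)
        assert len(rows) == 4
        # central slice of length 4 from "AC-GTAC-" is "-GTA"; degapped "GTA"
        assert set(rows.values()) == {"GTA"}
        tree = parse_newick(sub_newick)  # pruned tree is strictly binary
        assert tree.n_leaves == 4

    def test_successive_halvings_nest(self):
        fasta, newick = self.make_alignment()
        instances = degrade_dataset(fasta, newick, 2)
        assert len(instances) == 2
        assert parse_newick(instances[1][0]).n_leaves == 2

    def test_all_gap_slice_warns(self):
        names = ["a", "b", "c", "d"]
        seqs = ["A--A", "AAAA", "AAAA", "AAAA"]  # "a" survives the halving
        fasta = "".join(f">{n}\n{s}\n" for n, s in zip(names, seqs))
        newick = "((a,b),(c,d));"
        with pytest.warns(UserWarning, match="empty"):
            degrade_dataset(fasta, newick, 1)

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            degrade_dataset(">a\nAC\n>b\nACG\n", "(a,b);", 1)


class TestScalingStudy:
    def test_grid_yields_one_positive_record_per_point(self):
        grid = [(4, 4), (4, 8), (8, 4), (8, 8)]
        records = run_scaling_study(grid, "perfect", repeats=2)
        assert len(records) == 4
        assert all(r.runtime_ms > 0 for r in records)
        assert {(r.k, r.n) for r in records} == set(grid)

    def test_degenerate_runtime_grows_with_n_at_fixed_k(self):
        records = run_scaling_study([(32, 4), (32, 64)], "degenerate", 3)
        by_n = {r.n: r.runtime_ms for r in records}
        assert by_n[64] > by_n[4]


class TestFitLogLog:
    def test_exact_on_noiseless_quadratic_linear_law(self):
        records = [
            ScalingRecord(n, k, float(n * n * k))
            for n in (4, 8, 16)
            for k in (16, 32)
        ]
        fit = fit_loglog(records)
        assert fit.beta1 == pytest.approx(2.0, abs=1e-9)
        assert fit.beta2 == pytest.approx(1.0, abs=1e-9)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_runtime_has_zero_exponents(self):
        records = [
            ScalingRecord(n, k, 7.0) for n in (4, 8, 16) for k in (16, 32)
        ]
        fit = fit_loglog(records)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-9)
        assert fit.beta2 == pytest.approx(0.0, abs=1e-9)

    def test_three_noiseless_points_match_direct_linear_solve(self):
        points = [(4, 16, 100.0), (8, 16, 300.0), (4, 64, 500.0)]
        records = [ScalingRecord(*p) for p in points]
        fit = fit_loglog(records)
        a = np.array([[1, np.log2(n), np.log2(k)] for n, k, _ in points])
        b = np.log2([r for *_, r in points])
        expect = np.linalg.solve(a, b)
        assert np.allclose([fit.beta0, fit.beta1, fit.beta2], expect)
        assert fit.adj_r2 == 1.0

    def test_rank_deficient_design_rejected(self):
        same_n = [ScalingRecord(4, k, 1.0 * k) for k in (2, 4, 8, 16)]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_loglog(same_n)
        with pytest.raises(ValueError, match="at least 3"):
            fit_loglog(same_n[:2])
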