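"""Progressive alignment, NJ trees, midpoint rooting, monophyly."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from conftest import mutate, random_protein
from quinrec.phylo import (
    MultipleAlignment,
    distance_matrix,
    is_monophyletic,
    midpoint_root,
    nj_tree,
    progressive_align,
    separation_report,
)


class TestProgressiveAlign:
    def test_identical_pair_aligns_gapless(self):
        aln = progressive_align({"a": "MKTAYIAKQR", "b": "MKTAYIAKQR"})
        assert aln.rows == ("MKTAYIAKQR", "MKTAYIAKQR")

    def test_internal_deletion_produces_one_gap_block(self):
        full = "MKTAYIAKQRWNDEFGHILV"
        deleted = full[:8] + full[12:]
        aln = progressive_align({"full": full, "del": deleted})
        row = aln.row("del")
        assert row.count("-") == 4
        gap_start = row.index("-")
        assert row[gap_start : gap_start + 4] == "----"
        assert aln.row("full") == full

    def test_column_count_at_least_longest_input(self):
        rng = np.random.default_rng(4)
        seqs = {f"s{i}": random_protein(rng, int(rng.integers(20, 40)))
                for i in range(5)}
        aln = progressive_align(seqs)
        assert aln.n_columns >= max(len(s) for s in seqs.values())

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align({"a": "MKTA"})


class TestDistanceMatrix:
    def test_identical_rows_have_zero_distance(self):
        aln = MultipleAlignment(("a", "b"), ("MKTA", "MKTA"))
        dm = distance_matrix(aln, "p_distance")
        assert dm["a", "b"] == 0.0

    def test_half_mismatches_give_p_half(self):
        aln = MultipleAlignment(("a", "b"), ("MKTA", "MKAY"))
        dm = distance_matrix(aln, "p_distance")
        assert dm["a", "b"] == pytest.approx(0.5)

    def test_poisson_correction_formula(self):
        aln = MultipleAlignment(("a", "b"), ("MKTA", "MKAY"))
        dm = distance_matrix(aln, "poisson")
        assert dm["a", "b"] == pytest.approx(-math.log(0.5))

    def test_gap_columns_pairwise_deleted(self):
        aln = MultipleAlignment(("a", "b"), ("MK-A", "MKTA"))
        dm = distance_matrix(aln, "p_distance")
        assert dm["a", "b"] == 0.0

    def test_no_comparable_columns_names_the_pair(self):
        aln = MultipleAlignment(("a", "b"), ("MK--", "--TA"))
        with pytest.raises(ValueError, match="'a'.*'b'"):
            distance_matrix(aln)


class TestNJ:
    def test_three_taxa_closed_form_branch_lengths(self):
        dm = DistanceMatrix(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"]
        )
        tree = nj_tree(dm)
        depths = {t.name: t.length for t in tree.tips()}
        # three-point formulas: a=(dab+dac-dbc)/2 etc.
        assert depths["a"] == pytest.approx(1.0)
        assert depths["b"] == pytest.approx(2.0)
        assert depths["c"] == pytest.approx(3.0)

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        # ((a:2,b:3):1,(c:1,d:4):2,e:5) - pairwise path lengths are additive
        ref = TreeNode.read(["((a:2,b:3):1,(c:1,d:4):2,e:5);"])
        taxa = ["a", "b", "c", "d", "e"]
        dm = DistanceMatrix(
            [[ref.find(x).distance(ref.find(y)) for y in taxa] for x in taxa],
            taxa,
        )
        tree = nj_tree(dm)
        for i, x in enumerate(taxa):
            for y in taxa[i + 1 :]:
                assert tree.find(x).distance(tree.find(y)) == pytest.approx(
                    dm[x, y]
                ), (x, y)
        assert tree.compare_rfd(ref) == 0

    def test_leaf_order_permutation_gives_same_tree(self):
        rng = np.random.default_rng(9)
        taxa = ["a", "b", "c", "d", "e"]
        mat = rng.random((5, 5)) * 5 + 1
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        dm1 = DistanceMatrix(mat, taxa)
        perm = [3, 1, 4, 0, 2]
        dm2 = DistanceMatrix(mat[np.ix_(perm, perm)], [taxa[i] for i in perm])
        t1, t2 = nj_tree(dm1), nj_tree(dm2)
        assert t1.compare_rfd(t2) == 0
        for i, x in enumerate(taxa):
            for y in taxa[i + 1 :]:
                assert t1.find(x).distance(t1.find(y)) == pytest.approx(
                    t2.find(x).distance(t2.find(y))
                )

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))


def _random_tree(rng, n) -> TreeNode:
    nodes = [TreeNode(name=f"t{i}", length=float(rng.random() + 0.1))
             for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = TreeNode(length=float(rng.random() + 0.1),
                          children=[nodes[i], nodes[j]])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    root = nodes[0]
    root.length = None
    return root


class TestMidpointRoot:
    def test_two_leaf_arithmetic(self):
        tree = TreeNode.read(["(a:1,b:3);"])
        rooted = midpoint_root(tree)
        depths = {t.name: rooted.find(t.name).accumulate_to_ancestor(rooted)
                  for t in rooted.tips()}
        assert depths["a"] == pytest.approx(2.0)
        assert depths["b"] == pytest.approx(2.0)

    def test_symmetric_quartet_roots_on_central_edge(self):
        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        rooted = midpoint_root(tree)
        depths = [t.accumulate_to_ancestor(rooted) for t in rooted.tips()]
        assert all(d == pytest.approx(2.0) for d in depths)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_deepest_leaves_equidistant_from_root(self, seed):
        rng = np.random.default_rng(seed)
        tree = _random_tree(rng, int(rng.integers(4, 9)))
        rooted = midpoint_root(tree)
        depths = sorted(
            (t.accumulate_to_ancestor(rooted) for t in rooted.tips()),
            reverse=True,
        )
        assert depths[0] == pytest.approx(depths[1], abs=1e-9)


class TestMonophyly:
    def test_full_leaf_set_and_singletons_are_monophyletic(self):
        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1):1;"])
        assert is_monophyletic(tree, {"a", "b", "c", "d"})
        assert is_monophyletic(tree, {"c"})

    def test_unknown_leaf_rejected(self):
        tree = TreeNode.read(["((a:1,b:1):1,c:1):1;"])
        with pytest.raises(ValueError, match="ghost"):
            is_monophyletic(tree, {"ghost"})

    @pytest.mark.parametrize("seed", range(6))
    def test_verdicts_match_lca_oracle_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        tree = _random_tree(rng, int(rng.integers(4, 9)))
        tips = [t.name for t in tree.tips()]
        for _ in range(12):
            k = int(rng.integers(1, len(tips) + 1))
            query = set(rng.choice(tips, size=k, replace=False).tolist())
            if len(query) == 1:
                expected = True
            else:
                lca = tree.lca(list(query))
                expected = {t.name for t in lca.tips()} == query
            assert is_monophyletic(tree, query) == expected, query


class TestSeparationReport:
    def test_interleaved_labels_on_caterpillar_not_monophyletic(self):
        tree = TreeNode.read(["(((a:1,b:1):1,c:1):1,d:1):1;"])
        report = separation_report(
            tree, {"a": "X", "b": "Y", "c": "X", "d": "Y"}
        )
        assert report["monophyletic"] == {"X": False, "Y": False}
        assert ("X", "Y") in report["mixed_pairs"]  # union is the whole tree

    def test_clean_split_is_monophyletic_both_sides(self):
        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1):1;"])
        report = separation_report(
            tree, {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        )
        assert report["monophyletic"] == {"X": True, "Y": True}
        assert report["mixed_pairs"] == []

    def test_labeling_must_cover_all_tips(self):
        tree = TreeNode.read(["((a:1,b:1):1,c:1):1;"])
        with pytest.raises(ValueError, match="c"):
            separation_report(tree, {"a": "X", "b": "Y"})

    def test_three_divergent_families_separate(self):
        rng = np.random.default_rng(15)
        seqs = {}
        for fam in ("F1", "F2", "F3"):
            anc = random_protein(rng, 100)
            for i in range(4):
                seqs[f"{fam}_{i}"] = mutate(rng, anc, 0.15)
        aln = progressive_align(seqs)
        tree = midpoint_root(nj_tree(distance_matrix(aln)))
        report = separation_report(
            tree, {name: name.split("_")[0] for name in seqs}
        )
        assert all(report["monophyletic"].values())
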