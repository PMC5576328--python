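import numpy as np
import pandas as pd
import pytest
from skbio.diversity.alpha import chao1 as skbio_chao1
from skbio.diversity.beta import (
    unweighted_unifrac as skbio_uwuf,
    weighted_unifrac as skbio_wuf,
)

import _oracles
from microconcord.diversity import (
    BranchIndex,
    alpha_diversity,
    alpha_group_test,
    chao1,
    faith_pd,
    observed_otus,
    pairwise_unifrac_significance,
    unifrac_matrix,
    unifrac_pair_significance,
    unweighted_unifrac,
    weighted_unifrac,
)
from microconcord.errors import DataError, ParameterError
from microconcord.io_formats import CountTable, read_newick_string
from microconcord.synthetic_data import simulate_tree


def _counts_dict(tree, counts):
    leaves = [t.name for t in tree.tips()]
    return dict(zip(leaves, counts))


class TestAlpha:
    def test_observed_otus(self):
        assert observed_otus(np.array([3, 0, 1])) == 2
        assert observed_otus(np.zeros(4)) == 0

    def test_chao1_with_doubletons(self):
        assert chao1(np.array([4, 2, 1, 1, 2])) == pytest.approx(6.0)

    def test_chao1_without_singletons_equals_observed(self):
        assert chao1(np.array([4, 3, 2])) == pytest.approx(3.0)
        assert chao1(np.array([4, 3, 3])) == pytest.approx(3.0)

    def test_chao1_bias_corrected_branch(self):
        assert chao1(np.array([1, 1])) == pytest.approx(3.0)

    def test_chao1_matches_skbio(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            col = rng.integers(0, 6, 30)
            if np.count_nonzero(col == 2) == 0:
                continue
            assert chao1(col) == pytest.approx(
                float(skbio_chao1(col, bias_corrected=False))
            )

    def test_chao1_at_least_observed(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            col = rng.integers(0, 5, 20)
            assert chao1(col) >= observed_otus(col)

    def test_faith_pd_single_leaf_path(self, three_leaf_tree):
        # ((A:1,B:2):0.5,C:3):0; observing only A spans 1 + 0.5
        val = faith_pd(
            np.array([1, 0, 0]), three_leaf_tree, otu_ids=["A", "B", "C"]
        )
        assert val == pytest.approx(1.5)

    def test_faith_pd_all_leaves_is_total_length(self, three_leaf_tree):
        val = faith_pd(
            np.array([1, 1, 1]), three_leaf_tree, otu_ids=["A", "B", "C"]
        )
        assert val == pytest.approx(6.5)

    def test_faith_pd_empty_sample_is_zero(self, three_leaf_tree):
        assert faith_pd(
            np.zeros(3), three_leaf_tree, otu_ids=["A", "B", "C"]
        ) == 0.0

    def test_faith_pd_missing_otu_named_in_error(self, three_leaf_tree):
        with pytest.raises(DataError, match="OTU_X"):
            faith_pd(np.array([1]), three_leaf_tree, otu_ids=["OTU_X"])

    def test_faith_pd_monotone_in_observed_set(self):
        rng = np.random.default_rng(17)
        tree = simulate_tree(10, seed=3)
        names = [t.name for t in tree.tips()]
        col = (rng.random(10) < 0.4).astype(int)
        base = faith_pd(col, tree, otu_ids=names)
        grown = col.copy()
        grown[np.argmin(grown)] = 1
        assert faith_pd(grown, tree, otu_ids=names) >= base

    def test_faith_pd_matches_brute_force(self):
        rng = np.random.default_rng(90)
        for seed in range(20):
            tree = simulate_tree(8, seed=seed)
            names = [t.name for t in tree.tips()]
            col = rng.integers(0, 3, 8)
            if col.sum() == 0:
                col[0] = 1
            assert faith_pd(col, tree, otu_ids=names) == pytest.approx(
                _oracles.brute_faith_pd(tree, dict(zip(names, col)))
            )


class TestUniFrac:
    def test_identical_presence_sets_give_zero(self, three_leaf_tree):
        a = np.array([2, 1, 5])
        assert unweighted_unifrac(
            a, a * 3, three_leaf_tree, otu_ids=["A", "B", "C"]
        ) == pytest.approx(0.0)

    def test_star_tree_disjoint_sets_give_one(self):
        tree = read_newick_string("(A:1,B:2,C:3,D:1):0;")
        d = unweighted_unifrac(
            np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1]), tree,
            otu_ids=["A", "B", "C", "D"],
        )
        assert d == pytest.approx(1.0)

    def test_worked_shared_and_unique_branches(self):
        tree = read_newick_string("((A:1,B:1):1,C:2):0;")
        d = unweighted_unifrac(
            np.array([1, 1, 0]), np.array([1, 0, 1]), tree,
            otu_ids=["A", "B", "C"],
        )
        assert d == pytest.approx(0.6)

    def test_weighted_proportional_columns_give_zero(self, three_leaf_tree):
        a = np.array([4, 2, 2])
        assert weighted_unifrac(
            a, a * 10, three_leaf_tree, otu_ids=["A", "B", "C"]
        ) == pytest.approx(0.0)

    def test_weighted_two_leaf_separation(self):
        tree = read_newick_string("(A:1,B:1):0;")
        d = weighted_unifrac(
            np.array([5, 0]), np.array([0, 7]), tree, otu_ids=["A", "B"]
        )
        assert d == pytest.approx(2.0)

    @pytest.mark.parametrize("eps", [0.0, 0.1, 0.25, 0.5])
    def test_weighted_linear_in_moved_mass_on_two_leaf_tree(self, eps):
        tree = read_newick_string("(A:1,B:1):0;")
        d = weighted_unifrac(
            np.array([1 - eps, eps]), np.array([1.0, 0.0]), tree,
            otu_ids=["A", "B"],
        )
        assert d == pytest.approx(2 * eps)

    def test_empty_sample_rejected(self, three_leaf_tree):
        with pytest.raises(ParameterError):
            weighted_unifrac(
                np.zeros(3), np.array([1, 1, 1]), three_leaf_tree,
                otu_ids=["A", "B", "C"],
            )

    def test_oracle_agreement_on_random_trees(self):
        rng = np.random.default_rng(1234)
        for seed in range(100):
            tree = simulate_tree(8, seed=seed)
            names = [t.name for t in tree.tips()]
            a = rng.integers(0, 5, 8)
            b = rng.integers(0, 5, 8)
            if a.sum() == 0:
                a[0] = 1
            if b.sum() == 0:
                b[-1] = 1
            da = dict(zip(names, a))
            db = dict(zip(names, b))
            uw = unweighted_unifrac(a, b, tree, otu_ids=names)
            assert uw == pytest.approx(
                _oracles.brute_unweighted_unifrac(tree, da, db), abs=1e-12
            )
            assert 0.0 <= uw <= 1.0
            w = weighted_unifrac(a, b, tree, otu_ids=names)
            assert w == pytest.approx(
                _oracles.brute_weighted_unifrac(tree, da, db), abs=1e-12
            )
            wn = weighted_unifrac(a, b, tree, otu_ids=names, normalized=True)
            assert wn == pytest.approx(
                _oracles.brute_weighted_unifrac(tree, da, db, normalized=True),
                abs=1e-12,
            )
            assert 0.0 <= wn <= 1.0

    def test_agreement_with_skbio(self):
        rng = np.random.default_rng(55)
        for seed in range(10):
            tree = simulate_tree(8, seed=100 + seed)
            names = [t.name for t in tree.tips()]
            a = rng.integers(1, 6, 8)
            b = rng.integers(1, 6, 8)
            assert unweighted_unifrac(a, b, tree, otu_ids=names) == pytest.approx(
                float(skbio_uwuf(a, b, taxa=names, tree=tree))
            )
            assert weighted_unifrac(a, b, tree, otu_ids=names) == pytest.approx(
                float(skbio_wuf(a, b, taxa=names, tree=tree))
            )

    def test_symmetry(self):
        tree = simulate_tree(8, seed=7)
        names = [t.name for t in tree.tips()]
        rng = np.random.default_rng(0)
        a, b = rng.integers(1, 9, 8), rng.integers(1, 9, 8)
        for metric in (unweighted_unifrac, weighted_unifrac):
            assert metric(a, b, tree, otu_ids=names) == pytest.approx(
                metric(b, a, tree, otu_ids=names)
            )


class TestPairSignificance:
    def test_identical_columns_give_p_one(self, three_leaf_tree):
        a = np.array([5, 5, 5])
        d, p = unifrac_pair_significance(
            a, a, three_leaf_tree, metric="wuf", n_perm=199, seed=1,
            otu_ids=["A", "B", "C"],
        )
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_invariant_to_labeling_order(self):
        tree = simulate_tree(10, seed=2)
        names = [t.name for t in tree.tips()]
        rng = np.random.default_rng(6)
        a = rng.integers(0, 30, 10)
        b = rng.integers(0, 30, 10)
        r1 = unifrac_pair_significance(
            a, b, tree, metric="wuf", n_perm=199, seed=42, otu_ids=names
        )
        r2 = unifrac_pair_significance(
            b, a, tree, metric="wuf", n_perm=199, seed=42, otu_ids=names
        )
        assert r1 == r2

    def test_too_few_permutations_rejected(self, three_leaf_tree):
        with pytest.raises(ParameterError):
            unifrac_pair_significance(
                np.array([1, 1, 1]), np.array([1, 1, 1]), three_leaf_tree,
                n_perm=10, otu_ids=["A", "B", "C"],
            )

    def test_all_unordered_pairs_compared(self):
        # 72 samples -> 72 * 71 / 2 = 2556 Bonferroni-corrected comparisons
        tree = simulate_tree(12, seed=5)
        rng = np.random.default_rng(8)
        data = pd.DataFrame(
            rng.integers(1, 20, size=(12, 72)),
            index=[t.name for t in tree.tips()],
            columns=[f"S{i}" for i in range(72)],
        )
        out = pairwise_unifrac_significance(
            CountTable(data), tree, metric="wuf", n_perm=100, seed=0
        )
        assert len(out) == 2556
        assert (out.p_bonferroni >= out.p_raw).all()
        assert (out.p_bonferroni <= 1.0).all()

    def test_matrix_matches_pointwise_metric(self):
        tree = simulate_tree(6, seed=9)
        names = [t.name for t in tree.tips()]
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            rng.integers(1, 15, size=(6, 4)), index=names,
            columns=list("wxyz"),
        )
        table = CountTable(data)
        dm = unifrac_matrix(table, tree, "uwuf")
        val = unweighted_unifrac(
            table.column("w"), table.column("y"), tree, otu_ids=names
        )
        assert dm["w", "y"] == pytest.approx(val)


class TestAlphaGroupTest:
    def test_identical_groups_give_p_one(self):
        t, p = alpha_group_test(
            np.array([5.0, 5.0, 5.0]), np.array([5.0, 5.0, 5.0]),
            n_perm=199, seed=0,
        )
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_complete_separation_matches_enumeration(self):
        # exact two-sided enumeration over the C(6,3)=20 label splits: the
        # observed split and its mirror reach |t|, so p -> 2/20 = 0.1
        t, p = alpha_group_test(
            np.array([1.0, 2.0, 3.0]), np.array([101.0, 102.0, 103.0]),
            n_perm=999, seed=1,
        )
        assert abs(t) > 50
        assert p == pytest.approx(0.1, abs=0.03)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ParameterError):
            alpha_group_test(np.array([1.0]), np.array([2.0, 3.0]))

    def test_alpha_diversity_table_driver(self, three_leaf_tree):
        table = CountTable(
            pd.DataFrame({"S1": [2, 1, 1], "S2": [0, 0, 9]},
                         index=["A", "B", "C"])
        )
        res = alpha_diversity(table, three_leaf_tree)
        assert [r.sample_id for r in res] == ["S1", "S2"]
        assert res[0].observed_otus == 3
        assert res[1].faith_pd == pytest.approx(3.0)
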