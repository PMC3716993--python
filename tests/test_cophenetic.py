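"""Cophenetic vectors, the d_phi_p family, and derived encodings."""

import itertools
import random

import numpy as np
import pytest

from cophen.tree_model import parse_newick, PhyloTree
from cophen.cophenetic import (
    cophenetic_vector,
    reduced_vector,
    depths_from_reduced,
    d_phi_p,
    d_phi_0,
    D_p,
    patristic_from_cophenetic,
    splitted_lengths_from_cophenetic,
)
from cophen.treespaces import sample_binary
from tests.conftest import TABLE1_VALUES


def naive_cophenetic(tree: PhyloTree):
    """O(n^3) oracle: depth of the LCA found by ancestor-set intersection,
    independent of the postorder pair-assignment algorithm."""
    depth = tree.depths()
    out = {}
    for i in tree.taxa:
        for j in tree.taxa:
            node = tree.lca(i, j)
            out[(i, j)] = depth[node]
    return out


class TestCopheneticVector:
    def test_worked_example_all_entries(self, table1_tree):
        vec = cophenetic_vector(table1_tree)
        for (i, j), expected in TABLE1_VALUES.items():
            assert vec.get(str(i), str(j)) == expected

    def test_star_tree(self):
        vec = cophenetic_vector(parse_newick("(1,2,3);"))
        for i, j in itertools.combinations("123", 2):
            assert vec.get(i, j) == 0
        for i in "123":
            assert vec.get(i, i) == 1

    def test_matches_naive_oracle_on_bt5(self, bt5_trees):
        assert len(bt5_trees) == 105
        for tree in bt5_trees:
            vec = cophenetic_vector(tree)
            oracle = naive_cophenetic(tree)
            for i, j in itertools.combinations_with_replacement(tree.taxa, 2):
                assert vec.get(i, j) == oracle[(i, j)]

    def test_three_point_condition(self, table1_tree, t5_trees):
        # among the three pairwise values of any taxon triple, the two
        # smallest coincide
        for tree in [table1_tree] + t5_trees[::10]:
            vec = cophenetic_vector(tree)
            for i, j, k in itertools.combinations(tree.taxa, 3):
                vals = sorted([vec.get(i, j), vec.get(i, k), vec.get(j, k)])
                assert vals[0] == vals[1]

    def test_bounds(self, table1_tree):
        vec = cophenetic_vector(table1_tree)
        for i, j in itertools.combinations(table1_tree.taxa, 2):
            assert 0 <= vec.get(i, j) <= min(vec.get(i, i), vec.get(j, j))


class TestReducedVector:
    def test_worked_example_offdiagonal(self, table1_tree):
        red = reduced_vector(table1_tree)
        assert len(red.values) == 21
        for (i, j), expected in TABLE1_VALUES.items():
            if i != j:
                assert red.get(str(i), str(j)) == expected

    def test_cherry_single_entry(self):
        red = reduced_vector(parse_newick("(1,2);"))
        assert red.values.tolist() == [0.0]

    def test_injective_on_t5_but_not_on_weighted_cherries(self, t5_trees):
        vectors = {tuple(reduced_vector(t).values) for t in t5_trees}
        assert len(vectors) == len(t5_trees)
        a = reduced_vector(parse_newick("(1:1,2:1);"))
        b = reduced_vector(parse_newick("(1:2,2:2);"))
        assert a.values.tolist() == b.values.tolist() == [0.0]


class TestDepthsFromReduced:
    def test_small_examples(self):
        d = depths_from_reduced(reduced_vector(parse_newick("((1,2),3);")))
        assert d == {"1": 2.0, "2": 2.0, "3": 1.0}
        d = depths_from_reduced(reduced_vector(parse_newick("(1,2,3);")))
        assert d == {"1": 1.0, "2": 1.0, "3": 1.0}

    def test_single_taxon(self):
        assert depths_from_reduced(reduced_vector(parse_newick("1;"))) == {"1": 0.0}

    def test_exact_on_all_of_t5(self, t5_trees):
        for tree in t5_trees:
            assert depths_from_reduced(reduced_vector(tree)) == tree.taxon_depths()


class TestMetricFamily:
    def test_cherry_parent_contraction_value(self):
        t, tc = parse_newick("((1,2),3);"), parse_newick("(1,2,3);")
        assert d_phi_p(t, tc, 1) == 3  # n_v = 2 descendant taxa

    def test_identity(self, table1_tree):
        for p in (1, 2, 3.5):
            assert d_phi_p(table1_tree, table1_tree, p) == 0
        assert d_phi_0(table1_tree, table1_tree) == 0

    def test_bt3_euclidean(self):
        t1, t2 = parse_newick("((1,2),3);"), parse_newick("((1,3),2);")
        assert d_phi_p(t1, t2, 2) == pytest.approx(2.0)
        assert D_p(t1, t2, 2) == 4

    def test_hamming_equals_nonzero_count(self):
        rng = random.Random(5)
        for _ in range(100):
            t1, t2 = sample_binary(8, rng), sample_binary(8, rng)
            diff = cophenetic_vector(t1).values - cophenetic_vector(t2).values
            assert d_phi_0(t1, t2) == int((diff != 0).sum())

    def test_taxon_mismatch_and_bad_p(self):
        t1, t2 = parse_newick("(1,2);"), parse_newick("(1,3);")
        with pytest.raises(Exception):
            d_phi_p(t1, t2, 1)
        with pytest.raises(ValueError):
            d_phi_p(t1, parse_newick("(1,2);"), 0.5)

    def test_contraction_closed_form(self):
        # contracting an arc whose head has n_v descendant taxa changes
        # C(n_v+1, 2) entries, so D_0 = C(n_v+1,2) and
        # d_phi_p = C(n_v+1,2)^(1/p)
        from cophen.tree_model import contract_arc
        cat = parse_newick("(((((1,2),3),4),5),6);")
        for n_v in range(2, 6):
            node = cat.lca("1", str(n_v))
            tc = contract_arc(cat, node)
            expected = n_v * (n_v + 1) // 2
            assert D_p(cat, tc, 0) == expected
            for p in (1, 2, 3):
                assert d_phi_p(cat, tc, p) == pytest.approx(expected ** (1 / p))
        # n_v = 1: pendant contraction
        pend = contract_arc(cat, cat.node_of("1"))
        assert D_p(cat, pend, 0) == 1 and d_phi_p(cat, pend, 2) == 1

    def test_metric_axioms_on_t4(self, t4_trees):
        from scipy.spatial.distance import pdist, squareform
        from cophen.experiments import distance_tables
        tables = distance_tables(t4_trees, ["phi-1", "phi-2"], "T4")
        keys = [t.canonical_key() for t in t4_trees]
        for name in ("phi-1", "phi-2"):
            d = squareform(tables[name].values)
            assert np.allclose(d, d.T)
            # identity of indiscernibles: all enumerated trees distinct
            off = d[~np.eye(len(d), dtype=bool)]
            assert (off > 0).all()
            # triangle inequality over all ordered triples
            m = len(d)
            lhs = d[:, None, :]                      # d(i, k)
            rhs = d[:, :, None] + d[None, :, :]      # d(i, j) + d(j, k)
            assert (lhs <= rhs + 1e-9).all()
        assert len(set(keys)) == len(t4_trees)

    def test_dominance_of_manhattan(self):
        # d_phi_p <= d_phi_1 for all p >= 1
        rng = random.Random(17)
        for _ in range(1000):
            t1, t2 = sample_binary(10, rng), sample_binary(10, rng)
            d1 = d_phi_p(t1, t2, 1)
            for p in (1.5, 2, 3):
                assert d_phi_p(t1, t2, p) <= d1 + 1e-9

    def test_Dp_dominates_hamming(self):
        rng = random.Random(29)
        for _ in range(200):
            t1, t2 = sample_binary(7, rng), sample_binary(7, rng)
            d0 = D_p(t1, t2, 0)
            for p in (1, 2, 3):
                assert D_p(t1, t2, p) >= d0


class TestDerivedEncodings:
    def test_patristic_from_table1(self, table1_tree):
        d = patristic_from_cophenetic(cophenetic_vector(table1_tree))
        taxa = table1_tree.taxa
        assert d[taxa.index("1"), taxa.index("2")] == 4 + 3 - 2 * 2
        assert (np.diag(d) == 0).all()

    def test_patristic_against_path_oracle_on_t5(self, t5_trees):
        for tree in t5_trees:
            depth = tree.depths()
            d = patristic_from_cophenetic(cophenetic_vector(tree))
            for a, i in enumerate(tree.taxa):
                for b, j in enumerate(tree.taxa):
                    lca = tree.lca(i, j)
                    path = (depth[tree.node_of(i)] + depth[tree.node_of(j)]
                            - 2 * depth[lca])
                    assert d[a, b] == pytest.approx(path)

    def test_splitted_lengths_table1(self, table1_tree):
        ell = splitted_lengths_from_cophenetic(cophenetic_vector(table1_tree))
        taxa = table1_tree.taxa
        i1, i7 = taxa.index("1"), taxa.index("7")
        assert ell[i1, i7] == 1  # delta(1) - phi(1,7) = 4 - 3
        assert ell[i7, i1] == 0  # 7 is an ancestor of 1
        assert (np.diag(ell) == 0).all()

    def test_splitted_plus_transpose_is_patristic(self, t5_trees):
        for tree in t5_trees[::5]:
            vec = cophenetic_vector(tree)
            ell = splitted_lengths_from_cophenetic(vec)
            d = patristic_from_cophenetic(vec)
            assert np.allclose(ell + ell.T, d)
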