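"""Matrix/cube transforms: single-link decode, MRCA encode, orderings."""

import itertools

import numpy as np
import pytest

from cubevb.synthetic_data import simulate_yule
from cubevb.treespace import (
    CubeOrdering,
    EntryPattern,
    IncompatibleOrderingError,
    InvalidMatrixError,
    TreeMatrix,
    count_representable_topologies,
    cube_decode,
    cube_encode,
    enumerate_rooted_topologies,
    matrix_is_valid,
    random_compatible_ordering,
    single_link_tree,
    tree_to_matrix,
)

from conftest import three_taxon


class TestSingleLink:
    def test_two_taxa_cherry(self):
        T = single_link_tree(TreeMatrix(2, {(0, 1): 0.5}, taxa=["x1", "x2"]))
        assert T.n_leaves == 2
        assert T.root_height == 0.5

    def test_three_taxon_hand_execution(self):
        # cube entries m_AB=1, m_BC=2: first merge joins A,B at 1, then C at 2
        T = single_link_tree(TreeMatrix(3, {(0, 1): 1.0, (1, 2): 2.0}, taxa=list("ABC")))
        clades = {m: T.height[v] for v, m in T.clades().items()}
        assert clades[0b011] == 1.0  # {A,B}
        assert clades[0b111] == 2.0  # root
        assert T.newick() == "((A:1,B:1):1,C:2);"

    def test_disconnected_matrix_raises_with_components(self):
        # n=6 with n-1=5 entries but two components {0,1,2} and {3,4,5}
        M = TreeMatrix(6, {(0, 1): 1, (0, 2): 2, (1, 2): 3, (3, 4): 1, (3, 5): 2})
        with pytest.raises(InvalidMatrixError) as err:
            single_link_tree(M)
        assert [sorted(c) for c in err.value.components] == [[0, 1, 2], [3, 4, 5]]

    def test_entries_consumed_nondecreasing_and_subset(self, rng):
        for _ in range(20):
            n = 8
            vals = rng.uniform(0.1, 5.0, size=n * (n - 1) // 2)
            M = TreeMatrix(n, dict(zip(itertools.combinations(range(n), 2), vals)))
            T = single_link_tree(M)
            heights = sorted(T.height[n:])
            assert all(h in set(M.entries.values()) for h in heights)
            assert heights == sorted(heights)

    def test_label_permutation_equivariance(self, rng):
        n = 6
        vals = {p: float(v) for p, v in zip(
            itertools.combinations(range(n), 2), rng.uniform(0.1, 5, 15))}
        T = single_link_tree(TreeMatrix(n, vals))
        perm = rng.permutation(n)
        pvals = {
            (min(perm[i], perm[j]), max(perm[i], perm[j])): v
            for (i, j), v in vals.items()
        }
        T2 = single_link_tree(TreeMatrix(n, pvals))
        # clade heights must map through the permutation
        def remap(mask):
            return sum(1 << int(perm[i]) for i in range(n) if mask >> i & 1)
        a = {remap(m): T.height[v] for v, m in T.clades().items()}
        b = {m: T2.height[v] for v, m in T2.clades().items()}
        assert a == b


class TestValidity:
    def test_cube_pattern_valid(self):
        M = CubeOrdering([0, 1, 2, 3], np.array([1.0, 2.0, 3.0])).to_matrix()
        ok, comps = matrix_is_valid(M)
        assert ok and len(comps) == 1

    def test_disconnected_components_reported(self):
        M = TreeMatrix(6, {(0, 1): 1, (0, 2): 1, (1, 2): 1, (3, 4): 1, (3, 5): 1})
        ok, comps = matrix_is_valid(M)
        assert not ok
        assert [sorted(c) for c in comps] == [[0, 1, 2], [3, 4, 5]]

    def test_full_pattern_valid(self):
        M = tree_to_matrix(three_taxon())
        assert matrix_is_valid(M)[0]


class TestTreeToMatrix:
    def test_cherry_entry(self):
        T = single_link_tree(TreeMatrix(2, {(0, 1): 0.7}, taxa=["A", "B"]))
        M = tree_to_matrix(T)
        assert M[0, 1] == 0.7

    def test_full_pattern_mrca_heights(self):
        M = tree_to_matrix(three_taxon(1.0, 2.0))
        assert (M[0, 1], M[0, 2], M[1, 2]) == (1.0, 2.0, 2.0)

    def test_roundtrip_random_trees(self, rng):
        for _ in range(25):
            T = simulate_yule(12, 5.0, rng)
            T2 = single_link_tree(tree_to_matrix(T))
            assert T2.same_tree(T, atol=1e-12)


class TestCube:
    def test_decode_hand_example(self):
        T = cube_decode(CubeOrdering([0, 1, 2], np.array([1.0, 2.0]), taxa=list("ABC")))
        assert T.newick() == "((A:1,B:1):1,C:2);"

    def test_unreachable_topology(self):
        # ordering (A,B,C) cannot express ((A,C),B) for any heights
        target = single_link_tree(
            TreeMatrix(3, {(0, 2): 1.0, (0, 1): 2.0}, taxa=list("ABC"))
        )
        for h1, h2 in [(1, 2), (2, 1), (0.3, 5)]:
            T = cube_decode(CubeOrdering([0, 1, 2], np.array([h1, h2], float), taxa=list("ABC")))
            assert T.topology_key() != target.topology_key()
        with pytest.raises(IncompatibleOrderingError):
            cube_encode(target, [0, 1, 2])

    def test_encode_decode_identity(self, rng):
        for _ in range(30):
            h = rng.uniform(0.05, 4.0, size=9)
            ordering = CubeOrdering(list(rng.permutation(10)), h)
            T = cube_decode(ordering)
            back = cube_encode(T, ordering.order)
            np.testing.assert_allclose(back.heights, h)

    def test_roundtrip_random_yule_trees(self, rng):
        for _ in range(100):
            T = simulate_yule(20, 6.0, rng)
            ordering = random_compatible_ordering(T, rng)
            assert cube_decode(ordering).same_tree(T, atol=1e-12)

    def test_monotone_in_nonminimal_heights(self, rng):
        # raising the largest gap keeps every merge below it intact
        for _ in range(20):
            h = rng.uniform(0.1, 2.0, size=7)
            ordering = CubeOrdering(list(range(8)), h)
            key = cube_decode(ordering).topology_key()
            h2 = h.copy()
            h2[np.argmax(h2)] *= 3.0
            assert cube_decode(CubeOrdering(list(range(8)), h2)).topology_key() == key


class TestCompatibleOrderings:
    def test_two_taxa_both_orders(self, rng):
        T = single_link_tree(TreeMatrix(2, {(0, 1): 1.5}, taxa=["A", "B"]))
        seen = set()
        for _ in range(50):
            o = random_compatible_ordering(T, rng)
            seen.add(tuple(o.order))
            assert o.heights[0] == 1.5
        assert seen == {(0, 1), (1, 0)}

    def test_three_taxon_orderings_enumerated(self, rng):
        T = three_taxon()
        seen = {tuple(random_compatible_ordering(T, rng).order) for _ in range(400)}
        # ((A,B),C): exactly ABC, BAC, CAB, CBA
        assert seen == {(0, 1, 2), (1, 0, 2), (2, 0, 1), (2, 1, 0)}


class TestTopologyCounts:
    def test_cube_three_taxa_reaches_two_of_three(self):
        assert count_representable_topologies(EntryPattern.cube(3)) == 2
        assert len(enumerate_rooted_topologies(3)) == 3

    def test_first_row_caterpillars(self):
        assert count_representable_topologies(EntryPattern.first_row(4)) == 6  # 3!

    def test_full_pattern_all_topologies(self):
        assert count_representable_topologies(EntryPattern.full(4)) == 15  # (2n-3)!!
        assert len(enumerate_rooted_topologies(4)) == 15

    def test_cube_counts_match_catalan_shift(self):
        # the cube over n taxa reaches the (n-1)-th Catalan number of topologies
        def catalan(k):
            from math import comb
            return comb(2 * k, k) // (k + 1)
        for n in (3, 4, 5):
            assert count_representable_topologies(EntryPattern.cube(n)) == catalan(n - 1)

    def test_refuses_large_problems(self):
        with pytest.raises(ValueError):
            count_representable_topologies(EntryPattern.full(8))
        with pytest.raises(ValueError):
            count_representable_topologies(EntryPattern.full(5))  # 10 entries > 9
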