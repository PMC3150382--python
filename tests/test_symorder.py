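"""Bilateral symmetric distance, greedy pairing, SYM vector, HC-SYM driver.

The deeper checks run the production code against independently coded
oracles: a direct index-by-index summation for B, exhaustive matching
enumeration for the greedy pairing, and a second from-scratch trace of the
whole symOrder procedure (naive nested loops, recursive flips).
"""

import itertools

import numpy as np
import pytest

import hcsym
from hcsym import (DistanceMatrix, HCSymParams, ValidationError,
                   apply_sym_flips, bilateral_symmetric_distance,
                   build_sym_vector, clade_signature, flip_orbit_orders,
                   greedy_symmetric_pairing, hc_sym, leaf_order,
                   linkage_to_tree, order_unpaired, reorder,
                   select_target_nodes, sym_order)
from hcsym.symorder import SymVector

from conftest import random_distance_matrix, random_tree


# ---------------------------------------------------------------- oracles --

def b_oracle(orderL, orderR, dist):
    """Direct index-wise rendering of the defining sum."""
    m, k = len(orderL), min(len(orderL), len(orderR))
    return sum(dist.value(orderL[m - i], orderR[i - 1]) for i in range(1, k + 1))


def sym_order_oracle(tree, dist):
    """From-scratch trace of symOrder at the root; returns the leaf order.

    Coded independently of the library: plain dict/list scans, recursive
    flip decisions.
    """
    lists = tree.leaf_lists()
    L = list(lists[id(tree.root.left)])
    R = list(lists[id(tree.root.right)])
    # greedy pairing by scanning all remaining pairs each round
    unpL, unpR = sorted(L), sorted(R)
    pairs = []
    while unpL and unpR:
        best = None
        for x in unpL:
            for y in unpR:
                cand = (dist.value(x, y), x, y)
                if best is None or cand < best:
                    best = cand
        pairs.append(best)
        unpL.remove(best[1])
        unpR.remove(best[2])
    sym = [x for _, x, _ in reversed(pairs)] + [y for _, _, y in pairs]
    if unpL:
        scored = sorted((np.mean([dist.value(u, x) for _, x, _ in pairs]), u)
                        for u in unpL)
        sym = [u for _, u in reversed(scored)] + sym
    if unpR:
        scored = sorted((np.mean([dist.value(u, y) for _, _, y in pairs]), u)
                        for u in unpR)
        sym = sym + [u for _, u in scored]
    pos = {lab: i + 1 for i, lab in enumerate(sym)}

    def realise(node):
        if node.is_leaf:
            return [node.label]
        left, right = realise(node.left), realise(node.right)
        if np.mean([pos[x] for x in right]) < np.mean([pos[x] for x in left]):
            left, right = right, left
        return left + right

    return realise(tree.root)


# ------------------------------------------------------------------ tests --

class TestBilateralSymmetricDistance:
    def test_single_pair(self):
        dist = DistanceMatrix(["a", "b"], [[0, 0.5], [0.5, 0]])
        assert bilateral_symmetric_distance(["a"], ["b"], dist) == \
            pytest.approx(0.5)

    def test_constant_cross_distances(self):
        n = 6
        vals = np.ones((n, n)) - np.eye(n)
        labels = [f"x{i}" for i in range(3)] + [f"y{i}" for i in range(3)]
        dist = DistanceMatrix(labels, vals)
        assert bilateral_symmetric_distance(labels[:3], labels[3:], dist) == \
            pytest.approx(3.0)

    @pytest.mark.parametrize("m,n,seed", [(4, 4, 0), (5, 2, 1), (1, 6, 2)])
    def test_matches_index_wise_oracle(self, m, n, seed):
        rng = np.random.default_rng(seed)
        dist = random_distance_matrix(m + n, rng)
        L, R = list(dist.labels[:m]), list(dist.labels[m:])
        assert bilateral_symmetric_distance(L, R, dist) == \
            pytest.approx(b_oracle(L, R, dist))

    def test_overlapping_clusters_rejected(self, rng):
        dist = random_distance_matrix(4, rng)
        with pytest.raises(ValidationError):
            bilateral_symmetric_distance(dist.labels[:2], dist.labels[1:], dist)


class TestGreedyPairing:
    def _cross(self, dmat):
        """DistanceMatrix for 2 x-objects and 2 y-objects with given cross block."""
        vals = np.zeros((4, 4))
        for i in range(2):
            for j in range(2):
                vals[i, 2 + j] = vals[2 + j, i] = dmat[i][j]
        vals[0, 1] = vals[1, 0] = 9.0
        vals[2, 3] = vals[3, 2] = 9.0
        return DistanceMatrix(["x1", "x2", "y1", "y2"], vals)

    def test_hand_executed_trace(self):
        dist = self._cross([[4, 1], [2, 3]])
        res = greedy_symmetric_pairing({"x1", "x2"}, {"y1", "y2"}, dist)
        assert res.pairs == (("x1", "y2", 1.0), ("x2", "y1", 2.0))
        assert res.B == pytest.approx(3.0)
        sym = build_sym_vector({"x1", "x2"}, {"y1", "y2"}, dist)
        assert list(sym.order) == ["x2", "x1", "y2", "y1"]

    def test_greedy_beats_or_ties_no_other_perfect_matching_here(self):
        # both perfect matchings: greedy picks {(x1,y2),(x2,y1)} with B=3 < 4+3
        dist = self._cross([[4, 1], [2, 3]])
        res = greedy_symmetric_pairing({"x1", "x2"}, {"y1", "y2"}, dist)
        other_B = dist.value("x1", "y1") + dist.value("x2", "y2")
        assert res.B < other_B

    def test_equal_distances_tie_broken_lexicographically(self):
        dist = self._cross([[1, 1], [1, 1]])
        res = greedy_symmetric_pairing({"x2", "x1"}, {"y2", "y1"}, dist)
        assert res.pairs == (("x1", "y1", 1.0), ("x2", "y2", 1.0))
        assert res.B == pytest.approx(2.0)

    def test_singleton_left_picks_argmin(self, rng):
        dist = random_distance_matrix(5, rng)
        L = {dist.labels[0]}
        R = set(dist.labels[1:])
        res = greedy_symmetric_pairing(L, R, dist)
        assert res.k == 1
        x, y, d = res.pairs[0]
        assert d == pytest.approx(min(dist.value(x, r) for r in R))

    def test_nondecreasing_distances_many_seeds(self):
        """Inner pairs never farther than outer pairs, by construction."""
        for seed in range(300):
            rng = np.random.default_rng(seed)
            m = int(rng.integers(1, 7))
            n = int(rng.integers(1, 7))
            dist = random_distance_matrix(m + n, rng)
            res = greedy_symmetric_pairing(set(dist.labels[:m]),
                                           set(dist.labels[m:]), dist)
            ds = [d for _, _, d in res.pairs]
            assert all(a <= b for a, b in zip(ds, ds[1:]))
            assert res.k == min(m, n)
            assert res.B == pytest.approx(sum(ds))


class TestOrderUnpaired:
    def test_empty_unpaired(self, rng):
        dist = random_distance_matrix(4, rng)
        assert order_unpaired(set(), dist.labels[:2], dist, "left") == []

    def test_mean_distance_placement_left(self):
        # u mean 0.9, v mean 0.2 to core {a}; left side -> v innermost (last)
        vals = np.array([[0.0, 0.9, 0.2],
                         [0.9, 0.0, 0.5],
                         [0.2, 0.5, 0.0]])
        dist = DistanceMatrix(["a", "u", "v"], vals)
        assert order_unpaired({"u", "v"}, ["a"], dist, "left") == ["u", "v"]
        assert order_unpaired({"u", "v"}, ["a"], dist, "right") == ["v", "u"]

    def test_empty_core_rejected(self, rng):
        dist = random_distance_matrix(3, rng)
        with pytest.raises(ValidationError):
            order_unpaired({dist.labels[0]}, [], dist, "left")


class TestBuildSymVector:
    def test_unbalanced_three_one_hand_trace(self):
        # L={a,b,c}, R={z}; min cross pair is (b,z); a,c ranked by d(.,b)
        vals = np.array([
            [0.0, 1.0, 1.0, 5.0],   # a
            [1.0, 0.0, 1.5, 2.0],   # b
            [1.0, 1.5, 0.0, 7.0],   # c
            [5.0, 2.0, 7.0, 0.0],   # z
        ])
        dist = DistanceMatrix(["a", "b", "c", "z"], vals)
        sym = build_sym_vector({"a", "b", "c"}, {"z"}, dist)
        # d(a,b)=1 < d(c,b)=1.5 -> a innermost of the unpaired pair
        assert list(sym.order) == ["c", "a", "b", "z"]

    def test_result_is_permutation(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            m = int(rng.integers(1, 8))
            n = int(rng.integers(1, 8))
            dist = random_distance_matrix(m + n, rng)
            sym = build_sym_vector(set(dist.labels[:m]), set(dist.labels[m:]),
                                   dist)
            assert sorted(sym.order) == sorted(dist.labels)
            assert sym.rank[sym.order[0]] == 1


class TestApplySymFlips:
    def test_identity_when_sym_equals_current_order(self, rng):
        tree, _ = random_tree(9, rng)
        before = leaf_order(tree)
        apply_sym_flips(tree, tree.root, SymVector(tuple(before)))
        assert leaf_order(tree) == before

    def test_reversed_sym_reverses_order(self, rng):
        tree, _ = random_tree(9, rng)
        before = leaf_order(tree)
        apply_sym_flips(tree, tree.root, SymVector(tuple(reversed(before))))
        assert leaf_order(tree) == list(reversed(before))

    def test_mismatched_sym_rejected(self, rng):
        tree, _ = random_tree(5, rng)
        with pytest.raises(ValidationError):
            apply_sym_flips(tree, tree.root, SymVector(("q", "w", "e")))

    def test_flip_decisions_match_recursive_reference(self):
        """Per-node mean-rank rule agrees with an independent recursion."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tree, _ = random_tree(7, rng)
            target = list(rng.permutation(leaf_order(tree)))
            pos = {lab: i + 1 for i, lab in enumerate(target)}

            def realise(node):
                if node.is_leaf:
                    return [node.label]
                l, r = realise(node.left), realise(node.right)
                if np.mean([pos[x] for x in r]) < np.mean([pos[x] for x in l]):
                    l, r = r, l
                return l + r

            expected = realise(tree.root)
            apply_sym_flips(tree, tree.root, SymVector(tuple(target)))
            assert leaf_order(tree) == expected


class TestSymOrder:
    def test_two_leaf_subtree_unchanged(self, two_leaf_dist):
        tree = hcsym.cluster_average_linkage(two_leaf_dist)
        sym_order(tree, tree.root, two_leaf_dist)
        assert leaf_order(tree) == ["a", "b"]

    def test_matches_independent_trace(self):
        """Dual-implementation check of the full symOrder procedure."""
        for seed in range(40):
            rng = np.random.default_rng(seed)
            tree, dist = random_tree(int(rng.integers(3, 9)), rng)
            expected = sym_order_oracle(tree, dist)
            sym_order(tree, tree.root, dist)
            assert leaf_order(tree) == expected

    def test_idempotent_at_root(self):
        for seed in range(15):
            rng = np.random.default_rng(seed)
            tree, dist = random_tree(10, rng)
            sym_order(tree, tree.root, dist)
            once = leaf_order(tree)
            sym_order(tree, tree.root, dist)
            assert leaf_order(tree) == once

    def test_structure_preserved(self, rng):
        tree, dist = random_tree(20, rng)
        sig = clade_signature(tree)
        sym_order(tree, tree.root, dist)
        assert clade_signature(tree) == sig


class TestSelectTargetNodes:
    def test_level_one_unfiltered_is_root(self, rng):
        tree, _ = random_tree(10, rng)
        assert select_target_nodes(tree, HCSymParams(1, 0.0, 0.0)) == [tree.root]

    def test_br_one_requires_exact_balance(self):
        balanced = linkage_to_tree(
            [("a", "b", 1.0), ("c", "d", 1.0), ("a", "c", 2.0)])
        skewed = linkage_to_tree(
            [("a", "b", 1.0), ("a", "c", 2.0), ("a", "d", 3.0)])
        assert select_target_nodes(balanced, HCSymParams(1, 1.0, 0.0)) == \
            [balanced.root]
        assert select_target_nodes(skewed, HCSymParams(1, 1.0, 0.0)) == []

    def test_balanced_16_leaf_level_two_defaults(self):
        # perfect 16-leaf balanced tree: root + both depth-1 nodes pass
        rows = []
        ids = [f"t{i:02d}" for i in range(16)]
        h = 1.0
        groups = [[x] for x in ids]
        while len(groups) > 1:
            nxt = []
            for a, b in zip(groups[::2], groups[1::2]):
                rows.append((a[0], b[0], h))
                nxt.append(a + b)
            groups = nxt
            h += 1.0
        tree = linkage_to_tree(rows)
        sel = select_target_nodes(tree, HCSymParams(level=2))
        assert sel[0] is tree.root
        assert set(sel[1:]) == {tree.root.left, tree.root.right}

    def test_preorder_parents_before_descendants(self, rng):
        tree, _ = random_tree(32, rng)
        sel = select_target_nodes(tree, HCSymParams(level=4, br=0.0, sr=0.0))
        preorder_pos = {id(nd): i for i, nd in enumerate(tree.preorder())}
        positions = [preorder_pos[id(nd)] for nd in sel]
        assert positions == sorted(positions)
        assert sel[0] is tree.root


class TestHCSym:
    def test_level_one_equals_single_sym_order(self, rng):
        tree, dist = random_tree(14, rng)
        expected = tree.copy()
        sym_order(expected, expected.root, dist)
        got = hc_sym(tree, dist, HCSymParams(level=1, br=0.0, sr=0.0))
        assert leaf_order(got) == leaf_order(expected)

    def test_large_sr_excludes_everything(self, rng):
        # caterpillar: every split is 1 vs rest, so min/total < 0.5 throughout
        rows = [("a", "b", 1.0), ("a", "c", 2.0), ("a", "d", 3.0),
                ("a", "e", 4.0)]
        tree = linkage_to_tree(rows)
        dist = random_distance_matrix(5, rng, labels=list("abcde"))
        assert select_target_nodes(tree, HCSymParams(3, 0.0, 0.5)) == []
        got = hc_sym(tree, dist, HCSymParams(level=3, br=0.0, sr=0.5))
        assert leaf_order(got) == leaf_order(tree)

    def test_deterministic_across_runs(self):
        ds = hcsym.make_clustered_data([8, 7, 6], dim=6, separation=3,
                                       noise=1, seed=5)
        dist = hcsym.euclidean_distances(ds.data)
        tree = hcsym.cluster_average_linkage(dist)
        a = hc_sym(tree, dist, HCSymParams(level=2))
        b = hc_sym(tree, dist, HCSymParams(level=2))
        assert leaf_order(a) == leaf_order(b)

    def test_input_tree_untouched(self, rng):
        tree, dist = random_tree(12, rng)
        before = leaf_order(tree)
        hc_sym(tree, dist)
        assert leaf_order(tree) == before

    def test_structure_preserved_many_trees(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            tree, dist = random_tree(int(rng.integers(4, 25)), rng)
            out = hc_sym(tree, dist, HCSymParams(level=3, br=0.0, sr=0.0))
            assert clade_signature(out) == clade_signature(tree)

    def test_output_in_flip_orbit(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tree, dist = random_tree(int(rng.integers(3, 9)), rng)
            out = hc_sym(tree, dist, HCSymParams(level=2, br=0.0, sr=0.0))
            assert tuple(leaf_order(out)) in flip_orbit_orders(tree)

    def test_missing_leaves_in_matrix_rejected(self, rng):
        tree, _ = random_tree(6, rng)
        small = random_distance_matrix(3, rng, labels=list(tree.leaf_ids)[:3])
        with pytest.raises(ValidationError, match="missing"):
            hc_sym(tree, small)

    def test_reorder_returns_log(self, rng):
        tree, dist = random_tree(12, rng)
        out, log = reorder(tree, dist, level=2, br=0.0, sr=0.0)
        assert log and all("B" in e and "pair_distances" in e for e in log)
        assert log[0]["depth"] == 0
        ds = log[0]["pair_distances"]
        assert ds == sorted(ds)
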