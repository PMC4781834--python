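"""Cuts, split tracking, dissociable nodes, iterative extraction, IC curves."""

import math
import warnings

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from oracles import ic_bruteforce, random_distance_matrix
from rfnclust.dissect import (
    ExtractionConfig,
    ICCurve,
    cut,
    cut_subtree,
    dissociable_nodes,
    extract_rfns,
    ic_curve,
    ic_intersection,
    inconsistency,
    track_split,
)
from rfnclust.tree import Dendrogram, average_linkage


def toy3():
    return average_linkage(squareform([0.2, 0.6, 0.8]))


def balanced4():
    """Two tight pairs joining at the root: (0,1)@0.1, (2,3)@0.2, root@0.9."""
    D = np.array(
        [
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.9, 0.9],
            [0.9, 0.9, 0.0, 0.2],
            [0.9, 0.9, 0.2, 0.0],
        ]
    )
    return average_linkage(D)


class TestCut:
    def test_k1_is_everything(self):
        cs = cut(toy3(), 1)
        assert cs.cut_level_k == 1
        assert cs.clusters[0].leaves.tolist() == [0, 1, 2]

    def test_k_equals_n_all_singletons(self):
        cs = cut(toy3(), 3)
        assert sorted(c.size for c in cs.clusters) == [1, 1, 1]

    def test_toy_k2(self):
        cs = cut(toy3(), 2)
        leaf_sets = sorted(c.leaves.tolist() for c in cs.clusters)
        assert leaf_sets == [[0, 1], [2]]

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            cut(toy3(), 0)
        with pytest.raises(ValueError):
            cut(toy3(), 4)

    def test_partitions_leaves_at_every_k(self, rng):
        dend = average_linkage(random_distance_matrix(rng, 20))
        for k in range(1, 21):
            cs = cut(dend, k)
            assert len(cs.clusters) == k
            all_leaves = np.sort(np.concatenate([c.leaves for c in cs.clusters]))
            assert all_leaves.tolist() == list(range(20))


class TestTrackSplit:
    def test_toy_first_split(self):
        dend = toy3()
        mother, a, b = track_split(cut(dend, 1), cut(dend, 2))
        assert mother == dend.root_id
        assert sorted([a.leaves.tolist(), b.leaves.tolist()]) == [[0, 1], [2]]

    def test_every_consecutive_cut_differs_by_one_split(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 31))
            dend = average_linkage(random_distance_matrix(rng, n))
            for k in range(1, n):
                mother, a, b = track_split(cut(dend, k), cut(dend, k + 1))
                union = np.sort(np.concatenate([a.leaves, b.leaves]))
                assert union.tolist() == dend.leaves_under(mother).tolist()

    def test_nonconsecutive_rejected(self):
        dend = toy3()
        with pytest.raises(ValueError):
            track_split(cut(dend, 1), cut(dend, 3))


class TestDissociable:
    def test_all_pass_predicate(self):
        dend = balanced4()
        out = dissociable_nodes(dend, dend.root_id, lambda s, c: True)
        assert len(out) == 3  # every internal node

    def test_size_two_predicate_selects_root_only(self):
        dend = balanced4()
        out = dissociable_nodes(dend, dend.root_id, lambda s, c: s >= 2)
        assert [nd for nd, _, _ in out] == [dend.root_id]

    def test_never_pass_predicate(self):
        dend = balanced4()
        assert dissociable_nodes(dend, dend.root_id, lambda s, c: False) == []


class TestExtractRFNs:
    def test_recovers_three_planted_networks(self):
        """Three distinct correlation blocks plus unconnected background ->
        the blocks come back exactly (ARI 1.0 over planted voxels); background
        fragments fall below s_min and are filtered away."""
        rng = np.random.default_rng(7)
        sizes = [120, 100, 80]
        labels = np.concatenate([np.repeat(np.arange(3), sizes), np.full(30, -1)])
        n = labels.size
        # tight within-block distances; sentinel-far everywhere else
        same = (labels[:, None] == labels[None, :]) & (labels[:, None] >= 0)
        D = np.where(same, 0.4, 9.0).astype(float)
        D += rng.uniform(0, 0.01, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        dend = average_linkage(D)
        cands, log = extract_rfns(dend, ExtractionConfig(k_initial=8, s_min=20, s_max=150))
        pred = np.full(n, -1)
        for c in cands:
            pred[c.leaves] = c.cluster_id
        planted = labels >= 0
        assert adjusted_rand_score(labels[planted], pred[planted]) == 1.0
        assert np.all(pred[planted] >= 0)
        assert log

    def test_oversize_cluster_recut_at_halved_count(self):
        rng = np.random.default_rng(3)
        dend = average_linkage(random_distance_matrix(rng, 60))
        cfg = ExtractionConfig(k_initial=4, s_min=2, s_max=20)
        _, log = extract_rfns(dend, cfg)
        recursed = [r for r in log if r.status == "oversize_recursed"]
        if recursed:  # halved count recorded in the follow-up records
            children = [r for r in log if r.parent_node == recursed[0].node_id]
            assert children and all(r.k_used <= max(2, 4 // 2) for r in children)

    def test_all_small_gives_empty_candidates_nonempty_log(self):
        dend = balanced4()
        cands, log = extract_rfns(dend, ExtractionConfig(k_initial=2, s_min=3, s_max=4))
        assert cands == []
        assert log

    def test_oversize_at_max_depth_emitted_with_warning(self):
        # all-equal distances: no cut can shrink clusters below s_max quickly
        D = np.full((16, 16), 0.5)
        np.fill_diagonal(D, 0.0)
        dend = average_linkage(D)
        cfg = ExtractionConfig(k_initial=2, s_min=1, s_max=3, max_depth=1)
        with pytest.warns(UserWarning, match="oversize"):
            cands, log = extract_rfns(dend, cfg)
        assert any(r.status == "oversize_maxdepth" for r in log)
        covered = np.sort(np.concatenate([c.leaves for c in cands]))
        assert covered.tolist() == list(range(16))  # nothing silently dropped


class TestInconsistency:
    def test_equal_heights_give_zero(self):
        dend = average_linkage(np.full((4, 4), 0.5) - 0.5 * np.eye(4))
        assert inconsistency(dend, dend.root_id) == 0.0

    def test_direct_formula_on_toy(self):
        """Root with internal children at 0.5, 0.4: link set {0.9, 0.5, 0.4},
        IC = (0.9 - 0.6)/std."""
        heights = np.array([0.4, 0.5, 0.9])
        children = np.array([[0, 1], [2, 3], [4, 5]])
        dend = Dendrogram(n_leaves=4, heights=heights, children=children)
        hs = np.array([0.9, 0.5, 0.4])
        expect = (0.9 - hs.mean()) / hs.std(ddof=1)
        assert inconsistency(dend, dend.root_id) == pytest.approx(expect, abs=1e-12)

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 25))
            dend = average_linkage(random_distance_matrix(rng, n))
            for nd in range(n, 2 * n - 1):
                assert inconsistency(dend, nd) == pytest.approx(
                    ic_bruteforce(dend, nd), abs=1e-9
                )

    def test_matches_scipy_inconsistent(self, rng):
        """Cross-check against scipy's depth-2 inconsistency statistics."""
        dend = average_linkage(random_distance_matrix(rng, 20))
        R = sch.inconsistent(dend.to_linkage(), d=2)
        ours = np.array([inconsistency(dend, nd) for nd in range(20, 39)])
        np.testing.assert_allclose(ours, R[:, 3], atol=1e-9)

    def test_leaf_rejected(self):
        with pytest.raises(ValueError):
            inconsistency(toy3(), 0)


class TestICCurve:
    def test_k_max_2_is_root_ic(self):
        dend = balanced4()
        curve = ic_curve(dend, dend.root_id, 2)
        assert curve.k.tolist() == [2]
        assert curve.ic[0] == pytest.approx(inconsistency(dend, dend.root_id))

    def test_length_and_descending_order_cross_check(self, rng):
        dend = average_linkage(random_distance_matrix(rng, 15))
        curve = ic_curve(dend, dend.root_id, 10)
        assert len(curve.k) == 9
        order = dend.removal_order()
        for k, ic in zip(curve.k, curve.ic):
            assert ic == pytest.approx(inconsistency(dend, int(order[k - 2])))


class TestICIntersection:
    def test_parallel_curves_never_cross(self):
        a = ICCurve(k=[2, 3, 4], ic=[3.0, 2.0, 1.0])
        b = ICCurve(k=[2, 3, 4], ic=[4.0, 3.0, 2.0])
        assert ic_intersection(a, b) is None

    def test_first_sign_change(self):
        a = ICCurve(k=[2, 3, 4], ic=[3.0, 2.0, 1.0])
        b = ICCurve(k=[2, 3, 4], ic=[1.0, 2.5, 2.0])
        k_star, ic_star = ic_intersection(a, b)
        assert k_star == 3
        # segments a: 3->2 and b: 1->2.5 cross at t = 0.8 between k=2 and k=3
        assert ic_star == pytest.approx(3.0 + 0.8 * (2.0 - 3.0))

    def test_symmetric_in_arguments(self):
        a = ICCurve(k=[2, 3, 4], ic=[3.0, 2.0, 1.0])
        b = ICCurve(k=[2, 3, 4], ic=[1.0, 2.5, 2.0])
        assert ic_intersection(a, b) == pytest.approx(ic_intersection(b, a))

    def test_disjoint_ranges_rejected(self):
        a = ICCurve(k=[2, 3], ic=[1.0, 2.0])
        b = ICCurve(k=[5, 6], ic=[1.0, 2.0])
        with pytest.raises(ValueError):
            ic_intersection(a, b)


def test_cut_subtree_restricts_to_subtree():
    dend = balanced4()
    left = dend.children_of(dend.root_id)[0]
    cs = cut_subtree(dend, left, 2)
    union = np.sort(np.concatenate([c.leaves for c in cs.clusters]))
    assert union.tolist() == dend.leaves_under(left).tolist()
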