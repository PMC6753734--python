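import numpy as np
import pytest
from scipy.optimize import linprog

import linac_clear as lc

from conftest import random_obb, random_point_mesh, random_rigid_transform


def cube_corners():
    return np.array(
        [[x, y, z] for x in (-0.5, 0.5) for y in (-0.5, 0.5) for z in (-0.5, 0.5)]
    )


def aligned_box(center, half):
    return lc.OBB(np.asarray(center, float), np.eye(3), np.asarray(half, float))


def boxes_overlap_lp(a: lc.OBB, b: lc.OBB) -> bool:
    """Independent convex-intersection oracle: feasibility LP over the 12
    slab constraints of the two boxes."""
    A_ub, b_ub = [], []
    for box in (a, b):
        for i in range(3):
            n = box.axes[i]
            c = float(n @ box.center)
            h = float(box.half_extents[i])
            A_ub.append(n)
            b_ub.append(c + h)
            A_ub.append(-n)
            b_ub.append(h - c)
    res = linprog(
        c=[0.0, 0.0, 0.0],
        A_ub=np.array(A_ub),
        b_ub=np.array(b_ub),
        bounds=[(None, None)] * 3,
        method="highs",
    )
    return res.status == 0


def surface_samples(box: lc.OBB, rng, n=400):
    local = rng.uniform(-1.0, 1.0, size=(n, 3))
    # push each sample to a random face so the hull surface is covered
    face = rng.integers(0, 3, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    local[np.arange(n), face] = sign
    return box.center + (local * box.half_extents) @ box.axes


class TestFitObb:
    def test_unit_cube_corners(self):
        box = lc.fit_obb(cube_corners())
        np.testing.assert_allclose(box.center, 0.0, atol=1e-12)
        np.testing.assert_allclose(sorted(box.half_extents), [0.5] * 3)

    def test_single_point(self):
        box = lc.fit_obb(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(box.center, [1, 2, 3])
        np.testing.assert_allclose(box.half_extents, 0.0)

    def test_collinear_points_zero_extent_axes(self):
        pts = np.array([[t, 0.0, 0.0] for t in np.linspace(-1, 1, 9)])
        box = lc.fit_obb(pts)
        assert np.sum(box.half_extents < 1e-12) == 2
        assert box.contains(pts).all()

    def test_random_cloud_contained_and_volume_bounded(self):
        rng = np.random.default_rng(41)
        pts = rng.normal(size=(1000, 3)) * [3.0, 1.0, 0.3]
        box = lc.fit_obb(pts)
        assert box.contains(pts).all()
        radius = np.linalg.norm(pts - pts.mean(axis=0), axis=1).max()
        volume = np.prod(2.0 * box.half_extents)
        assert volume <= (2.0 * radius) ** 3

    def test_empty_rejected(self):
        with pytest.raises(lc.EmptyMeshError):
            lc.fit_obb(np.zeros((0, 3)))


class TestBuildTree:
    def test_two_vertices_capacity_one(self):
        mesh = lc.TriangleMesh(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        tree = lc.build_obb_tree(mesh, leaf_capacity=1)
        assert not tree.root.is_leaf
        kids = [tree.root.left, tree.root.right]
        assert all(k.is_leaf and k.vertex_indices.size == 1 for k in kids)

    def test_small_mesh_single_leaf(self):
        rng = np.random.default_rng(42)
        mesh = random_point_mesh(rng, 8)
        tree = lc.build_obb_tree(mesh, leaf_capacity=8)
        assert tree.root.is_leaf

    def test_structural_audit_random_mesh(self):
        rng = np.random.default_rng(43)
        mesh = random_point_mesh(rng, 1000, scale=4.0)
        tree = lc.build_obb_tree(mesh, leaf_capacity=8)
        seen = []
        for node in tree.iter_nodes():
            if node.is_leaf:
                seen.append(node.vertex_indices)
                assert node.box.contains(mesh.vertices[node.vertex_indices]).all()
            else:
                assert node.left is not None and node.right is not None
        all_idx = np.concatenate(seen)
        assert all_idx.size == 1000
        np.testing.assert_array_equal(np.sort(all_idx), np.arange(1000))

    def test_child_vertices_inside_parent_box(self):
        rng = np.random.default_rng(44)
        mesh = random_point_mesh(rng, 300, scale=2.0)
        tree = lc.build_obb_tree(mesh, leaf_capacity=4)

        def owned(node):
            if node.is_leaf:
                return node.vertex_indices
            return np.concatenate([owned(node.left), owned(node.right)])

        for node in tree.iter_nodes():
            assert node.box.contains(mesh.vertices[owned(node)]).all()


class TestSeparatingAxis:
    def test_coincident_boxes_overlap(self):
        a = aligned_box((0, 0, 0), (0.5, 0.5, 0.5))
        assert lc.obb_overlap_sat(a, a)

    def test_far_boxes_disjoint(self):
        a = aligned_box((0, 0, 0), (0.5, 0.5, 0.5))
        b = aligned_box((10, 0, 0), (0.5, 0.5, 0.5))
        assert not lc.obb_overlap_sat(a, b)

    def test_agrees_with_lp_oracle(self):
        rng = np.random.default_rng(45)
        n_checked = 0
        for _ in range(500):
            a = random_obb(rng, center_scale=3.0)
            b = random_obb(rng, center_scale=3.0)
            gap = max(0.0, lc.obb_distance_lower_bound(a, b))
            sat = lc.obb_overlap_sat(a, b)
            lp = boxes_overlap_lp(a, b)
            n_checked += 1
            assert sat == lp, f"SAT {sat} vs LP {lp} (gap {gap})"
        assert n_checked >= 500

    def test_sat_consistent_with_lower_bound(self):
        rng = np.random.default_rng(46)
        for _ in range(200):
            a = random_obb(rng)
            b = random_obb(rng)
            bound = lc.obb_distance_lower_bound(a, b)
            if lc.obb_overlap_sat(a, b):
                assert bound == 0.0
            else:
                assert bound > 0.0


class TestDistanceLowerBound:
    def test_overlapping_boxes_zero(self):
        a = aligned_box((0, 0, 0), (1, 1, 1))
        b = aligned_box((0.5, 0, 0), (1, 1, 1))
        assert lc.obb_distance_lower_bound(a, b) == 0.0

    def test_axis_aligned_gap_exact(self):
        a = aligned_box((0, 0, 0), (0.5, 0.5, 0.5))
        b = aligned_box((3, 0, 0), (0.5, 0.5, 0.5))
        assert lc.obb_distance_lower_bound(a, b) == pytest.approx(2.0, abs=1e-12)

    def test_never_exceeds_sampled_distance(self):
        rng = np.random.default_rng(47)
        for _ in range(100):
            a = random_obb(rng, center_scale=4.0)
            b = random_obb(rng, center_scale=4.0)
            bound = lc.obb_distance_lower_bound(a, b)
            sa = surface_samples(a, rng)
            sb = surface_samples(b, rng)
            d2 = ((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1)
            assert bound <= np.sqrt(d2.min()) + 1e-6


class TestTreeMinDistance:
    def test_cubes_match_brute_force(self):
        from linac_clear.meshing import box_mesh

        a = box_mesh((0, 0, 0), (1, 1, 1), 1.0)
        b = box_mesh((3, 0, 0), (1, 1, 1), 1.0)
        ta, tb = lc.build_obb_tree(a, 2), lc.build_obb_tree(b, 2)
        res = lc.tree_min_distance(ta, tb)
        assert res.distance == lc.brute_force_min_distance(a, b)[0] == 2.0

    def test_identical_trees_zero(self):
        rng = np.random.default_rng(48)
        mesh = random_point_mesh(rng, 100)
        tree = lc.build_obb_tree(mesh, 4)
        res = lc.tree_min_distance(tree, lc.build_obb_tree(mesh.copy(), 4))
        assert res.distance == 0.0

    def test_oracle_equivalence_random_pairs(self):
        rng = np.random.default_rng(49)
        pruned = 0
        n_pairs = 50
        for k in range(n_pairs):
            na, nb = rng.integers(20, 500, size=2)
            a = random_point_mesh(rng, int(na), scale=rng.uniform(0.5, 4.0))
            b = random_point_mesh(
                rng, int(nb), scale=rng.uniform(0.5, 4.0),
                offset=rng.uniform(-6, 6, size=3),
            )
            t = random_rigid_transform(rng)
            res = lc.tree_min_distance(
                lc.build_obb_tree(a), lc.build_obb_tree(b), t
            )
            expect, ea, eb = lc.brute_force_min_distance(a, lc.apply_transform(b, t))
            assert res.distance == expect
            assert res.stats.n_primitive_tests <= na * nb
            if res.stats.n_primitive_tests < na * nb:
                pruned += 1
        assert pruned >= 0.95 * n_pairs

    def test_stats_counters_populated(self):
        rng = np.random.default_rng(50)
        a = random_point_mesh(rng, 200)
        b = random_point_mesh(rng, 200, offset=(8, 0, 0))
        res = lc.tree_min_distance(lc.build_obb_tree(a), lc.build_obb_tree(b))
        assert res.stats.n_volume_tests > 0
        assert 0 < res.stats.n_primitive_tests <= 200 * 200

    def test_pruning_efficiency_far_meshes(self):
        rng = np.random.default_rng(51)
        a = random_point_mesh(rng, 1000, scale=5.0)
        b = random_point_mesh(rng, 1000, scale=5.0, offset=(35.0, 0.0, 0.0))
        assert lc.brute_force_min_distance(a, b)[0] >= 20.0
        res = lc.tree_min_distance(lc.build_obb_tree(a), lc.build_obb_tree(b))
        assert res.stats.n_primitive_tests <= 0.01 * 1000 * 1000

    def test_witness_points_realize_distance(self):
        rng = np.random.default_rng(52)
        a = random_point_mesh(rng, 150)
        b = random_point_mesh(rng, 150, offset=(4, 1, 0))
        res = lc.tree_min_distance(lc.build_obb_tree(a), lc.build_obb_tree(b))
        assert np.linalg.norm(res.witness_a - res.witness_b) == pytest.approx(
            res.distance, abs=1e-12
        )


class TestTreeCollision:
    @pytest.fixture()
    def geometry_two_apart(self):
        from linac_clear.meshing import box_mesh

        a = box_mesh((0, 0, 0), (1, 1, 1), 1.0)
        b = box_mesh((3, 0, 0), (1, 1, 1), 1.0)
        return lc.build_obb_tree(a, 2), lc.build_obb_tree(b, 2)

    def test_inside_margin_flags_collision(self, geometry_two_apart):
        ta, tb = geometry_two_apart
        hit, d = lc.tree_collision(ta, tb, margin=5.0)
        assert hit and d < 5.0

    def test_outside_margin_clear(self, geometry_two_apart):
        ta, tb = geometry_two_apart
        hit, d = lc.tree_collision(ta, tb, margin=1.0)
        assert not hit and d == 2.0

    def test_zero_margin_disjoint_is_clear(self, geometry_two_apart):
        ta, tb = geometry_two_apart
        hit, _ = lc.tree_collision(ta, tb, margin=0.0)
        assert not hit

    def test_early_exit_upper_bound(self, geometry_two_apart):
        ta, tb = geometry_two_apart
        hit, d = lc.tree_collision(ta, tb, margin=5.0, early_exit=True)
        assert hit and d < 5.0
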