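import numpy as np
import pytest

import linac_clear as lc


def random_point_mesh(rng, n, scale=1.0, offset=(0.0, 0.0, 0.0), faces=False, name="cloud"):
    """Random vertex cloud (optionally with arbitrary valid faces) for distance tests."""
    verts = rng.uniform(-scale, scale, size=(n, 3)) + np.asarray(offset, float)
    f = np.zeros((0, 3), dtype=np.int64)
    if faces and n >= 3:
        m = max(1, n // 2)
        f = np.stack(
            [rng.choice(n, size=3, replace=False) for _ in range(m)]
        ).astype(np.int64)
    return lc.TriangleMesh(verts, f, name=name)


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2**31 - 1))).as_matrix()
    return lc.RigidTransform(rot, rng.uniform(-5, 5, size=3))


def random_obb(rng, center_scale=5.0, extent_scale=2.0):
    t = random_rigid_transform(rng)
    return lc.OBB(
        rng.uniform(-center_scale, center_scale, size=3),
        t.rotation,
        rng.uniform(0.05, extent_scale, size=3),
    )


@pytest.fixture(scope="session")
def default_head():
    return lc.build_gantry_head_mesh()


@pytest.fixture(scope="session")
def default_head_tree(default_head):
    return lc.build_obb_tree(default_head)


@pytest.fixture(scope="session")
def cuboid_scene():
    return lc.make_scene("calibration_sweep")


@pytest.fixture(scope="session")
def cuboid_structures(cuboid_scene, default_head_tree):
    return lc.SceneStructures(
        body_tree=lc.build_obb_tree(cuboid_scene.body),
        couch_tree=lc.build_obb_tree(cuboid_scene.couch),
        gantry_tree=default_head_tree,
    )


@pytest.fixture(scope="session")
def clear_scene():
    return lc.make_scene("clear_demo")


@pytest.fixture(scope="session")
def clear_structures(clear_scene, default_head_tree):
    return lc.SceneStructures(
        body_tree=lc.build_obb_tree(clear_scene.body),
        couch_tree=lc.build_obb_tree(clear_scene.couch),
        gantry_tree=default_head_tree,
    )
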