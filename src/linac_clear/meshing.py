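"""Internal parametric mesh builders (boxes, lathes, ellipsoids).

These produce plain :class:`~linac_clear.geometry.TriangleMesh` objects with
exactly-welded vertices; they back both the machine model and the synthetic
phantom fixtures.
"""

from __future__ import annotations

import numpy as np

from .geometry import TriangleMesh


def _weld(vertices: np.ndarray, faces: np.ndarray):
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return uniq, inverse.reshape(-1)[faces]


def _grid_face(origin, du, dv, nu, nv, flip=False):
    """A rectangular face subdivided into an nu x nv triangle grid."""
    origin = np.asarray(origin, float)
    du = np.asarray(du, float)
    dv = np.asarray(dv, float)
    iu, iv = np.meshgrid(np.arange(nu + 1), np.arange(nv + 1), indexing="ij")
    verts = (
        origin[None, :]
        + (iu.reshape(-1, 1) / nu) * du[None, :]
        + (iv.reshape(-1, 1) / nv) * dv[None, :]
    )
    idx = np.arange((nu + 1) * (nv + 1)).reshape(nu + 1, nv + 1)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    if flip:
        faces = np.concatenate([np.stack([a, c, b], 1), np.stack([a, d, c], 1)])
    else:
        faces = np.concatenate([np.stack([a, b, c], 1), np.stack([a, c, d], 1)])
    return verts, faces


def box_mesh(center, size, resolution: float = 5.0, name: str = "box") -> TriangleMesh:
    """Axis-aligned box tessellated so edges are at most ``resolution`` cm."""
    center = np.asarray(center, float)
    size = np.asarray(size, float)
    if np.any(size <= 0) or resolution <= 0:
        raise ValueError("box dimensions and resolution must be positive")
    lo = center - size / 2.0
    hi = center + size / 2.0
    n = np.maximum(1, np.ceil(size / resolution).astype(int))
    ex = np.array([size[0], 0, 0])
    ey = np.array([0, size[1], 0])
    ez = np.array([0, 0, size[2]])
    specs = [
        (lo, ey, ez, n[1], n[2], True),   # x = lo face
        ([hi[0], lo[1], lo[2]], ey, ez, n[1], n[2], False),
        (lo, ex, ez, n[0], n[2], False),  # y = lo face
        ([lo[0], hi[1], lo[2]], ex, ez, n[0], n[2], True),
        (lo, ex, ey, n[0], n[1], True),   # z = lo face
        ([lo[0], lo[1], hi[2]], ex, ey, n[0], n[1], False),
    ]
    all_v, all_f = [], []
    offset = 0
    for origin, du, dv, nu, nv, flip in specs:
        v, f = _grid_face(origin, du, dv, int(nu), int(nv), flip)
        all_v.append(v)
        all_f.append(f + offset)
        offset += v.shape[0]
    verts, faces = _weld(np.vstack(all_v), np.vstack(all_f))
    return TriangleMesh(verts, faces, name=name)


def lathe_mesh(
    levels_y,
    radii,
    n_segments: int = 48,
    center_xz=(0.0, 0.0),
    cap_first: bool = True,
    cap_last: bool = True,
    name: str = "lathe",
) -> TriangleMesh:
    """Surface of revolution about a line parallel to +y.

    ``levels_y[i]`` is the y of ring i, ``radii[i]`` its radius in the x-z
    plane.  Optional fan caps close the first/last rings with a center
    vertex.
    """
    levels_y = np.asarray(levels_y, float)
    radii = np.asarray(radii, float)
    if levels_y.ndim != 1 or levels_y.shape != radii.shape or levels_y.size < 2:
        raise ValueError("need matching 1-d levels and radii with >= 2 rings")
    cx, cz = center_xz
    ang = 2.0 * np.pi * np.arange(n_segments) / n_segments
    cos_a, sin_a = np.cos(ang), np.sin(ang)
    verts = []
    for y, r in zip(levels_y, radii):
        ring = np.stack(
            [cx + r * cos_a, np.full(n_segments, y), cz + r * sin_a], axis=1
        )
        verts.append(ring)
    verts = np.vstack(verts)
    faces = []
    for i in range(levels_y.size - 1):
        base0 = i * n_segments
        base1 = (i + 1) * n_segments
        for j in range(n_segments):
            k = (j + 1) % n_segments
            faces.append([base0 + j, base1 + j, base1 + k])
            faces.append([base0 + j, base1 + k, base0 + k])
    extra = []
    if cap_first:
        c0 = verts.shape[0] + len(extra)
        extra.append([cx, levels_y[0], cz])
        for j in range(n_segments):
            faces.append([c0, (j + 1) % n_segments, j])
    if cap_last:
        c1 = verts.shape[0] + len(extra)
        extra.append([cx, levels_y[-1], cz])
        base = (levels_y.size - 1) * n_segments
        for j in range(n_segments):
            faces.append([c1, base + j, base + (j + 1) % n_segments])
    if extra:
        verts = np.vstack([verts, np.asarray(extra, float)])
    return TriangleMesh(verts, np.asarray(faces, np.int64), name=name)


def ellipsoid_mesh(
    center, semi_axes, n_lat: int = 16, n_lon: int = 24, name: str = "ellipsoid"
) -> TriangleMesh:
    """UV-tessellated ellipsoid, poles on the +/- z (superior/inferior) axis."""
    center = np.asarray(center, float)
    semi = np.asarray(semi_axes, float)
    if np.any(semi <= 0):
        raise ValueError("semi axes must be positive")
    verts = [np.array([0.0, 0.0, 1.0])]
    for i in range(1, n_lat):
        theta = np.pi * i / n_lat
        st, ct = np.sin(theta), np.cos(theta)
        phi = 2.0 * np.pi * np.arange(n_lon) / n_lon
        verts.append(np.stack([st * np.cos(phi), st * np.sin(phi), np.full(n_lon, ct)], 1))
    verts.append(np.array([0.0, 0.0, -1.0]))
    verts = np.vstack([v.reshape(-1, 3) for v in verts])
    faces = []
    for j in range(n_lon):  # top fan
        faces.append([0, 1 + j, 1 + (j + 1) % n_lon])
    for i in range(n_lat - 2):
        r0 = 1 + i * n_lon
        r1 = r0 + n_lon
        for j in range(n_lon):
            k = (j + 1) % n_lon
            faces.append([r0 + j, r1 + j, r1 + k])
            faces.append([r0 + j, r1 + k, r0 + k])
    bottom = verts.shape[0] - 1
    rN = 1 + (n_lat - 2) * n_lon
    for j in range(n_lon):
        faces.append([bottom, rN + (j + 1) % n_lon, rN + j])
    verts = verts * semi[None, :] + center[None, :]
    return TriangleMesh(verts, np.asarray(faces, np.int64), name=name)


def cylinder_mesh(
    center, radius: float, height: float, axis: str = "z",
    n_segments: int = 24, name: str = "cylinder",
) -> TriangleMesh:
    """Closed circular cylinder along one coordinate axis."""
    if radius <= 0 or height <= 0:
        raise ValueError("radius and height must be positive")
    mesh = lathe_mesh(
        [-height / 2.0, height / 2.0], [radius, radius],
        n_segments=n_segments, name=name,
    )
    verts = mesh.vertices
    if axis == "y":
        pass
    elif axis == "z":  # lathe axis y -> z
        verts = verts[:, [0, 2, 1]] * np.array([1.0, -1.0, 1.0])
    elif axis == "x":
        verts = verts[:, [1, 0, 2]] * np.array([1.0, 1.0, 1.0])
    else:
        raise ValueError("axis must be one of x, y, z")
    return TriangleMesh(verts + np.asarray(center, float), mesh.faces, name=name)


def concat_meshes(meshes, name: str = "combined") -> TriangleMesh:
    """Concatenate meshes into one multi-component mesh (no welding)."""
    verts, faces, offset = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        offset += m.n_vertices
    return TriangleMesh(np.vstack(verts), np.vstack(faces), name=name)


def mirror_x(mesh: TriangleMesh) -> TriangleMesh:
    """Reflect a mesh through the midsagittal plane (x -> -x), fixing winding."""
    verts = mesh.vertices * np.array([-1.0, 1.0, 1.0])
    faces = mesh.faces[:, [0, 2, 1]]
    return TriangleMesh(verts, faces, name=mesh.name)
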