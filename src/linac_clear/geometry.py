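"""Core mesh and rigid-transform types.

All geometry lives in a fixed patient-based DICOM coordinate frame with the
plan isocenter at the origin: +x patient-left, +y patient-posterior,
+z patient-superior.  Every length in this package is a centimetre.

The minimum clearance between two structures is defined over *vertex pairs*
(the meshes' point clouds), not over triangle surfaces.  This matches how
treatment-planning body contours are used for clearance checks: the reported
distance can overestimate the true surface clearance by up to a local edge
length, which is one reason clearance software is always run with a safety
margin on top.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import trimesh


class GeometryError(ValueError):
    """Base class for geometry-layer errors."""


class EmptyMeshError(GeometryError):
    """An operation that needs vertices received an empty mesh."""


class InvalidTransformError(GeometryError):
    """Rotation matrix is not a proper rotation (orthonormal, det +1)."""


class MeshFormatError(GeometryError):
    """A mesh file could not be parsed."""


class UnsupportedFormatError(GeometryError):
    """Unknown mesh file extension / format."""


_ORTHO_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``v -> rotation @ v + translation`` (cm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(r)) or not np.all(np.isfinite(t)):
            raise InvalidTransformError("non-finite transform components")
        err = np.abs(r @ r.T - np.eye(3)).max()
        if err > 1e-8:
            raise InvalidTransformError(
                f"rotation not orthonormal (max deviation {err:.3g})"
            )
        if np.linalg.det(r) < 0:
            raise InvalidTransformError("rotation has negative determinant")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() <= tol
            and np.abs(self.translation).max() <= tol
        )


@dataclasses.dataclass
class TriangleMesh:
    """Indexed triangle mesh: ``vertices`` (n, 3) float64 cm, ``faces`` (m, 3) int.

    A mesh may carry zero faces (a bare point cloud is a legal degenerate
    input for extent and distance queries); when faces are present, the
    vertex count must be at least 3 and every index in range.
    """

    vertices: np.ndarray
    faces: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros((0, 3), dtype=np.int64)
    )
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(v)):
            raise GeometryError(f"mesh {self.name!r}: non-finite vertex coordinates")
        if f.size:
            if v.shape[0] < 3:
                raise GeometryError(
                    f"mesh {self.name!r}: faces present but fewer than 3 vertices"
                )
            if f.min() < 0 or f.max() >= v.shape[0]:
                raise GeometryError(f"mesh {self.name!r}: face index out of range")
            if (
                np.any(f[:, 0] == f[:, 1])
                or np.any(f[:, 1] == f[:, 2])
                or np.any(f[:, 0] == f[:, 2])
            ):
                raise GeometryError(f"mesh {self.name!r}: face with repeated indices")
        self.vertices = v
        self.faces = f

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    @property
    def is_empty(self) -> bool:
        return self.n_vertices == 0

    def copy(self, name: str | None = None) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.name if name is None else name,
        )


@dataclasses.dataclass(frozen=True)
class Extents:
    """Axis-aligned per-axis bounds, ``min <= max`` componentwise (cm)."""

    min: np.ndarray
    max: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.min, dtype=float).reshape(3)
        hi = np.asarray(self.max, dtype=float).reshape(3)
        if np.any(lo > hi):
            raise GeometryError("extents min exceeds max")
        object.__setattr__(self, "min", lo)
        object.__setattr__(self, "max", hi)

    @property
    def size(self) -> np.ndarray:
        return self.max - self.min

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.min + self.max)


def apply_transform(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    """Return a new mesh with every vertex mapped through ``t``; topology kept."""
    if not isinstance(t, RigidTransform):
        raise InvalidTransformError("expected a RigidTransform")
    return TriangleMesh(t.apply(mesh.vertices), mesh.faces.copy(), mesh.name)


def mesh_extents(mesh: TriangleMesh) -> Extents:
    """Componentwise min/max of the vertex coordinates."""
    if mesh.is_empty:
        raise EmptyMeshError(f"mesh {mesh.name!r} has no vertices")
    return Extents(mesh.vertices.min(axis=0), mesh.vertices.max(axis=0))


# ---------------------------------------------------------------------------
# vertex-pair minimum distance
# ---------------------------------------------------------------------------

def pairwise_sq_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared distances between every row of ``a`` and every row of ``b``.

    Shared by the brute-force scan and the tree traversal's leaf tests so
    both paths produce bit-identical floating-point minima.
    """
    diff = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


_BLOCK = 512  # rows per brute-force block; bounds peak memory at ~2 MB per block pair


def brute_force_min_distance(
    a: TriangleMesh, b: TriangleMesh
) -> tuple[float, int, int]:
    """Exact minimum vertex-pair distance with the argmin pair.

    This is the quadratic point-to-point scan that tree traversal must
    reproduce exactly.  Ties between equidistant pairs are broken by the
    lexicographically smallest ``(index_a, index_b)``.
    """
    if a.is_empty or b.is_empty:
        raise EmptyMeshError("brute_force_min_distance needs two non-empty meshes")
    va, vb = a.vertices, b.vertices
    best = np.inf
    best_ia = best_ib = 0
    for i0 in range(0, va.shape[0], _BLOCK):
        ablk = va[i0 : i0 + _BLOCK]
        for j0 in range(0, vb.shape[0], _BLOCK):
            bblk = vb[j0 : j0 + _BLOCK]
            d2 = pairwise_sq_distances(ablk, bblk)
            flat = int(np.argmin(d2))  # first occurrence = lexicographic min
            m = d2.flat[flat]
            if m < best:  # strict: earlier blocks win ties
                best = float(m)
                best_ia = i0 + flat // d2.shape[1]
                best_ib = j0 + flat % d2.shape[1]
    return float(np.sqrt(best)), best_ia, best_ib


# ---------------------------------------------------------------------------
# mesh file I/O
# ---------------------------------------------------------------------------

_EXT_FORMAT = {".stl": "stl", ".ply": "ply", ".obj": "obj"}


def _resolve_format(path: Path, file_format: str | None) -> str:
    if file_format is not None:
        fmt = file_format.lower()
        if fmt not in {"stl", "stl_ascii", "ply", "obj"}:
            raise UnsupportedFormatError(f"unsupported mesh format {file_format!r}")
        return fmt
    ext = path.suffix.lower()
    if ext not in _EXT_FORMAT:
        raise UnsupportedFormatError(f"unknown mesh extension {ext!r} for {path}")
    return _EXT_FORMAT[ext]


def _weld_exact(vertices: np.ndarray, faces: np.ndarray):
    """Merge bit-identical duplicate vertices (STL stores one copy per facet).

    Exact-coordinate welding keeps the weld independent of any tolerance, so
    the logical vertex set — and therefore every vertex-pair distance — is
    reproducible across platforms.
    """
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return uniq, inverse.reshape(-1)[faces]


def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal OBJ reader for v/f records.

    Handled directly because general OBJ loaders drop vertices that no face
    references, and clearance queries here run over the full vertex cloud.
    Only triangle ``f`` records with plain or slash-qualified indices are
    supported.
    """
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        parts = raw.split()
        if not parts or parts[0].startswith("#"):
            continue
        try:
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(tok.split("/")[0]) for tok in parts[1:]]
                if len(idx) != 3:
                    raise ValueError("non-triangle face")
                faces.append([i - 1 if i > 0 else len(verts) + i for i in idx])
        except (ValueError, IndexError) as exc:
            raise MeshFormatError(f"{path}:{lineno}: bad OBJ record {raw!r}") from exc
    return (
        np.asarray(verts, dtype=float).reshape(-1, 3),
        np.asarray(faces, dtype=np.int64).reshape(-1, 3),
    )


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    lines = [
        f"v {float(x)!r} {float(y)!r} {float(z)!r}" for x, y, z in mesh.vertices
    ]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.faces]
    path.write_text("\n".join(lines) + "\n")


def read_mesh(path, file_format: str | None = None, name: str | None = None) -> TriangleMesh:
    """Read STL (binary or ASCII), PLY, or OBJ into a :class:`TriangleMesh`.

    STL input is welded with an exact-coordinate merge; PLY/OBJ keep their
    stored indexing.
    """
    path = Path(path)
    fmt = _resolve_format(path, file_format)
    if not path.exists():
        raise MeshFormatError(f"no such mesh file: {path}")
    if fmt == "obj":
        vertices, faces = _read_obj(path)
        if vertices.shape[0] == 0:
            raise MeshFormatError(f"{path}: no vertices parsed")
        return TriangleMesh(
            vertices, faces, name=name if name is not None else path.stem
        )
    try:
        loaded = trimesh.load_mesh(
            str(path), file_type="stl" if fmt.startswith("stl") else fmt, process=False
        )
    except Exception as exc:  # noqa: BLE001 - surface parser failures uniformly
        size = path.stat().st_size
        raise MeshFormatError(
            f"failed to parse {path} ({fmt}, {size} bytes): {exc}"
        ) from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: file contains no mesh geometry")
        loaded = trimesh.util.concatenate(geoms)
    vertices = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if vertices.shape[0] == 0:
        raise MeshFormatError(
            f"{path}: no geometry parsed ({path.stat().st_size} bytes; truncated file?)"
        )
    if fmt.startswith("stl"):
        vertices, faces = _weld_exact(vertices, faces)
    return TriangleMesh(vertices, faces, name=name if name is not None else path.stem)


def write_mesh(mesh: TriangleMesh, path, file_format: str | None = None) -> Path:
    """Write a mesh as STL (binary; ``stl_ascii`` for text), PLY (ASCII) or OBJ."""
    path = Path(path)
    fmt = _resolve_format(path, file_format)
    tm = trimesh.Trimesh(
        vertices=mesh.vertices.copy(), faces=mesh.faces.copy(), process=False
    )
    if fmt == "stl":
        data = trimesh.exchange.stl.export_stl(tm)
        path.write_bytes(data)
    elif fmt == "stl_ascii":
        path.write_text(trimesh.exchange.stl.export_stl_ascii(tm))
    elif fmt == "ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    elif fmt == "obj":
        _write_obj(mesh, path)
    return path
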