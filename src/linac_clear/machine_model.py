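"""Parametric linac machine geometry and pose kinematics.

The gantry head is rebuilt parametrically from tape-measure style data: a
casing profile given as (height, circumference) pairs that is linearly
interpolated between measured heights, plus cylindrical face projections
(locking pins, the horseshoe-shaped tray insert).  Only the 14 cm of casing
nearest the face — the part that can actually strike a patient or couch — is
modeled; structures further up the head are deliberately absent, so
clearances larger than the modeled extent are not meaningful.

Pose convention (C-arm linac, IEC-style scales, head-first supine patient):

* patient frame: +x patient-left, +y patient-posterior, +z patient-superior,
  origin at the plan isocenter;
* gantry 0 puts the source anterior (head face center at ``(0, -face_to_iso, 0)``)
  and the gantry angle increases toward patient-left (gantry 90 -> source on
  the patient's left);
* the couch angle rotates the whole machine assembly by ``-couch_deg`` about
  the room-vertical axis while patient and couch meshes stay fixed — the
  patient body is the rigid frame of reference and every rotation is applied
  to the gantry model;
* the collimator spins the head about the beam axis, applied before the
  gantry rotation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .geometry import RigidTransform, TriangleMesh
from .meshing import box_mesh, concat_meshes, lathe_mesh

MACHINE_CONFIG_VERSION = 1


class MachineParameterError(ValueError):
    """Invalid machine geometry parameters."""


@dataclasses.dataclass(frozen=True)
class FaceProjection:
    """A cylindrical boss protruding from the gantry face toward isocenter."""

    name: str
    diameter: float  # cm
    projection: float  # cm toward isocenter
    offset: tuple[float, float] = (0.0, 0.0)  # (x, z) in the face plane
    n_segments: int = 12


def _default_profile() -> tuple[tuple[float, float], ...]:
    # (height behind face, circumference) pairs; schematic C-arm linac head
    return ((0.0, 239.0), (7.0, 248.0), (14.0, 254.0))


def _default_projections() -> tuple[FaceProjection, ...]:
    return (
        FaceProjection("locking_pin_left", 4.0, 2.0, (20.0, 10.0), 12),
        FaceProjection("locking_pin_right", 4.0, 2.0, (-20.0, 10.0), 12),
        FaceProjection("horseshoe_tray_insert", 24.0, 3.0, (0.0, 0.0), 24),
    )


@dataclasses.dataclass(frozen=True)
class GantryHeadParams:
    """Parametric description of the gantry-head collision envelope.

    ``face_to_iso`` is the isocenter-to-face distance at gantry zero; it is
    machine- and configuration-specific and exposed as an adjustable default
    rather than a calibrated constant.  ``target_vertex_count`` steers the
    tessellation density of the rebuilt model.
    """

    casing_length: float = 14.0
    casing_profile: tuple[tuple[float, float], ...] = dataclasses.field(
        default_factory=_default_profile
    )
    face_projections: tuple[FaceProjection, ...] = dataclasses.field(
        default_factory=_default_projections
    )
    face_to_iso: float = 40.0
    target_vertex_count: int = 1639
    n_segments: int = 48

    def __post_init__(self) -> None:
        if self.casing_length <= 0 or self.face_to_iso <= 0:
            raise MachineParameterError("lengths must be positive")
        heights = [h for h, _ in self.casing_profile]
        circs = [c for _, c in self.casing_profile]
        if len(heights) < 2 or any(c <= 0 for c in circs):
            raise MachineParameterError("need >= 2 profile rows with positive circumference")
        if any(b <= a for a, b in zip(heights, heights[1:])):
            raise MachineParameterError("profile heights must be strictly increasing")
        for p in self.face_projections:
            if p.diameter <= 0 or p.projection <= 0:
                raise MachineParameterError(f"projection {p.name!r}: non-positive dims")
            if p.projection >= self.face_to_iso:
                raise MachineParameterError(
                    f"projection {p.name!r} reaches past the isocenter"
                )

    # -- JSON config ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": MACHINE_CONFIG_VERSION,
            "casing_length": self.casing_length,
            "casing_profile": [list(row) for row in self.casing_profile],
            "face_projections": [
                {
                    "name": p.name,
                    "diameter": p.diameter,
                    "projection": p.projection,
                    "offset": list(p.offset),
                    "n_segments": p.n_segments,
                }
                for p in self.face_projections
            ],
            "face_to_iso": self.face_to_iso,
            "target_vertex_count": self.target_vertex_count,
            "n_segments": self.n_segments,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GantryHeadParams":
        version = d.get("version", MACHINE_CONFIG_VERSION)
        if version != MACHINE_CONFIG_VERSION:
            raise MachineParameterError(f"unsupported machine config version {version}")
        return cls(
            casing_length=float(d["casing_length"]),
            casing_profile=tuple(tuple(map(float, row)) for row in d["casing_profile"]),
            face_projections=tuple(
                FaceProjection(
                    name=p["name"],
                    diameter=float(p["diameter"]),
                    projection=float(p["projection"]),
                    offset=tuple(map(float, p.get("offset", (0.0, 0.0)))),
                    n_segments=int(p.get("n_segments", 12)),
                )
                for p in d.get("face_projections", ())
            ),
            face_to_iso=float(d["face_to_iso"]),
            target_vertex_count=int(d.get("target_vertex_count", 1639)),
            n_segments=int(d.get("n_segments", 48)),
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path) -> "GantryHeadParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _face_radius(p: GantryHeadParams) -> float:
    return p.casing_profile[0][1] / (2.0 * np.pi)


def build_gantry_head_mesh(params: GantryHeadParams | None = None) -> TriangleMesh:
    """Rebuild the gantry-head envelope mesh in the canonical (gantry 0) frame.

    The face plane sits at ``y = -face_to_iso`` with the casing extruded away
    from the isocenter; face projections protrude toward the isocenter by
    their projection distance.  Ring count is derived from
    ``target_vertex_count`` so the rebuilt model's density tracks the
    reference model it emulates.
    """
    p = params if params is not None else GantryHeadParams()
    face_r = _face_radius(p)
    for proj in p.face_projections:
        if np.hypot(*proj.offset) + proj.diameter / 2.0 > face_r:
            raise MachineParameterError(
                f"projection {proj.name!r} overlaps the casing boundary"
            )
    overhead = 2 + sum(2 * proj.n_segments + 1 for proj in p.face_projections)
    n_rings = max(2, round((p.target_vertex_count - overhead) / p.n_segments))
    heights = np.linspace(0.0, p.casing_length, n_rings)
    prof_h = np.array([h for h, _ in p.casing_profile])
    prof_c = np.array([c for _, c in p.casing_profile])
    radii = np.interp(heights, prof_h, prof_c) / (2.0 * np.pi)
    # casing: rings march from the face plane away from isocenter (more negative y)
    casing = lathe_mesh(
        -(p.face_to_iso + heights), radii, n_segments=p.n_segments,
        cap_first=True, cap_last=True, name="casing",
    )
    parts = [casing]
    for proj in p.face_projections:
        ox, oz = proj.offset
        boss = lathe_mesh(
            [-p.face_to_iso, -(p.face_to_iso - proj.projection)],
            [proj.diameter / 2.0, proj.diameter / 2.0],
            n_segments=proj.n_segments,
            center_xz=(ox, oz),
            cap_first=False,
            cap_last=True,
            name=proj.name,
        )
        parts.append(boss)
    mesh = concat_meshes(parts, name="gantry_head")
    return mesh


def build_couch_board_mesh(kind: str, dims: dict | None = None) -> TriangleMesh:
    """Couch-side collision structures as cuboid composites.

    ``flat_couch_top`` is a single slab; ``board_with_head_extension`` adds a
    narrower head-extension slab continuing superiorly past the couch top
    (immobilization-board head rest).  The posterior (couch-top) surface sits
    at ``dims['top_y']``.
    """
    d = {
        "width": 50.0,       # x extent
        "length": 120.0,     # z extent of the main slab
        "thickness": 5.0,    # y extent
        "top_y": 10.0,       # y of the surface the patient rests on
        "superior_z": 15.0,  # z of the main slab's superior edge
        "extension": 25.0,   # head-extension length (z) beyond the couch top
        "resolution": 5.0,
    }
    if dims:
        d.update(dims)
    for key in ("width", "length", "thickness", "resolution"):
        if d[key] <= 0:
            raise ValueError(f"couch dimension {key!r} must be positive")
    main = box_mesh(
        center=(
            0.0,
            d["top_y"] + d["thickness"] / 2.0,
            d["superior_z"] - d["length"] / 2.0,
        ),
        size=(d["width"], d["thickness"], d["length"]),
        resolution=d["resolution"],
        name="couch_top",
    )
    if kind == "flat_couch_top":
        main.name = "flat_couch_top"
        return main
    if kind == "board_with_head_extension":
        if d["extension"] <= 0:
            raise ValueError("extension must be positive")
        ext = box_mesh(
            center=(
                0.0,
                d["top_y"] + d["thickness"] / 2.0,
                d["superior_z"] + d["extension"] / 2.0,
            ),
            size=(d["width"] * 0.6, d["thickness"], d["extension"]),
            resolution=d["resolution"],
            name="head_extension",
        )
        return concat_meshes([main, ext], name="board_with_head_extension")
    raise ValueError(f"unknown couch structure kind {kind!r}")


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _rot_y(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _normalize_angle(deg: float, label: str) -> float:
    if not 0.0 <= deg < 360.0:
        norm = float(np.mod(deg, 360.0))
        warnings.warn(
            f"{label} angle {deg} out of [0, 360); normalized to {norm}",
            stacklevel=3,
        )
        return norm
    return float(deg)


@dataclasses.dataclass(frozen=True)
class MachinePose:
    gantry_deg: float
    couch_deg: float
    collimator_deg: float
    transform: RigidTransform


def machine_pose(
    gantry_deg: float,
    couch_deg: float = 0.0,
    collimator_deg: float = 0.0,
    isocenter_shift=None,
) -> MachinePose:
    """Rigid transform placing the canonical head mesh for a machine pose.

    Order of application to the canonical mesh: collimator spin about the
    beam axis, then gantry rotation about the patient superior axis, then the
    couch rotation of the whole machine about room-vertical, then the
    isocenter shift (a pure translation of the machine assembly — the
    patient mesh never moves).
    """
    g = _normalize_angle(gantry_deg, "gantry")
    c = _normalize_angle(couch_deg, "couch")
    k = _normalize_angle(collimator_deg, "collimator")
    shift = np.zeros(3) if isocenter_shift is None else np.asarray(isocenter_shift, float)
    # -couch_deg about room-vertical (-y) == +couch_deg about +y
    rotation = _rot_y(c) @ _rot_z(g) @ _rot_y(k)
    return MachinePose(g, c, k, RigidTransform(rotation, shift))
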