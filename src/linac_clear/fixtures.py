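"""Synthetic phantoms and fully self-contained test scenes.

No external dataset is needed anywhere in the package: these generators
rebuild the two physical validation set-ups as schematic meshes — a cuboid
calibration phantom resting on an immobilization board, and an
anthropomorphic-style upper-body phantom (ellipsoidal head, cylindrical
neck, box chest) — plus engineered demonstration scenes.  Realism is
intentionally geometric rather than anatomical: the validation surface for
this package is oracle equivalence and symmetry of the clearance
computation, not anatomy.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .geometry import TriangleMesh, brute_force_min_distance, write_mesh
from .machine_model import GantryHeadParams, build_couch_board_mesh, build_gantry_head_mesh
from .meshing import box_mesh, concat_meshes, cylinder_mesh, ellipsoid_mesh
from .registration import AddonDatums
from .trajectory import Direction, Plan, PlanBeam, couch_sweep_angles
from .machine_model import machine_pose
from .geometry import apply_transform

SCENARIOS = ("calibration_sweep", "srs_four_isocenters", "collision_demo", "clear_demo")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    kind: str  # cuboid_calibration | upper_body | shoulders_addon
    dims: dict = dataclasses.field(default_factory=dict)
    mesh_resolution: float = 2.0
    lateral_symmetry: bool = True

    def __post_init__(self) -> None:
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be positive")
        if any(v <= 0 for v in self.dims.values() if isinstance(v, (int, float))):
            raise ValueError("phantom dimensions must be positive")


def make_cuboid_phantom(spec: PhantomSpec | None = None) -> tuple[TriangleMesh, TriangleMesh]:
    """Cuboid calibration phantom resting on a board.

    Laterally symmetric about x = 0 with the posterior face on the board
    plane; returns ``(phantom, board)``.  Default dims 30 x 20 x 20 cm
    (LR x AP x SI) tessellated at the requested edge length.
    """
    spec = spec or PhantomSpec("cuboid_calibration")
    d = {"width": 30.0, "ap": 20.0, "length": 20.0, "board_top_y": 10.0}
    d.update(spec.dims)
    phantom = box_mesh(
        center=(0.0, d["board_top_y"] - d["ap"] / 2.0, 0.0),
        size=(d["width"], d["ap"], d["length"]),
        resolution=spec.mesh_resolution,
        name="cuboid_phantom",
    )
    board = build_couch_board_mesh(
        "board_with_head_extension",
        {
            "top_y": d["board_top_y"],
            "superior_z": d["length"] / 2.0 + 5.0,
            "resolution": max(spec.mesh_resolution, 2.0),
        },
    )
    return phantom, board


_SIZE_FACTORS = {"small": 0.9, "medium": 1.0, "large": 1.1}


def make_upper_body_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[TriangleMesh, dict[str, np.ndarray]]:
    """Schematic upper-body phantom: head + neck + shoulders/chest.

    Returns the laterally symmetric mesh and a landmark dictionary including
    ``base_of_skull``, the worst-case inferior isocenter site used in
    clearance validation.  ``dims['size']`` selects small/medium/large
    scaling.
    """
    spec = spec or PhantomSpec("upper_body")
    size = spec.dims.get("size", "medium")
    if size not in _SIZE_FACTORS:
        raise ValueError(f"unknown phantom size {size!r}")
    f = _SIZE_FACTORS[size]
    res = spec.mesh_resolution
    n_lon = max(12, 2 * round(8.0 * np.pi / res))  # even for lateral symmetry
    n_lat = max(8, round(n_lon / 2))
    head_top_z = spec.dims.get("stature_z", 15.0) * f
    head_semi = f * np.array([8.0, 10.0, 11.0])
    head_center = np.array([0.0, 0.0, head_top_z - head_semi[2]])
    head = ellipsoid_mesh(head_center, head_semi, n_lat=n_lat, n_lon=n_lon, name="head")
    neck_h = 6.0 * f
    neck_bottom = head_center[2] - head_semi[2]
    neck = cylinder_mesh(
        (0.0, 2.0 * f, neck_bottom - neck_h / 2.0),
        radius=5.5 * f,
        height=neck_h,
        axis="z",
        n_segments=n_lon,
        name="neck",
    )
    chest_size = f * np.array([40.0, 22.0, 26.0])
    chest_top = neck_bottom - neck_h
    chest = box_mesh(
        center=(0.0, 0.0, chest_top - chest_size[2] / 2.0),
        size=chest_size,
        resolution=res,
        name="chest",
    )
    mesh = concat_meshes([head, neck, chest], name=f"upper_body_{size}")
    landmarks = {
        "base_of_skull": np.array([0.0, 2.0 * f, neck_bottom]),
        "head_top": np.array([0.0, 0.0, head_top_z]),
        "chest_inferior": np.array([0.0, 0.0, chest_top - chest_size[2]]),
    }
    return mesh, landmarks


def make_shoulders_addon(
    spec: PhantomSpec | None = None,
) -> tuple[TriangleMesh, AddonDatums]:
    """Shoulder/chest slab used to extend a head-only contour inferiorly.

    Built with its superior mating face at z = 0 and declared datums, ready
    for ``auto_register(mode="body_addition")``.
    """
    spec = spec or PhantomSpec("shoulders_addon")
    d = {"width": 44.0, "ap": 24.0, "length": 30.0}
    d.update(spec.dims)
    mesh = box_mesh(
        center=(0.0, 0.0, -d["length"] / 2.0),
        size=(d["width"], d["ap"], d["length"]),
        resolution=spec.mesh_resolution,
        name="shoulders_addon",
    )
    datums = AddonDatums(posterior_y=d["ap"] / 2.0, midline_x=0.0, superior_z=0.0)
    return mesh, datums


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Scene:
    """A complete, self-describing test scene."""

    name: str
    seed: int
    body: TriangleMesh
    couch: TriangleMesh
    machine: GantryHeadParams
    plans: list[Plan]
    landmarks: dict = dataclasses.field(default_factory=dict)
    manifest: dict = dataclasses.field(default_factory=dict)


def _full_arc_beam(beam_id: str, couch_deg: float, shift=(0.0, 0.0, 0.0)) -> PlanBeam:
    return PlanBeam(
        beam_id=beam_id,
        couch_deg=couch_deg,
        gantry_start_deg=0.0,
        gantry_stop_deg=355.0,
        rotation_direction=Direction.CW,
        isocenter_shift=tuple(shift),
    )


def make_scene(scenario_name: str, seed: int = 0) -> Scene:
    """Deterministically build one of the named scenarios.

    ``calibration_sweep``: cuboid phantom, 13 couch angles (90..270 by 15)
    each swept on the 5-degree gantry lattice, laterally symmetric isocenter.
    ``srs_four_isocenters``: upper-body phantom with the four
    anterior/posterior x left/right isocenter shifts at the base of skull.
    ``collision_demo``: a phantom engineered (and verified by brute force)
    to touch the gantry face at gantry zero.  ``clear_demo``: a small,
    distant phantom whose plan is entirely collision-free.
    """
    if scenario_name not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_name!r}")
    machine = GantryHeadParams()
    manifest = {"scenario": scenario_name, "seed": int(seed)}

    if scenario_name == "calibration_sweep":
        phantom, board = make_cuboid_phantom()
        beams = [
            _full_arc_beam(f"couch_{int(c):03d}", c) for c in couch_sweep_angles()
        ]
        plans = [Plan(plan_id="calibration_sweep", beams=beams)]
        manifest["n_couch_angles"] = len(beams)
        return Scene(scenario_name, seed, phantom, board, machine, plans, {}, manifest)

    if scenario_name == "srs_four_isocenters":
        body, landmarks = make_upper_body_phantom()
        board = build_couch_board_mesh(
            "board_with_head_extension",
            {"top_y": float(body.vertices[:, 1].max()), "superior_z": 18.0},
        )
        base = landmarks["base_of_skull"]
        plans = []
        for dx, tag_x in ((-2.0, "right"), (2.0, "left")):
            for dy, tag_y in ((-2.0, "ant"), (2.0, "post")):
                shift = (base[0] + dx, base[1] + dy, base[2])
                plans.append(
                    Plan(
                        plan_id=f"{tag_x}_{tag_y}",
                        isocenter_shift=shift,
                        beams=[
                            _full_arc_beam(f"{tag_x}_{tag_y}_c{int(c):03d}", c, shift)
                            for c in couch_sweep_angles()
                        ],
                    )
                )
        manifest["isocenters"] = [p.plan_id for p in plans]
        return Scene(scenario_name, seed, body, board, machine, plans, landmarks, manifest)

    if scenario_name == "collision_demo":
        # anterior face of the phantom reaches exactly the gantry face plane,
        # with a shared lattice point at (0, -face_to_iso, 0)
        f = machine.face_to_iso
        body = box_mesh(
            center=(0.0, (10.0 - f) / 2.0, 0.0),
            size=(20.0, f + 10.0, 20.0),
            resolution=5.0,
            name="collision_phantom",
        )
        board = build_couch_board_mesh("flat_couch_top", {"top_y": 10.0, "superior_z": 15.0})
        head = build_gantry_head_mesh(machine)
        posed = apply_transform(head, machine_pose(0.0, 0.0, 0.0).transform)
        touch, _, _ = brute_force_min_distance(body, posed)
        if touch != 0.0:
            raise AssertionError(
                f"collision_demo construction failed: contact distance {touch}"
            )
        plans = [
            Plan(
                plan_id="collision_demo",
                beams=[
                    PlanBeam(
                        beam_id="arc_through_contact",
                        couch_deg=0.0,
                        gantry_start_deg=350.0,
                        gantry_stop_deg=10.0,
                        rotation_direction=Direction.CW,
                    )
                ],
            )
        ]
        manifest["verified_contact_distance_cm"] = touch
        return Scene(scenario_name, seed, body, board, machine, plans, {}, manifest)

    # clear_demo
    body = box_mesh(center=(0.0, 5.0, 0.0), size=(10.0, 10.0, 10.0),
                    resolution=2.5, name="clear_phantom")
    # compact board: corners stay well inside the head's swept annulus, so
    # every pose clears the margin at any couch angle
    board = build_couch_board_mesh(
        "flat_couch_top",
        {"width": 30.0, "length": 30.0, "thickness": 3.0,
         "top_y": 10.0, "superior_z": 10.0},
    )
    plans = [
        Plan(
            plan_id="clear_demo",
            beams=[
                _full_arc_beam("c000", 0.0),
                _full_arc_beam("c045", 45.0),
                _full_arc_beam("c315", 315.0),
            ],
        )
    ]
    return Scene(scenario_name, seed, body, board, machine, plans, {}, manifest)


def write_scene(scene: Scene, out_dir) -> dict:
    """Write scene meshes (STL), machine.json, plan JSON files and a manifest.

    Output bytes are a pure function of the scene, so identical seeds give
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    write_mesh(scene.body, out_dir / "body.stl")
    files["body"] = "body.stl"
    write_mesh(scene.couch, out_dir / "couch.stl")
    files["couch"] = "couch.stl"
    scene.machine.save(out_dir / "machine.json")
    files["machine"] = "machine.json"
    plan_files = []
    for plan in scene.plans:
        fname = f"plan_{plan.plan_id}.json"
        plan.save(out_dir / fname)
        plan_files.append(fname)
    files["plans"] = plan_files
    manifest = dict(scene.manifest)
    manifest.update(
        {
            "scene": scene.name,
            "seed": scene.seed,
            "files": files,
            "landmarks": {k: [float(x) for x in v] for k, v in scene.landmarks.items()},
        }
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
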