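"""Extremal-coordinate placement of auxiliary structures on the body contour.

Cranial planning scans often cover only chin-to-crown, while most gantry
strikes happen at the shoulders or chest, and clinical couch contours can be
too coarse for a clearance check.  This module positions library add-on
meshes (shoulder/upper-body phantoms, detailed couch/immobilization boards)
against the patient body contour using only extremal coordinates:

* anterior-posterior: the add-on's declared posterior datum is moved to the
  body's posterior extreme;
* left-right: the add-on's lateral midline datum is moved to the midpoint of
  the body's lateral extremes;
* superior-inferior: for a body addition, the add-on's superior face meets
  the body's inferior extreme (extending a head-only scan inferiorly); for a
  couch structure, the add-on's superior extreme is placed at the body's
  superior extreme minus a configurable head offset.

Registration is translation-only and deterministic; a numeric manual offset
replaces interactive adjustment.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .geometry import (
    EmptyMeshError,
    RigidTransform,
    TriangleMesh,
    apply_transform,
    mesh_extents,
    read_mesh,
)

MODES = ("body_addition", "couch_structure")


class RegistrationError(ValueError):
    """Missing datums or invalid registration inputs."""


@dataclasses.dataclass(frozen=True)
class AddonDatums:
    """Reference coordinates on the add-on, in the add-on's own frame (cm).

    ``posterior_y``: y of the surface meant to coincide with the body's
    posterior extreme.  ``midline_x``: x of the lateral symmetry line.
    ``superior_z``: z of the superior mating face (body additions) or of the
    superior extreme (couch structures).
    """

    posterior_y: float
    midline_x: float
    superior_z: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AddonDatums":
        return cls(
            posterior_y=float(d["posterior_y"]),
            midline_x=float(d["midline_x"]),
            superior_z=float(d["superior_z"]),
        )


@dataclasses.dataclass
class RegistrationResult:
    transform: RigidTransform
    aligned_structure: TriangleMesh
    mode: str


def _overlap_warning(body: TriangleMesh, aligned: TriangleMesh, tolerance: float) -> None:
    """Warn when the aligned add-on's bounds cut into the body's bounds.

    Extent overlap is a proxy check (vertex clouds cannot detect true
    surface interpenetration); the workflow allows a manual offset to fix
    an unsatisfactory placement.
    """
    be = mesh_extents(body)
    ae = mesh_extents(aligned)
    depth = np.minimum(be.max, ae.max) - np.maximum(be.min, ae.min)
    if np.all(depth > tolerance):
        warnings.warn(
            f"registered add-on {aligned.name!r} overlaps body bounds by "
            f"{depth.min():.2f} cm; consider a manual offset",
            stacklevel=3,
        )


def auto_register(
    body: TriangleMesh,
    addon: TriangleMesh,
    mode: str,
    datums: AddonDatums | None = None,
    *,
    head_offset: float = 0.0,
    overlap_tolerance: float = 0.5,
) -> RegistrationResult:
    """Translation-only alignment of an add-on to the body contour extremes."""
    if body.is_empty or addon.is_empty:
        raise EmptyMeshError("auto_register needs non-empty meshes")
    if mode not in MODES:
        raise RegistrationError(f"unknown registration mode {mode!r}")
    if datums is None:
        raise RegistrationError(
            f"add-on {addon.name!r} carries no datums; declare posterior/midline/superior references"
        )
    be = mesh_extents(body)
    ty = be.max[1] - datums.posterior_y
    tx = 0.5 * (be.min[0] + be.max[0]) - datums.midline_x
    if mode == "body_addition":
        tz = be.min[2] - datums.superior_z
    else:
        tz = (be.max[2] - head_offset) - datums.superior_z
    transform = RigidTransform.from_translation((tx, ty, tz))
    aligned = apply_transform(addon, transform)
    if mode == "body_addition":
        _overlap_warning(body, aligned, overlap_tolerance)
    return RegistrationResult(transform=transform, aligned_structure=aligned, mode=mode)


def apply_manual_offset(result: RegistrationResult, offset) -> RegistrationResult:
    """Compose a numeric translation on top of an existing registration."""
    off = np.asarray(offset, float).reshape(3)
    if not np.all(np.isfinite(off)):
        raise RegistrationError("manual offset must be finite")
    shift = RigidTransform.from_translation(off)
    return RegistrationResult(
        transform=shift @ result.transform,
        aligned_structure=apply_transform(result.aligned_structure, shift),
        mode=result.mode,
    )


# ---------------------------------------------------------------------------
# add-on library (mesh files + JSON sidecars)
# ---------------------------------------------------------------------------

def save_addon(
    mesh: TriangleMesh, datums: AddonDatums, mode: str, directory, stem: str
) -> tuple[Path, Path]:
    """Store an add-on in a library directory for subsequent reuse."""
    from .geometry import write_mesh

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mesh_path = write_mesh(mesh, directory / f"{stem}.stl")
    sidecar = directory / f"{stem}.json"
    sidecar.write_text(
        json.dumps({"mode": mode, "datums": datums.to_dict()}, indent=2) + "\n"
    )
    return mesh_path, sidecar


def load_addon(mesh_path) -> tuple[TriangleMesh, AddonDatums, str]:
    """Load an add-on mesh plus its JSON sidecar (datums and default mode)."""
    mesh_path = Path(mesh_path)
    sidecar = mesh_path.with_suffix(".json")
    if not sidecar.exists():
        raise RegistrationError(f"add-on {mesh_path.name} has no datum sidecar")
    meta = json.loads(sidecar.read_text())
    return (
        read_mesh(mesh_path),
        AddonDatums.from_dict(meta["datums"]),
        meta.get("mode", "couch_structure"),
    )
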