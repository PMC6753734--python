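"""Arc sampling, per-beam clearance simulation, and risk classification.

A treatment beam is simulated by stepping the gantry in fixed angular
increments (default 5 degrees) from its start control point to its stop
control point, posing the gantry-head model at each step, and recording the
minimum vertex-pair distance to the patient body and to the couch structures
separately.  A beam is a "Collision Risk" when its minimum predicted
clearance is strictly below the safety margin (default 5 cm) and a "Near
Collision Risk" when the clearance lies within 10 cm above the margin.

Discrete sampling means between-sample collisions are not detected; that
residual risk is part of what the safety margin absorbs.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import time
from pathlib import Path

import numpy as np

from .geometry import TriangleMesh, apply_transform, write_mesh
from .machine_model import machine_pose
from .obbtree import OBBTree, tree_min_distance

logger = logging.getLogger(__name__)

DEFAULT_MARGIN_CM = 5.0
DEFAULT_STEP_DEG = 5.0
NEAR_BAND_CM = 10.0

_ANGLE_DECIMALS = 9  # snap sampled angles to avoid float lattice drift


class RiskLabel(str, enum.Enum):
    COLLISION = "CollisionRisk"
    NEAR_COLLISION = "NearCollisionRisk"
    CLEAR = "Clear"


class Direction(str, enum.Enum):
    CW = "CW"    # increasing gantry angle (mod 360)
    CCW = "CCW"  # decreasing gantry angle (mod 360)


@dataclasses.dataclass(frozen=True)
class PlanBeam:
    beam_id: str
    couch_deg: float
    gantry_start_deg: float
    gantry_stop_deg: float
    collimator_deg: float = 0.0
    rotation_direction: Direction = Direction.CW
    static: bool = False
    isocenter_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.static and self.gantry_start_deg % 360.0 == self.gantry_stop_deg % 360.0:
            raise ValueError(
                f"beam {self.beam_id!r}: zero-length arc without the static flag"
            )


@dataclasses.dataclass
class Plan:
    plan_id: str
    beams: list[PlanBeam]
    isocenter_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def to_dict(self) -> dict:
        return {
            "plan_id": self.plan_id,
            "isocenter_shift": list(self.isocenter_shift),
            "beams": [
                {
                    "beam_id": b.beam_id,
                    "couch_deg": b.couch_deg,
                    "collimator_deg": b.collimator_deg,
                    "gantry_start_deg": b.gantry_start_deg,
                    "gantry_stop_deg": b.gantry_stop_deg,
                    "rotation_direction": b.rotation_direction.value,
                    "static": b.static,
                    "isocenter_shift": list(b.isocenter_shift),
                }
                for b in self.beams
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Plan":
        plan_shift = tuple(d.get("isocenter_shift", (0.0, 0.0, 0.0)))
        return cls(
            plan_id=str(d["plan_id"]),
            isocenter_shift=plan_shift,
            beams=[
                PlanBeam(
                    beam_id=str(b["beam_id"]),
                    couch_deg=float(b["couch_deg"]),
                    collimator_deg=float(b.get("collimator_deg", 0.0)),
                    gantry_start_deg=float(b["gantry_start_deg"]),
                    gantry_stop_deg=float(b["gantry_stop_deg"]),
                    rotation_direction=Direction(b.get("rotation_direction", "CW")),
                    static=bool(b.get("static", False)),
                    isocenter_shift=tuple(b.get("isocenter_shift", plan_shift)),
                )
                for b in d["beams"]
            ],
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path) -> "Plan":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass(frozen=True)
class ClearanceSample:
    couch_deg: float
    gantry_deg: float
    min_distance: float
    witness_patient: np.ndarray
    witness_gantry: np.ndarray
    against: str  # "body" or "couch"


@dataclasses.dataclass
class BeamResult:
    beam_id: str
    samples: list[ClearanceSample]
    overall_min: ClearanceSample
    risk_label: RiskLabel
    margin_cm: float
    runtime_s: float = 0.0

    def table_rows(self) -> list[dict]:
        s = self.overall_min
        return [
            {
                "beam_id": self.beam_id,
                "couch_deg": s.couch_deg,
                "gantry_deg_at_min": s.gantry_deg,
                "min_distance_cm": s.min_distance,
                "against": s.against,
                "risk_label": self.risk_label.value,
            }
        ]


@dataclasses.dataclass
class PlanResult:
    plan_id: str
    beam_results: list[BeamResult]
    errors: dict[str, str]

    @property
    def safe(self) -> bool:
        return not any(
            r.risk_label is RiskLabel.COLLISION for r in self.beam_results
        )

    def summary_rows(self) -> list[dict]:
        rows = []
        for r in self.beam_results:
            rows.extend(r.table_rows())
        return rows


@dataclasses.dataclass
class SceneStructures:
    """Collision-check inputs: body and couch trees plus the canonical gantry tree."""

    body_tree: OBBTree
    couch_tree: OBBTree | None
    gantry_tree: OBBTree


def sample_arc(
    start_deg: float,
    stop_deg: float,
    direction: Direction | str = Direction.CW,
    step_deg: float = DEFAULT_STEP_DEG,
    *,
    static: bool = False,
) -> list[float]:
    """Gantry angles along an arc: the start-anchored step lattice plus the stop.

    Both control points are always included (they are physical limits of
    travel), angles wrap through 0/360 along the travel direction, and the
    sequence is monotone along that direction.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    direction = Direction(direction)
    start = float(np.mod(start_deg, 360.0))
    stop = float(np.mod(stop_deg, 360.0))
    if start == stop:
        if not static:
            raise ValueError("zero-length arc without the static flag")
        return [start]
    sweep = (stop - start) % 360.0 if direction is Direction.CW else (start - stop) % 360.0
    n_steps = int(np.floor(sweep / step_deg + 1e-9))
    sign = 1.0 if direction is Direction.CW else -1.0
    angles = [
        float(np.round(np.mod(start + sign * k * step_deg, 360.0), _ANGLE_DECIMALS))
        for k in range(n_steps + 1)
    ]
    if angles[-1] != stop:
        angles.append(stop)
    return angles


def classify_risk(
    min_distance_cm: float,
    margin_cm: float = DEFAULT_MARGIN_CM,
    near_band_cm: float = NEAR_BAND_CM,
) -> RiskLabel:
    """Collision below the margin (strict); near-collision within the band above it.

    The band is half-open: a clearance of exactly ``margin + near_band`` is
    already Clear.
    """
    if min(min_distance_cm, margin_cm, near_band_cm) < 0:
        raise ValueError("distances and margins must be non-negative")
    if min_distance_cm < margin_cm:
        return RiskLabel.COLLISION
    if min_distance_cm < margin_cm + near_band_cm:
        return RiskLabel.NEAR_COLLISION
    return RiskLabel.CLEAR


def couch_sweep_angles(
    start_deg: float = 90.0, stop_deg: float = 270.0, step_deg: float = 15.0
) -> list[float]:
    """The standard validation couch sweep: 90..270 in 15-degree steps, 13 angles."""
    n = int(round((stop_deg - start_deg) / step_deg))
    return [start_deg + k * step_deg for k in range(n + 1)]


def _pose_clearances(
    gantry_deg: float,
    couch_deg: float,
    collimator_deg: float,
    isocenter_shift,
    structures: SceneStructures,
) -> list[ClearanceSample]:
    pose = machine_pose(gantry_deg, couch_deg, collimator_deg, isocenter_shift)
    samples = []
    targets = [("body", structures.body_tree)]
    if structures.couch_tree is not None:
        targets.append(("couch", structures.couch_tree))
    for label, target_tree in targets:
        res = tree_min_distance(target_tree, structures.gantry_tree, pose.transform)
        samples.append(
            ClearanceSample(
                couch_deg=couch_deg,
                gantry_deg=gantry_deg,
                min_distance=res.distance,
                witness_patient=res.witness_a,
                witness_gantry=res.witness_b,
                against=label,
            )
        )
    return samples


def test_beam(
    beam: PlanBeam,
    structures: SceneStructures,
    margin_cm: float = DEFAULT_MARGIN_CM,
    step_deg: float = DEFAULT_STEP_DEG,
) -> BeamResult:
    """Sweep one beam's gantry arc and classify its minimum clearance.

    Body and couch are tested as separate targets with separate witnesses;
    the overall minimum is taken across both.  Ties in the minimum are
    broken by the earliest position along the travel direction (body before
    couch at the same pose).
    """
    if structures.body_tree is None or structures.gantry_tree is None:
        missing = "body" if structures.body_tree is None else "gantry"
        raise ValueError(f"missing structure tree: {missing}")
    if margin_cm < 0:
        raise ValueError("margin must be non-negative")
    t0 = time.perf_counter()
    angles = sample_arc(
        beam.gantry_start_deg,
        beam.gantry_stop_deg,
        beam.rotation_direction,
        step_deg,
        static=beam.static,
    )
    samples: list[ClearanceSample] = []
    overall: ClearanceSample | None = None
    for gantry_deg in angles:
        for sample in _pose_clearances(
            gantry_deg, beam.couch_deg, beam.collimator_deg,
            beam.isocenter_shift, structures,
        ):
            samples.append(sample)
            if overall is None or sample.min_distance < overall.min_distance:
                overall = sample
    runtime = time.perf_counter() - t0
    result = BeamResult(
        beam_id=beam.beam_id,
        samples=samples,
        overall_min=overall,
        risk_label=classify_risk(overall.min_distance, margin_cm),
        margin_cm=margin_cm,
        runtime_s=runtime,
    )
    logger.info(
        "beam %s: %d poses, min %.2f cm (%s) -> %s in %.2f s",
        beam.beam_id, len(angles), overall.min_distance,
        overall.against, result.risk_label.value, runtime,
    )
    return result


def test_plan(
    plan: Plan,
    structures: SceneStructures,
    margin_cm: float = DEFAULT_MARGIN_CM,
    step_deg: float = DEFAULT_STEP_DEG,
) -> PlanResult:
    """Test every beam; a plan is unsafe if any beam is a Collision Risk.

    Per-beam failures are collected and reported while the remaining beams
    are still tested.
    """
    if not plan.beams:
        raise ValueError("plan has no beams")
    results, errors = [], {}
    for beam in plan.beams:
        try:
            results.append(test_beam(beam, structures, margin_cm, step_deg))
        except Exception as exc:  # noqa: BLE001 - keep testing remaining beams
            errors[beam.beam_id] = str(exc)
    return PlanResult(plan_id=plan.plan_id, beam_results=results, errors=errors)


def max_gantry_range(
    couch_deg: float,
    isocenter_shift,
    structures: SceneStructures,
    margin_cm: float = DEFAULT_MARGIN_CM,
    step_deg: float = DEFAULT_STEP_DEG,
    collimator_deg: float = 0.0,
) -> list[tuple[float, float]]:
    """Maximal collision-free gantry intervals on the full angular lattice.

    Scans every lattice angle in [0, 360) at the given couch angle and
    returns maximal circularly-contiguous runs where the clearance is at
    least the margin, each as ``(start, stop)`` along clockwise travel.  An
    empty list means no safe angle exists.
    """
    n = int(round(360.0 / step_deg))
    lattice = [float(np.round(k * step_deg, _ANGLE_DECIMALS)) for k in range(n)]
    safe = []
    for g in lattice:
        clearances = _pose_clearances(
            g, couch_deg, collimator_deg, isocenter_shift, structures
        )
        safe.append(min(s.min_distance for s in clearances) >= margin_cm)
    if all(safe):
        return [(lattice[0], lattice[-1])]
    if not any(safe):
        return []
    # rotate so the scan starts just after an unsafe angle; runs cannot wrap
    start = next(i for i in range(n) if not safe[i])
    intervals = []
    run_start = None
    for k in range(1, n + 1):
        i = (start + k) % n
        if safe[i] and run_start is None:
            run_start = lattice[i]
        elif not safe[i] and run_start is not None:
            intervals.append((run_start, lattice[(start + k - 1) % n]))
            run_start = None
    return sorted(intervals)


def export_scene(
    beam_result: BeamResult,
    body: TriangleMesh,
    couch: TriangleMesh | None,
    gantry_head: TriangleMesh,
    out_dir,
    pose_selector: str | tuple[float, float] = "min",
) -> dict:
    """Write the posed scene meshes plus a JSON manifest for external viewing.

    ``pose_selector`` is "min" (the beam's closest pose) or an explicit
    ``(couch_deg, gantry_deg)`` pair present in the beam's samples.  The
    manifest records the witness segment endpoints and the clearance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if pose_selector == "min":
        sample = beam_result.overall_min
    else:
        couch_deg, gantry_deg = pose_selector
        matches = [
            s
            for s in beam_result.samples
            if s.couch_deg == couch_deg and s.gantry_deg == gantry_deg
        ]
        if not matches:
            raise ValueError(f"pose {pose_selector} not present in beam samples")
        sample = min(matches, key=lambda s: s.min_distance)
    pose = machine_pose(sample.gantry_deg, sample.couch_deg, 0.0)
    posed_gantry = apply_transform(gantry_head, pose.transform)
    write_mesh(body, out_dir / "body.stl")
    if couch is not None:
        write_mesh(couch, out_dir / "couch.stl")
    write_mesh(posed_gantry, out_dir / "gantry.stl")
    manifest = {
        "beam_id": beam_result.beam_id,
        "couch_deg": sample.couch_deg,
        "gantry_deg": sample.gantry_deg,
        "min_distance_cm": sample.min_distance,
        "against": sample.against,
        "witness_patient": [float(x) for x in sample.witness_patient],
        "witness_gantry": [float(x) for x in sample.witness_gantry],
        "risk_label": beam_result.risk_label.value,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
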