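import json

import numpy as np
import pytest

import linac_clear as lc
from linac_clear.meshing import box_mesh
from linac_clear.trajectory import Direction


class TestSampleArc:
    def test_simple_cw_arc(self):
        assert lc.sample_arc(0, 15, "CW", 5) == [0, 5, 10, 15]

    def test_cw_wraparound(self):
        assert lc.sample_arc(350, 10, "CW", 5) == [350, 355, 0, 5, 10]

    def test_ccw_off_lattice_endpoint_appended(self):
        assert lc.sample_arc(10, 3, "CCW", 5) == [10, 5, 3]

    def test_static_beam_single_angle(self):
        assert lc.sample_arc(90, 90, "CW", 5, static=True) == [90]

    def test_zero_length_without_static_rejected(self):
        with pytest.raises(ValueError):
            lc.sample_arc(90, 90, "CW", 5)

    def test_monotone_along_travel(self):
        angles = lc.sample_arc(300, 123, "CCW", 7)
        unwrapped = np.array(angles)
        unwrapped[unwrapped > 300] -= 360.0
        assert np.all(np.diff(unwrapped) < 0)
        assert angles[0] == 300 and angles[-1] == 123

    def test_full_lattice_has_72_angles(self):
        assert len(lc.sample_arc(0, 355, "CW", 5)) == 72


class TestClassifyRisk:
    @pytest.mark.parametrize(
        "d,margin,expected",
        [
            (4.0, 5.0, lc.RiskLabel.COLLISION),
            (12.0, 5.0, lc.RiskLabel.NEAR_COLLISION),
            (15.0, 5.0, lc.RiskLabel.CLEAR),  # boundary of the half-open band
            (5.0, 5.0, lc.RiskLabel.NEAR_COLLISION),  # exactly at margin: safe
            (40.0, 5.0, lc.RiskLabel.CLEAR),
        ],
    )
    def test_label_rules(self, d, margin, expected):
        assert lc.classify_risk(d, margin) is expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            lc.classify_risk(-1.0, 5.0)


def test_couch_sweep_has_13_angles():
    angles = lc.couch_sweep_angles()
    assert len(angles) == 13
    assert angles[0] == 90.0 and angles[-1] == 270.0
    assert np.all(np.diff(angles) == 15.0)


class TestTestBeam:
    def test_samples_match_brute_force_per_pose(self, clear_scene, clear_structures, default_head):
        beam = lc.PlanBeam("b", couch_deg=30.0, gantry_start_deg=0.0,
                           gantry_stop_deg=40.0)
        result = lc.test_beam(beam, clear_structures, step_deg=10.0)
        body_samples = [s for s in result.samples if s.against == "body"]
        assert len(body_samples) == 5
        for s in body_samples:
            pose = lc.machine_pose(s.gantry_deg, 30.0).transform
            expect = lc.brute_force_min_distance(
                clear_scene.body, lc.apply_transform(default_head, pose)
            )[0]
            assert s.min_distance == expect

    def test_collision_demo_flags_contact_at_gantry_zero(self, default_head_tree):
        scene = lc.make_scene("collision_demo")
        structures = lc.SceneStructures(
            body_tree=lc.build_obb_tree(scene.body),
            couch_tree=lc.build_obb_tree(scene.couch),
            gantry_tree=default_head_tree,
        )
        result = lc.test_beam(scene.plans[0].beams[0], structures)
        assert result.risk_label is lc.RiskLabel.COLLISION
        assert result.overall_min.min_distance == 0.0
        assert result.overall_min.gantry_deg == 0.0

    def test_zero_margin_clear_unless_intersecting(self, clear_structures):
        beam = lc.PlanBeam("b", 0.0, 0.0, 40.0)
        result = lc.test_beam(beam, clear_structures, margin_cm=0.0, step_deg=10.0)
        assert result.risk_label is not lc.RiskLabel.COLLISION

    def test_margin_monotonicity_of_collision_set(self, default_head_tree):
        scene = lc.make_scene("collision_demo")
        structures = lc.SceneStructures(
            body_tree=lc.build_obb_tree(scene.body), couch_tree=None,
            gantry_tree=default_head_tree,
        )
        beam = scene.plans[0].beams[0]
        res0 = lc.test_beam(beam, structures, margin_cm=0.0)
        res5 = lc.test_beam(beam, structures, margin_cm=5.0)
        flagged0 = {
            (s.couch_deg, s.gantry_deg)
            for s in res0.samples if s.min_distance < 0.0 or s.min_distance == 0.0
        }
        flagged5 = {
            (s.couch_deg, s.gantry_deg)
            for s in res5.samples if s.min_distance < 5.0
        }
        assert flagged0 <= flagged5

    def test_step_refinement_never_increases_minimum(self, clear_structures):
        beam = lc.PlanBeam("b", 45.0, 0.0, 90.0)
        coarse = lc.test_beam(beam, clear_structures, step_deg=10.0)
        fine = lc.test_beam(beam, clear_structures, step_deg=5.0)
        assert fine.overall_min.min_distance <= coarse.overall_min.min_distance

    def test_missing_body_tree_rejected(self, clear_structures):
        broken = lc.SceneStructures(
            body_tree=None, couch_tree=None,
            gantry_tree=clear_structures.gantry_tree,
        )
        with pytest.raises(ValueError, match="body"):
            lc.test_beam(lc.PlanBeam("b", 0.0, 0.0, 40.0), broken)


class TestMaxGantryRange:
    def test_distant_body_full_interval(self, default_head_tree):
        tiny = box_mesh((0, 3.0, 0), (2.0, 2.0, 2.0), 1.0)
        structures = lc.SceneStructures(
            body_tree=lc.build_obb_tree(tiny), couch_tree=None,
            gantry_tree=default_head_tree,
        )
        assert lc.max_gantry_range(0.0, None, structures, margin_cm=5.0) == [(0.0, 355.0)]

    def test_huge_margin_no_safe_angle(self, clear_structures):
        assert lc.max_gantry_range(0.0, None, clear_structures, margin_cm=1e6) == []

    def test_intervals_complement_per_angle_oracle(self, default_head_tree):
        # bar on the patient-left side blocks gantry angles near 90
        bar = box_mesh((38.0, 0.0, 0.0), (4.0, 6.0, 6.0), 2.0)
        structures = lc.SceneStructures(
            body_tree=lc.build_obb_tree(bar), couch_tree=None,
            gantry_tree=default_head_tree,
        )
        margin = 5.0
        intervals = lc.max_gantry_range(0.0, None, structures, margin_cm=margin)
        # independent per-angle oracle over the same lattice
        safe = {}
        for k in range(72):
            g = 5.0 * k
            pose = lc.machine_pose(g, 0.0).transform
            d = lc.tree_min_distance(
                structures.body_tree, structures.gantry_tree, pose
            ).distance
            safe[g] = d >= margin
        assert not safe[90.0]
        covered = set()
        for start, stop in intervals:
            g = start
            while True:
                covered.add(g)
                if g == stop:
                    break
                g = (g + 5.0) % 360.0
        assert covered == {g for g, ok in safe.items() if ok}


class TestTestPlan:
    def test_all_clear_plan_safe(self, clear_scene, clear_structures):
        result = lc.test_plan(clear_scene.plans[0], clear_structures, step_deg=15.0)
        assert result.safe
        assert not result.errors
        assert len(result.beam_results) == 3

    def test_one_colliding_arc_flags_plan_unsafe(self, default_head_tree):
        scene = lc.make_scene("collision_demo")
        structures = lc.SceneStructures(
            body_tree=lc.build_obb_tree(scene.body),
            couch_tree=lc.build_obb_tree(scene.couch),
            gantry_tree=default_head_tree,
        )
        plan = scene.plans[0]
        safe_beam = lc.PlanBeam("high_arc", 0.0, 100.0, 140.0)
        plan = lc.Plan(plan.plan_id, [plan.beams[0], safe_beam])
        result = lc.test_plan(plan, structures)
        assert not result.safe
        labels = [r.risk_label for r in result.beam_results]
        assert labels.count(lc.RiskLabel.COLLISION) == 1

    def test_beam_by_beam_matches_all_at_once(self, clear_scene, clear_structures):
        plan = clear_scene.plans[0]
        whole = lc.test_plan(plan, clear_structures, step_deg=15.0)
        for beam, combined in zip(plan.beams, whole.beam_results):
            single = lc.test_beam(beam, clear_structures, step_deg=15.0)
            assert single.overall_min.min_distance == combined.overall_min.min_distance
            assert single.risk_label is combined.risk_label

    def test_plan_json_roundtrip(self, tmp_path, cuboid_scene):
        plan = cuboid_scene.plans[0]
        path = plan.save(tmp_path / "plan.json")
        assert lc.Plan.load(path) == plan


class TestExportScene:
    def test_min_pose_export_roundtrip(self, tmp_path, clear_scene, clear_structures, default_head):
        beam = lc.PlanBeam("b", 15.0, 0.0, 60.0)
        result = lc.test_beam(beam, clear_structures, step_deg=15.0)
        manifest = lc.export_scene(
            result, clear_scene.body, clear_scene.couch, default_head, tmp_path
        )
        assert manifest["min_distance_cm"] == result.overall_min.min_distance
        # exported gantry mesh must be the canonical mesh under the min pose
        pose = lc.machine_pose(
            manifest["gantry_deg"], manifest["couch_deg"]
        ).transform
        expect = lc.apply_transform(default_head, pose)
        back = lc.read_mesh(tmp_path / "gantry.stl")
        np.testing.assert_allclose(
            np.sort(back.vertices, axis=0),
            np.sort(np.unique(expect.vertices, axis=0), axis=0),
            atol=1e-4,
        )
        # recomputing the clearance from the exported files reproduces it
        body = lc.read_mesh(tmp_path / "body.stl")
        d_body = lc.brute_force_min_distance(body, back)[0]
        couch = lc.read_mesh(tmp_path / "couch.stl")
        d_couch = lc.brute_force_min_distance(couch, back)[0]
        assert min(d_body, d_couch) == pytest.approx(
            manifest["min_distance_cm"], abs=1e-4
        )
        data = json.loads((tmp_path / "manifest.json").read_text())
        assert data["beam_id"] == "b"

    def test_unknown_pose_rejected(self, tmp_path, clear_scene, clear_structures, default_head):
        beam = lc.PlanBeam("b", 15.0, 0.0, 60.0)
        result = lc.test_beam(beam, clear_structures, step_deg=15.0)
        with pytest.raises(ValueError):
            lc.export_scene(
                result, clear_scene.body, clear_scene.couch, default_head,
                tmp_path, pose_selector=(15.0, 2.5),
            )
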