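"""Virtual osteotomy, drill-hole placement, backward transposition, guides."""

import numpy as np
import pytest
import trimesh

from conftest import random_rigid
from zygoplan.geometry import Plane, RigidTransform
from zygoplan.planning import (
    DrillHole,
    OsteotomySpec,
    PlanningError,
    SurgicalPlan,
    backward_transpose,
    build_guides,
    cut_segment,
    make_plan,
    place_drill_holes,
    reposition,
    simulate_hole_execution_study,
    strip_plane_faces,
    verify_plan,
)


class TestCutSegment:
    def test_sphere_halved(self, unit_sphere):
        ost = OsteotomySpec([Plane([0, 0, 0], [0, 0, 1])], ["anterior"], kerf_mm=0.0)
        moving, stable = cut_segment(unit_sphere, ost)
        assert moving.is_watertight and stable.is_watertight
        half = unit_sphere.volume / 2
        assert moving.volume == pytest.approx(half, rel=0.01)
        assert stable.volume == pytest.approx(half, rel=0.01)

    def test_cube_quarter_cut(self):
        cube = trimesh.creation.box(extents=(20, 20, 20))
        ost = OsteotomySpec([Plane([5, 0, 0], [1, 0, 0])], ["anterior"], kerf_mm=0.0)
        moving, stable = cut_segment(cube, ost)
        assert moving.volume == pytest.approx(2000.0, rel=0.01)
        assert stable.volume == pytest.approx(6000.0, rel=0.01)

    def test_volume_conserved_at_zero_kerf(self, unit_sphere):
        ost = OsteotomySpec(
            [Plane([0.2, 0, 0], [1, 0.2, 0]), Plane([0, 0.1, 0], [0.1, 1, 0])],
            ["anterior", "posterior"],
            kerf_mm=0.0,
        )
        moving, stable = cut_segment(unit_sphere, ost)
        assert moving.volume + stable.volume == pytest.approx(
            unit_sphere.volume, rel=0.01
        )

    def test_kerf_removes_a_slab(self):
        cube = trimesh.creation.box(extents=(20, 20, 20))
        ost = OsteotomySpec([Plane([0, 0, 0], [1, 0, 0])], ["anterior"], kerf_mm=1.0)
        moving, stable = cut_segment(cube, ost)
        assert moving.volume + stable.volume == pytest.approx(7600.0, rel=1e-6)

    def test_plane_outside_mesh_rejected(self, unit_sphere):
        ost = OsteotomySpec([Plane([5, 0, 0], [1, 0, 0])], ["anterior"])
        with pytest.raises(PlanningError, match="does not intersect"):
            cut_segment(unit_sphere, ost)

    def test_open_mesh_rejected(self):
        tri = trimesh.Trimesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        ost = OsteotomySpec([Plane([0.2, 0.2, 0], [1, 0, 0])], ["anterior"])
        with pytest.raises(PlanningError, match="closed"):
            cut_segment(tri, ost)

    def test_multi_body_needs_hint(self):
        # two spheres side by side; a cut through both makes 2 moving bodies
        a = trimesh.creation.icosphere(2, radius=1.0)
        b = a.copy()
        b.apply_translation([5, 0, 0])
        both = trimesh.util.concatenate([a, b])
        ost = OsteotomySpec([Plane([0, 0, 0], [0, 0, 1])], ["anterior"])
        with pytest.raises(PlanningError, match="bodies"):
            cut_segment(both, ost)
        moving, stable = cut_segment(both, ost, keep_hint=[5, 0, 1])
        assert np.linalg.norm(moving.centroid - [5, 0, 0.4]) < 0.3


class TestReposition:
    def test_round_trip(self, unit_sphere, rng):
        t = random_rigid(rng)
        back = reposition(reposition(unit_sphere, t), t.inverse())
        assert np.abs(back.vertices - unit_sphere.vertices).max() < 1e-9

    def test_phantom_alignment_lands_on_template(self, small_phantom):
        case = small_phantom
        gt = case.ground_truth_malunion.inverse()
        planned = reposition(case.segment_outer_surface(), gt)
        from zygoplan._triangles import SurfaceDistanceQuery

        q = SurfaceDistanceQuery(case.intact_mesh.vertices, case.intact_mesh.faces)
        d, _, _ = q.query(planned.vertices)
        assert d.max() < 1e-6


class TestPlaceDrillHoles:
    def test_request_on_vertex_snaps_exactly(self, unit_sphere):
        v = unit_sphere.vertices[10]
        holes = place_drill_holes(
            unit_sphere,
            unit_sphere,
            [{"position": v, "role": "moving", "diameter_mm": 0.2, "name": "h"}],
        )
        assert np.allclose(holes[0].position, v, atol=1e-12)
        # axis is the inward normal
        assert holes[0].axis @ v < 0
        assert holes[0].frame == "planned"

    def test_far_request_rejected(self, unit_sphere):
        with pytest.raises(PlanningError, match="mm from"):
            place_drill_holes(
                unit_sphere,
                unit_sphere,
                [{"position": [12, 0, 0], "role": "stable", "diameter_mm": 2.0}],
            )

    def test_overlapping_holes_rejected(self, unit_sphere):
        reqs = [
            {"position": [1, 0, 0], "role": "stable", "diameter_mm": 2.0, "name": "a"},
            {"position": [1, 0.02, 0], "role": "stable", "diameter_mm": 2.0, "name": "b"},
        ]
        with pytest.raises(PlanningError, match="apart"):
            place_drill_holes(unit_sphere, unit_sphere, reqs)


def hole(pos, role, frame="planned", name="h"):
    return DrillHole(np.asarray(pos, float), [0, 0, 1.0], 2.0, role, frame, name)


class TestBackwardTranspose:
    def test_identity_only_changes_frame(self):
        holes = [hole([1, 2, 3], "moving"), hole([4, 5, 6], "stable", name="s")]
        out = backward_transpose(holes, RigidTransform.identity())
        assert all(h.frame == "preop" for h in out)
        assert np.allclose(out[0].position, [1, 2, 3])

    def test_translation_moves_only_moving_holes(self):
        t = RigidTransform(np.eye(3), [0, 0, 4.0])
        holes = [hole([1, 0, 0], "moving"), hole([5, 0, 0], "stable", name="s")]
        out = backward_transpose(holes, t)
        assert np.allclose(out[0].position, [1, 0, -4.0])
        assert np.allclose(out[1].position, [5, 0, 0])

    def test_round_trip_to_machine_precision(self, rng):
        t = random_rigid(rng)
        holes = [hole(rng.normal(size=3) * 10, "moving", name=f"m{i}") for i in range(5)]
        back = backward_transpose(holes, t)
        restored = [h.transformed(t) for h in back]
        for a, b in zip(holes, restored):
            assert np.linalg.norm(a.position - b.position) < 1e-9
            assert np.linalg.norm(a.axis - b.axis) < 1e-12

    def test_mixed_frame_input_rejected(self):
        holes = [hole([0, 0, 0], "moving"), hole([1, 1, 1], "moving", frame="preop", name="x")]
        with pytest.raises(PlanningError, match="frame"):
            backward_transpose(holes, RigidTransform.identity())


class TestBuildGuides:
    def flat_patch(self):
        # a closed thin slab whose top surface is z=0
        slab = trimesh.creation.box(extents=(40, 40, 2))
        slab.apply_translation([0, 0, -1.0])
        return slab

    def test_single_hole_guide_cylinder_axis(self):
        slab = self.flat_patch()
        h = DrillHole([0.0, 0.0, 0.0], [0, 0, -1.0], 2.0, "stable", "preop", "s0")
        guides = build_guides(slab, [h], footprint_radius_mm=8.0, thickness_mm=2.0)
        assert len(guides) == 1
        g = guides[0]
        # guide sits on/above the surface around the hole
        assert g.bounds[1][2] >= 2.0
        assert np.linalg.norm(g.centroid[:2]) < 2.0
        # the through-cylinder is aligned with the drill axis: the guide must
        # contain faces whose normals are perpendicular to z (cylinder wall)
        perp = np.abs(g.face_normals[:, 2]) < np.sin(np.radians(0.5))
        assert perp.sum() > 10

    def test_zero_holes_rejected(self, unit_sphere):
        with pytest.raises(PlanningError, match="no drill holes"):
            build_guides(unit_sphere, [])

    def test_planned_frame_hole_detected(self, small_phantom):
        """A hole left in the planned frame is off the pre-op surface."""
        case = small_phantom
        gt = case.ground_truth_malunion.inverse()
        apex = case.landmarks_preop.get("zygoma_apex", "right")
        planned_pos = gt.apply(apex)  # planned-frame location of a pre-op point
        h = DrillHole(planned_pos, [0, 0, 1.0], 2.0, "moving", "preop", "m0")
        with pytest.raises(PlanningError, match="off the pre-op surface"):
            build_guides(case.preop_mesh, [h])

    def test_frame_tag_mismatch_rejected(self, unit_sphere):
        h = hole(unit_sphere.vertices[0], "stable", frame="planned")
        with pytest.raises(PlanningError, match="pre-op frame"):
            build_guides(unit_sphere, [h])


class TestVerifyPlan:
    def make_consistent_plan(self, rng):
        t = random_rigid(rng)
        planned = [hole(rng.normal(size=3) * 10, "moving", name=f"m{i}") for i in range(4)]
        planned.append(hole([20, 0, 0], "stable", name="s0"))
        preop = backward_transpose(planned, t)
        ost = OsteotomySpec([Plane([0, 0, 0], [1, 0, 0])], ["anterior"])
        return SurgicalPlan(t, ost, planned, preop)

    def test_consistent_plan_passes(self, rng):
        plan = self.make_consistent_plan(rng)
        report = verify_plan(plan, tol_mm=1e-9)
        assert report["pass"]
        assert report["max_deviation_mm"] < 1e-9

    def test_perturbed_alignment_fails_uniformly(self, rng):
        plan = self.make_consistent_plan(rng)
        shifted = RigidTransform(np.eye(3), [1.0, 0, 0]).compose(plan.alignment)
        bad = SurgicalPlan(shifted, plan.osteotomy, plan.holes_planned, plan.holes_preop)
        report = verify_plan(bad, tol_mm=0.5)
        devs = np.array(list(report["hole_deviations_mm"].values()))
        assert np.allclose(devs, 1.0, atol=1e-9)  # rigid motion moves all equally
        assert not report["pass"]

    def test_missing_counterpart_is_structural_failure(self, rng):
        plan = self.make_consistent_plan(rng)
        report = verify_plan(
            SurgicalPlan(plan.alignment, plan.osteotomy, plan.holes_planned, plan.holes_preop[:-2])
        )
        assert report["structural_failures"]
        assert not report["pass"]

    def test_stable_hole_edited_in_one_frame_fails(self, rng):
        plan = self.make_consistent_plan(rng)
        edited = [
            hole(h.position + (0.5 if h.role == "stable" else 0.0), h.role, "preop", h.name)
            for h in plan.holes_preop
        ]
        report = verify_plan(
            SurgicalPlan(plan.alignment, plan.osteotomy, plan.holes_planned, edited)
        )
        assert any("stable" in f for f in report["structural_failures"])


class TestStripPlaneFaces:
    def test_caps_removed_outer_kept(self, unit_sphere):
        plane = Plane([0, 0, 0], [0, 0, 1])
        ost = OsteotomySpec([plane], ["anterior"], kerf_mm=0.0)
        moving, _ = cut_segment(unit_sphere, ost)
        outer = strip_plane_faces(moving, [plane], tol_mm=1e-3)
        # no remaining face centroid on the plane
        assert np.abs(plane.signed_distance(outer.triangles_center)).min() > 1e-3
        assert len(outer.faces) < len(moving.faces)


class TestMakePlanEndToEnd:
    def test_phantom_plan_verifies_by_construction(self, small_phantom):
        from zygoplan.phantom import default_hole_requests

        case = small_phantom
        gt = case.ground_truth_malunion.inverse()
        plan, _, _ = make_plan(
            case.preop_mesh,
            gt,
            case.osteotomy_preop,
            default_hole_requests(case, gt),
            precut=(case.moving_preop, case.stable),
            build_guide_meshes=True,
        )
        report = verify_plan(plan, tol_mm=1e-9)
        assert report["pass"]
        assert len(plan.guides) >= 1
        assert len(plan.psi_footprints) == 2
        assert all(g.is_watertight for g in plan.guides)
        assert all(p.is_watertight for p in plan.psi_footprints)

    def test_plan_json_round_trip(self, small_phantom, tmp_path):
        from zygoplan.phantom import default_hole_requests

        case = small_phantom
        gt = case.ground_truth_malunion.inverse()
        plan, _, _ = make_plan(
            case.preop_mesh, gt, case.osteotomy_preop,
            default_hole_requests(case, gt),
            precut=(case.moving_preop, case.stable), build_guide_meshes=False,
        )
        import json

        p = plan.to_json(tmp_path / "plan.json")
        doc = json.loads(p.read_text())
        assert len(doc["holes_planned"]) == len(plan.holes_planned)
        restored = DrillHole.from_record(doc["holes_preop"][0])
        assert restored.frame == "preop"


class TestTwoPsiStudy:
    def test_two_separated_clusters_beat_one(self):
        """Separated hole clusters constrain orientation better than one."""
        compact = np.array(
            [[0, 0, 0], [4, 0, 0], [0, 4, 0], [4, 4, 0]], dtype=float
        )
        spread = np.array(
            [[0, 0, 0], [4, 0, 0], [25, 0, 0], [29, 0, 4]], dtype=float
        )
        out = simulate_hole_execution_study(
            {"one_cluster": compact, "two_clusters": spread},
            noise_sigma_mm=0.3,
            n_seeds=150,
            seed=42,
        )
        assert np.median(out["two_clusters"]) < np.median(out["one_cluster"])

    def test_study_is_seed_reproducible(self):
        holes = {"a": np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0]], dtype=float)}
        r1 = simulate_hole_execution_study(holes, 0.3, n_seeds=10, seed=5)
        r2 = simulate_hole_execution_study(holes, 0.3, n_seeds=10, seed=5)
        assert np.array_equal(r1["a"], r2["a"])
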