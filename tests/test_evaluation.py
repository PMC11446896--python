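"""Cloud-to-mesh distances, Hausdorff statistics, outer shell, heat maps."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from zygoplan._triangles import brute_force_closest
from zygoplan.evaluation import (
    DistanceField,
    EvaluationError,
    cloud_to_mesh_distance,
    compare_meshes,
    compare_soft_tissue,
    extract_outer_shell,
    hausdorff,
    heatmap_mesh,
    landmark_displacement,
    summarize,
)
from zygoplan.geometry import mesh_scalars, read_mesh, write_mesh
from zygoplan.registration import sample_mesh_points


def random_cloud_mesh(seed):
    rng = np.random.default_rng(seed)
    n_pts = rng.integers(5, 200)
    n_tri = rng.integers(4, 100)
    pts = rng.normal(size=(n_pts, 3)) * rng.uniform(1, 10)
    verts = rng.normal(size=(n_tri * 3, 3)) * rng.uniform(1, 10)
    faces = np.arange(n_tri * 3).reshape(-1, 3)
    return pts, trimesh.Trimesh(verts, faces, process=False)


class TestCloudToMesh:
    def test_points_on_surface_have_zero_distance(self, unit_sphere):
        pts = sample_mesh_points(unit_sphere, 500, seed=0)
        field = cloud_to_mesh_distance(pts, unit_sphere)
        assert np.abs(field.signed_mm).max() < 1e-9

    def test_signed_plane_distance(self):
        plane = trimesh.Trimesh(
            [[-5, -5, 0], [5, -5, 0], [5, 5, 0], [-5, 5, 0]],
            [[0, 1, 2], [0, 2, 3]],
            process=False,
        )
        pts = np.array([[0.5, 0.5, 1.0], [-1.0, 2.0, 1.0], [1.0, -1.0, -2.0]])
        field = cloud_to_mesh_distance(pts, plane)
        assert np.allclose(field.signed_mm, [1.0, 1.0, -2.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_exactly(self, seed):
        pts, mesh = random_cloud_mesh(seed)
        field = cloud_to_mesh_distance(pts, mesh, signed=False)
        oracle, _, _ = brute_force_closest(pts, mesh.triangles)
        assert np.array_equal(field.signed_mm, oracle)

    def test_inside_sphere_is_negative(self, unit_sphere):
        field = cloud_to_mesh_distance(np.array([[0.0, 0.0, 0.0]]), unit_sphere)
        assert field.signed_mm[0] < -0.9


class TestHausdorff:
    def test_self_comparison_is_near_zero(self, unit_sphere):
        out = hausdorff(unit_sphere, unit_sphere, seed=0)
        assert out["directed_max_mm"] < 1e-9
        assert out["mean_mm"] < 1e-9
        assert out["symmetric_max_mm"] < 1e-9

    def test_parallel_squares_constant_field(self):
        def square(z):
            return trimesh.Trimesh(
                [[0, 0, z], [1, 0, z], [1, 1, z], [0, 1, z]],
                [[0, 1, 2], [0, 2, 3]],
                process=False,
            )

        out = hausdorff(square(3.0), square(0.0), seed=1)
        assert out["directed_max_mm"] == pytest.approx(3.0, abs=1e-12)
        assert out["mean_mm"] == pytest.approx(3.0, abs=1e-12)
        assert out["symmetric_max_mm"] == pytest.approx(3.0, abs=1e-12)

    def test_cloud_matches_oracle(self):
        pts, mesh = random_cloud_mesh(123)
        out = hausdorff(pts, mesh, seed=0)
        oracle, _, _ = brute_force_closest(pts, mesh.triangles)
        assert out["directed_max_mm"] == oracle.max()
        assert out["mean_mm"] == pytest.approx(oracle.mean(), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_triangle_inequality_on_sphere_triples(self, seed):
        rng = np.random.default_rng(seed)
        meshes = []
        for _ in range(3):
            m = trimesh.creation.icosphere(1, radius=rng.uniform(0.5, 2.0))
            m.apply_translation(rng.normal(size=3))
            meshes.append(m)
        a, b, c = meshes

        def sym(x, y):
            return hausdorff(x, y, samples_per_mm2=3.0, seed=0)["symmetric_max_mm"]

        # sampled symmetric Hausdorff: allow sampling slack in the inequality
        assert sym(a, c) <= sym(a, b) + sym(b, c) + 0.2


class TestSummarize:
    def test_constant_field_single_bin(self):
        field = DistanceField(np.zeros((1000, 3)), np.full(1000, 2.0))
        s = summarize(field, bin_width_mm=0.5)
        assert s.counts.sum() == 1000
        assert (s.counts > 0).sum() == 1
        assert s.mean_abs_mm == pytest.approx(2.0)

    def test_symmetric_field_means(self):
        vals = np.array([1.0, -1.0] * 500)
        s = summarize(DistanceField(np.zeros((1000, 3)), vals), 0.25)
        assert s.mean_abs_mm == pytest.approx(1.0)
        assert s.mean_signed_mm == pytest.approx(0.0)

    def test_counts_and_stats_match_direct_computation(self, rng):
        vals = rng.normal(0, 1.5, size=777)
        s = summarize(DistanceField(np.zeros((777, 3)), vals), 0.25)
        assert s.counts.sum() == 777
        assert s.mean_abs_mm == pytest.approx(np.abs(vals).mean(), abs=1e-12)
        assert s.rms_mm == pytest.approx(np.sqrt((vals**2).mean()), abs=1e-12)
        assert s.max_mm >= s.p95_mm >= s.p50_mm >= 0

    def test_bad_bin_width_rejected(self):
        with pytest.raises(EvaluationError):
            summarize(DistanceField(np.zeros((3, 3)), np.ones(3)), 0.0)


class TestOuterShell:
    def test_convex_mesh_fully_retained(self):
        sphere = trimesh.creation.icosphere(3, radius=10.0)
        shell = extract_outer_shell(sphere, n_directions=32)
        assert len(shell.faces) >= 0.99 * len(sphere.faces)

    def test_nested_sphere_interior_removed(self):
        outer = trimesh.creation.icosphere(3, radius=20.0)
        inner = trimesh.creation.icosphere(3, radius=10.0)
        both = trimesh.util.concatenate([outer, inner])
        shell = extract_outer_shell(both, n_directions=32)
        # every retained face centroid lies on the outer sphere
        r = np.linalg.norm(shell.triangles_center, axis=1)
        assert r.min() > 15.0
        assert len(shell.faces) <= len(both.faces)

    def test_open_flat_patch_seen_from_both_sides(self):
        patch = trimesh.Trimesh(
            [[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]],
            [[0, 1, 2], [0, 2, 3]],
            process=False,
        )
        shell = extract_outer_shell(patch, n_directions=14, ray_pitch_mm=0.5)
        assert len(shell.faces) == 2

    def test_never_adds_faces(self, small_phantom):
        mesh = small_phantom.intact_mesh
        shell = extract_outer_shell(mesh, n_directions=8)
        assert len(shell.faces) <= len(mesh.faces)
        # every retained triangle exists (by coordinates) in the input
        def key(tris):
            return {tuple(sorted(map(tuple, np.round(t, 9)))) for t in tris}
        assert key(shell.triangles) <= key(mesh.triangles)


class TestLandmarkDisplacement:
    def test_identity(self):
        out = landmark_displacement([1, 2, 3], [1, 2, 3])
        assert out["absolute_mm"] == 0.0

    def test_three_four_five(self):
        out = landmark_displacement([0, 0, 0], [3, 4, 0])
        assert out == {"dx_mm": 3.0, "dy_mm": 4.0, "dz_mm": 0.0, "absolute_mm": 5.0}

    def test_matches_transform_action(self, small_phantom):
        case = small_phantom
        lm = case.landmarks_intact.get("zygoma_apex", "right")
        moved = case.ground_truth_malunion.apply(lm)
        out = landmark_displacement(lm, moved)
        assert out["absolute_mm"] == pytest.approx(np.linalg.norm(moved - lm), abs=1e-9)
        assert out["absolute_mm"] >= max(abs(out["dx_mm"]), abs(out["dy_mm"]), abs(out["dz_mm"]))


class TestSoftTissue:
    def test_identical_scans_zero_field(self, unit_sphere):
        field, summary = compare_soft_tissue(unit_sphere, unit_sphere, seed=0)
        assert summary.mean_abs_mm < 1e-9

    def test_outward_displacement_positive_in_roi(self):
        from zygoplan.phantom import soft_tissue_surface

        bone_pre = trimesh.creation.icosphere(3, radius=20.0)
        bone_post = trimesh.creation.icosphere(3, radius=20.0)
        # push a malar-like patch of the post bone outward by 4 mm
        v = bone_post.vertices.copy()
        w = np.clip((v[:, 0]) / 20.0, 0, 1) ** 2
        bone_post.vertices = v + 4.0 * w[:, None] * (v / np.linalg.norm(v, axis=1)[:, None])
        soft_pre = soft_tissue_surface(bone_pre, 5.0)
        soft_post = soft_tissue_surface(bone_post, 5.0)
        field, summary = compare_soft_tissue(
            soft_pre, soft_post, roi_center=[25.0, 0, 0], roi_radius_mm=10.0, seed=1
        )
        assert 0 < summary.mean_signed_mm <= 4.0
        assert (field.signed_mm > 0).mean() > 0.8

    def test_disjoint_roi_rejected(self, unit_sphere):
        with pytest.raises(EvaluationError, match="region of interest"):
            compare_soft_tissue(
                unit_sphere, unit_sphere, roi_center=[100, 0, 0], roi_radius_mm=1.0
            )


class TestHeatmap:
    def test_scalars_and_colors_written(self, tmp_path, unit_sphere):
        moved = unit_sphere.copy()
        moved.apply_translation([0.5, 0, 0])
        hm = heatmap_mesh(moved, unit_sphere)
        s = mesh_scalars(hm)
        assert s is not None and len(s) == len(moved.vertices)
        # leading (+x) side projects outward, trailing side inward
        lead = s[moved.vertices[:, 0] > 1.2]
        trail = s[moved.vertices[:, 0] < -0.45]
        assert lead.mean() > 0 > trail.mean()
        from zygoplan.evaluation import write_heatmap

        p = write_heatmap(moved, unit_sphere, tmp_path / "hm.ply")
        back = read_mesh(p)
        assert mesh_scalars(back) is not None


class TestCompareMeshes:
    def test_known_offset_recovered(self):
        a = trimesh.creation.box(extents=(10, 10, 10))
        b = a.copy()
        b.apply_translation([0.0, 0.0, 0.3])
        field, summary = compare_meshes(b, a, samples_per_mm2=20, seed=0)
        # faces parallel to the offset see 0.3, side faces see ~0
        assert 0.0 < summary.mean_abs_mm <= 0.3
        assert summary.max_mm == pytest.approx(0.3, abs=0.02)
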