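"""Validation experiments run on phantom cases with known ground truth.

Each function builds its inputs from scratch (phantom generation, planning,
simulated execution), runs the method under test and measures the result, so
the same code backs both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from zygoplan._triangles import brute_force_closest
from zygoplan.evaluation import cloud_to_mesh_distance, compare_meshes
from zygoplan.geometry import apply_transform
from zygoplan.phantom import (
    PhantomParams,
    _farthest_point_subset,
    default_hole_requests,
    generate_phantom,
    rasterize,
    simulate_execution,
)
from zygoplan.planning import make_plan, reposition, simulate_hole_execution_study, verify_plan
from zygoplan.registration import recover_malunion_alignment
from zygoplan.segmentation import extract_surface, seeded_segment


def _register_case(case, seed: int):
    _, _, fine = recover_malunion_alignment(
        case.preop_mesh,
        case.segment_outer_surface(),
        case.landmarks_preop,
        case.segment_landmark_names,
        displaced_side="right",
        seed=seed,
    )
    return fine.transform


def _alignment_errors(case, alignment):
    gt = case.ground_truth_malunion.inverse()
    rot = alignment.compose(gt.inverse()).rotation_angle_deg()
    trans = float(np.linalg.norm(alignment.translation - gt.translation))
    return rot, trans


def recovery_experiment(seed: int = 0) -> dict:
    """Ground-truth malunion recovery on a noiseless phantom.

    Mirror -> landmark alignment -> trimmed ICP; reports the rotation (deg)
    and translation (mm) error of the recovered displacement against the
    phantom's known malunion (default 5 mm medial + 2 mm posterior, 8 deg).
    """
    case = generate_phantom(PhantomParams(seed=seed))
    alignment = _register_case(case, seed)
    rot, trans = _alignment_errors(case, alignment)
    return {
        "rotation_error_deg": rot,
        "translation_error_mm": trans,
        "n_surface_points": len(case.segment_outer_surface().vertices),
    }


def _plan_case(case, alignment, build_guides: bool = False):
    plan, _, _ = make_plan(
        case.preop_mesh,
        alignment,
        case.osteotomy_preop,
        default_hole_requests(case, alignment),
        precut=(case.moving_preop, case.stable),
        build_guide_meshes=build_guides,
    )
    return plan


def _voxel_path_mean(case, plan, planned_model, spacing: float, seed: int) -> float:
    """Planned model vs. a re-segmented rasterization of the executed
    anatomy (the synthetic 'post-op CT' route)."""
    postop = simulate_execution(case, plan, seed=seed)
    vol = rasterize(postop, spacing)
    ijk = tuple(
        int(round(v))
        for v in (plan.alignment.apply(case.moving_preop.centroid) - vol.origin) / vol.spacing
    )
    mask = seeded_segment(vol, [ijk], 300.0)
    recon = extract_surface(mask)
    _, summary = compare_meshes(planned_model, recon, seed=seed + 101)
    return summary.mean_abs_mm


def closure_experiment(seed: int = 0, voxel_spacing_mm: float = 0.5) -> dict:
    """End-to-end zero-noise closure: plan verification plus planned-vs-
    executed distances through both the mesh-only and the rasterize+segment
    routes."""
    case = generate_phantom(PhantomParams(seed=seed))
    alignment = _register_case(case, seed)
    plan = _plan_case(case, alignment)
    report = verify_plan(plan, tol_mm=1e-9)
    postop = simulate_execution(case, plan, seed=seed)
    planned_model = apply_transform(case.segment_outer_surface(), alignment)
    _, mesh_summary = compare_meshes(planned_model, postop, seed=seed + 51)
    voxel_mean = _voxel_path_mean(case, plan, planned_model, voxel_spacing_mm, seed)
    preop_field, preop_summary = compare_meshes(case.segment_outer_surface(), postop,
                                                seed=seed + 52)
    return {
        "verify_pass": report["pass"],
        "verify_max_deviation_mm": report["max_deviation_mm"],
        "planned_vs_postop_mean_mm": mesh_summary.mean_abs_mm,
        "planned_vs_postop_ct_mean_mm": voxel_mean,
        "preop_vs_postop_mean_mm": preop_summary.mean_abs_mm,
        "voxel_diagonal_mm": float(np.sqrt(3) * voxel_spacing_mm),
        "n_samples": mesh_summary.n,
    }


def noise_band_experiment(
    n_seeds: int = 20,
    vertex_noise_mm: float = 0.2,
    voxel_spacing_mm: float = 0.5,
    seed: int = 0,
) -> dict:
    """Planned-vs-postop mean distance under realistic imaging conditions.

    Per seed: a phantom with Gaussian vertex noise, registration from the
    noisy data, planning, zero-error execution, rasterization of the result
    at CT resolution and re-segmentation.  The reported median over seeds is
    the desk-scale analog of a planned-vs-post-op CT comparison.
    """
    means = []
    for i in range(n_seeds):
        case_seed = (seed + 1) * 1000 + i
        case = generate_phantom(
            PhantomParams(vertex_noise_mm=vertex_noise_mm, seed=case_seed)
        )
        alignment = _register_case(case, case_seed)
        plan = _plan_case(case, alignment)
        planned_model = apply_transform(case.segment_outer_surface(), alignment)
        means.append(
            _voxel_path_mean(case, plan, planned_model, voxel_spacing_mm, case_seed)
        )
    means = np.asarray(means)
    return {
        "per_seed_mean_mm": means,
        "median_mm": float(np.median(means)),
        "max_mm": float(means.max()),
        "n_seeds": n_seeds,
    }


def oracle_equivalence_experiment(n_pairs: int = 100, seed: int = 0) -> dict:
    """Accelerated vs. brute-force cloud-to-mesh distances on random pairs.

    Counts bitwise mismatches of per-point distances (hence of the directed
    max) and the worst absolute difference of the means.
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    worst_mean_diff = 0.0
    total_points = 0
    import trimesh

    for _ in range(n_pairs):
        n_pts = int(rng.integers(5, 200))
        n_tri = int(rng.integers(4, 100))
        pts = rng.normal(size=(n_pts, 3)) * rng.uniform(1, 10)
        verts = rng.normal(size=(n_tri * 3, 3)) * rng.uniform(1, 10)
        faces = np.arange(n_tri * 3).reshape(-1, 3)
        mesh = trimesh.Trimesh(verts, faces, process=False)
        fast = cloud_to_mesh_distance(pts, mesh, signed=False).signed_mm
        slow, _, _ = brute_force_closest(pts, mesh.triangles)
        mismatches += int((fast != slow).sum())
        worst_mean_diff = max(worst_mean_diff, abs(fast.mean() - slow.mean()))
        total_points += n_pts
    return {
        "bitwise_mismatches": mismatches,
        "worst_mean_abs_diff_mm": worst_mean_diff,
        "n_pairs": n_pairs,
        "n_points": total_points,
    }


def two_psi_experiment(
    noise_sigma_mm: float = 0.3, n_seeds: int = 150, seed: int = 0
) -> dict:
    """One plate vs. two separated plates on the phantom segment.

    Hole layouts are taken from the phantom's planned segment surface: four
    holes in one compact cluster (single PSI) vs. two pairs at maximally
    separated sites (two PSIs).  Per-hole execution noise is identical; the
    recovered segment orientation error is compared between layouts.
    """
    case = generate_phantom(PhantomParams(seed=seed))
    gt = case.ground_truth_malunion.inverse()
    outer = apply_transform(case.segment_outer_surface(), gt)
    verts = outer.vertices
    # a plate's screw holes all sit within its footprint (~6 mm radius)
    plate_radius = 6.0
    anchor = int(np.argmax(verts[:, 1]))  # anterior-most point of the segment
    one_site = verts[np.linalg.norm(verts - verts[anchor], axis=1) < plate_radius]
    one_cluster = _farthest_point_subset(one_site, 4)
    sites = _farthest_point_subset(verts, 2)
    two_clusters = []
    for s in sites:
        near = verts[np.linalg.norm(verts - s, axis=1) < plate_radius]
        two_clusters.append(_farthest_point_subset(near, 2))
    two_clusters = np.vstack(two_clusters)
    out = simulate_hole_execution_study(
        {"one_psi": one_cluster, "two_psi": two_clusters},
        noise_sigma_mm=noise_sigma_mm,
        n_seeds=n_seeds,
        seed=seed,
    )
    return {
        "median_one_psi_deg": float(np.median(out["one_psi"])),
        "median_two_psi_deg": float(np.median(out["two_psi"])),
        "n_seeds": n_seeds,
        "cluster_separation_mm": float(np.linalg.norm(sites[0] - sites[1])),
    }
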