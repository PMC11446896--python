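"""Midsagittal mirroring and rigid registration of the displaced zygoma.

The planning target for a unilateral malunion is the mirror image of the
intact side: a symmetry plane is fitted from landmarks, the intact hemiface
is reflected across it, and the displaced segment is aligned onto the
mirrored template — first by paired-landmark least squares (Kabsch/Umeyama
without scaling), then refined by trimmed point-to-surface ICP.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from zygoplan._triangles import SurfaceDistanceQuery
from zygoplan.geometry import (
    GeometryError,
    LandmarkSet,
    Plane,
    ReflectionTransform,
    RigidTransform,
    apply_transform,
)

logger = logging.getLogger(__name__)

#: ICP defaults: robust to non-overlapping fracture edges
DEFAULT_ICP_PARAMS = {"max_iter": 100, "tol_mm": 1e-4, "trim_fraction": 0.1}
#: cap on ICP source samples, for determinism and speed
ICP_MAX_SOURCE_POINTS = 5000


class RegistrationError(ValueError):
    """Degenerate landmark configuration or failed registration."""


@dataclass(frozen=True)
class SymmetryPlane:
    """Fitted midsagittal plane; normal points from left to right."""

    plane: Plane
    residual_rms_mm: float

    def __post_init__(self) -> None:
        if self.residual_rms_mm < 0:
            raise RegistrationError("negative plane-fit residual")

    @property
    def reflection(self) -> ReflectionTransform:
        return ReflectionTransform(self.plane)


@dataclass
class RegistrationResult:
    """Outcome of an alignment step (landmark or ICP)."""

    transform: RigidTransform
    rms_before_mm: float
    rms_after_mm: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.rms_after_mm > self.rms_before_mm + 1e-12:
            raise RegistrationError(
                f"registration increased RMS: {self.rms_before_mm:.6g} -> "
                f"{self.rms_after_mm:.6g} mm"
            )

    def to_json(self, path: str | Path, params: dict | None = None) -> Path:
        doc = {
            "matrix_4x4_row_major": [[float(v) for v in row] for row in self.transform.matrix],
            "rms_before_mm": float(self.rms_before_mm),
            "rms_after_mm": float(self.rms_after_mm),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "params": params or {},
        }
        Path(path).write_text(json.dumps(doc, indent=2))
        return Path(path)


def fit_symmetry_plane(landmarks: LandmarkSet) -> SymmetryPlane:
    """Fit the midsagittal plane from bilateral pairs or midline points.

    Bilateral mode (>= 2 left/right pairs): the plane passes through the
    centroid of the pair midpoints with its normal along the mean left-to-
    right direction — the perpendicular-bisector plane in the least-squares
    sense.  Midline mode (>= 3 midline landmarks, used when fewer than two
    pairs exist): the total-least-squares plane through the midline points.
    The reported residual is the RMS distance of the defining points to the
    plane.
    """
    pairs = landmarks.bilateral_pairs()
    midline = landmarks.points(side="midline")
    if len(pairs) >= 2:
        left = np.array([p[1] for p in pairs])
        right = np.array([p[2] for p in pairs])
        direction = (right - left).mean(axis=0)
        norm = np.linalg.norm(direction)
        if norm < 1e-12:
            raise RegistrationError("bilateral pairs coincide; cannot orient plane")
        normal = direction / norm
        midpoints = 0.5 * (left + right)
        point = midpoints.mean(axis=0)
        residual = float(np.sqrt(np.mean(((midpoints - point) @ normal) ** 2)))
        return SymmetryPlane(Plane(point, normal), residual)
    if len(midline) >= 3:
        centroid = midline.mean(axis=0)
        _, svals, vt = np.linalg.svd(midline - centroid)
        if svals[1] < 1e-9:
            raise RegistrationError("midline landmarks are collinear")
        normal = vt[2]
        if len(pairs) == 1:  # orient left -> right if a single pair is available
            if (pairs[0][2] - pairs[0][1]) @ normal < 0:
                normal = -normal
        elif normal[0] < 0:  # deterministic fallback orientation
            normal = -normal
        residual = float(np.sqrt(np.mean(((midline - centroid) @ normal) ** 2)))
        return SymmetryPlane(Plane(centroid, normal), residual)
    raise RegistrationError(
        "symmetry plane needs >= 2 bilateral landmark pairs or >= 3 midline "
        f"landmarks; got {len(pairs)} pairs and {len(midline)} midline points"
    )


def mirror_mesh(mesh: trimesh.Trimesh, plane: SymmetryPlane | Plane) -> trimesh.Trimesh:
    """Reflect a mesh across the symmetry plane (winding flipped)."""
    p = plane.plane if isinstance(plane, SymmetryPlane) else plane
    return apply_transform(mesh, ReflectionTransform(p))


def landmark_align(source_pts, target_pts) -> RigidTransform:
    """Least-squares rigid transform mapping ordered source onto target points.

    Kabsch/Umeyama solution without scaling; the reflection branch of the
    SVD is rejected so the returned rotation always has determinant +1.
    Needs >= 3 non-collinear, non-duplicate corresponding pairs.
    """
    src = np.asarray(source_pts, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target_pts, dtype=float).reshape(-1, 3)
    if len(src) != len(tgt):
        raise RegistrationError(f"point counts differ: {len(src)} vs {len(tgt)}")
    if len(src) < 3:
        raise RegistrationError("landmark alignment needs >= 3 point pairs")
    for name, pts in (("source", src), ("target", tgt)):
        d2 = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        if (d2 + np.eye(len(pts)) * 1e9).min() < 1e-9:
            raise RegistrationError(f"duplicate points in {name} set")
        svals = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if svals[1] < 1e-9 * max(svals[0], 1.0):
            raise RegistrationError(f"{name} points are collinear")
    sc = src.mean(axis=0)
    tc = tgt.mean(axis=0)
    H = (src - sc).T @ (tgt - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ sc
    return RigidTransform(R, t)


def _rms(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def sample_mesh_points(mesh: trimesh.Trimesh, count: int, seed: int) -> np.ndarray:
    """Uniform area-weighted surface samples, deterministic for a seed."""
    pts, _ = trimesh.sample.sample_surface(mesh, count, seed=int(seed))
    return np.asarray(pts, dtype=float)


def _point_to_plane_step(moved, closest, normals) -> RigidTransform:
    """Linearized least-squares rigid step minimizing point-to-plane error.

    Solves ``min over (w, t) of sum(((w x p + t) . n + (p - c) . n)^2)`` and
    re-orthonormalizes the small rotation with the exact Rodrigues map.
    """
    A = np.hstack([np.cross(moved, normals), normals])
    b = -np.sum((moved - closest) * normals, axis=1)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    w, t = x[:3], x[3:]
    angle = np.linalg.norm(w)
    if angle < 1e-15:
        return RigidTransform(np.eye(3), t)
    axis = w / angle
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return RigidTransform(R, t)


def icp_refine(
    source: trimesh.Trimesh | np.ndarray,
    target: trimesh.Trimesh,
    init: RigidTransform | None = None,
    max_iter: int = DEFAULT_ICP_PARAMS["max_iter"],
    tol_mm: float = DEFAULT_ICP_PARAMS["tol_mm"],
    trim_fraction: float = DEFAULT_ICP_PARAMS["trim_fraction"],
    method: str = "point_to_plane",
    seed: int = 0,
) -> RegistrationResult:
    """Trimmed iterative-closest-point refinement onto a target surface.

    Correspondences are exact nearest points on the target surface (not
    nearest vertices, which bias coarse meshes).  Each iteration discards the
    ``trim_fraction`` worst correspondences and solves either a linearized
    point-to-plane step (default; converges fast on smooth anatomy where
    point-to-point ICP slides tangentially) or a Kabsch point-to-point step.
    Iteration stops when the trimmed point-to-surface RMS improves by less
    than ``tol_mm`` or ``max_iter`` is reached; a step that worsens the RMS
    is rejected, so the reported RMS never increases.
    """
    if init is None:
        init = RigidTransform.identity()
    if method not in ("point_to_plane", "point_to_point"):
        raise RegistrationError(f"unknown ICP method {method!r}")
    if isinstance(source, trimesh.Trimesh):
        if source.is_empty:
            raise RegistrationError("empty source mesh")
        n = min(ICP_MAX_SOURCE_POINTS, max(len(source.vertices), 100))
        src = sample_mesh_points(source, n, seed)
    else:
        src = np.asarray(source, dtype=float).reshape(-1, 3)
        if len(src) == 0:
            raise RegistrationError("empty source point set")
        if len(src) > ICP_MAX_SOURCE_POINTS:
            rng = np.random.default_rng(seed)
            src = src[rng.choice(len(src), ICP_MAX_SOURCE_POINTS, replace=False)]
    if not isinstance(target, trimesh.Trimesh) or target.is_empty:
        raise RegistrationError("target must be a nonempty mesh")

    keep = max(3, int(round(len(src) * (1.0 - trim_fraction))))
    if keep < 3:
        raise RegistrationError("trimming leaves fewer than 3 correspondences")
    query = SurfaceDistanceQuery(target.vertices, target.faces)

    def correspondences(transform: RigidTransform):
        moved = transform.apply(src)
        dist, faces, closest = query.query(moved)
        order = np.argsort(dist, kind="stable")[:keep]
        rms = float(np.sqrt(np.mean(dist[order] ** 2)))
        return rms, moved[order], closest[order], query.face_normals[faces[order]]

    current = init
    rms_before, moved, closest, normals = correspondences(current)
    rms = rms_before
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        try:
            if method == "point_to_plane":
                step = _point_to_plane_step(moved, closest, normals)
            else:
                step = landmark_align(moved, closest)
        except (RegistrationError, np.linalg.LinAlgError):
            break
        candidate = step.compose(current)
        new_rms, new_moved, new_closest, new_normals = correspondences(candidate)
        if new_rms > rms:
            logger.debug("ICP step increased RMS (%.3g -> %.3g); stopping", rms, new_rms)
            converged = True
            break
        improvement = rms - new_rms
        current, rms = candidate, new_rms
        moved, closest, normals = new_moved, new_closest, new_normals
        if improvement < tol_mm:
            converged = True
            break
    return RegistrationResult(
        transform=current,
        rms_before_mm=rms_before,
        rms_after_mm=rms,
        iterations=iterations,
        converged=converged,
    )


def recover_malunion_alignment(
    preop_mesh: trimesh.Trimesh,
    segment_mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    segment_landmark_names: list[str],
    displaced_side: str = "right",
    run_icp: bool = True,
    icp_params: dict | None = None,
    seed: int = 0,
) -> tuple[SymmetryPlane, RegistrationResult, RegistrationResult | None]:
    """Full mirroring + registration chain for a unilateral malunion.

    Fits the symmetry plane, mirrors the pre-op mesh (carrying the intact
    side onto the injured side as the template), aligns the displaced-side
    zygoma landmarks onto the mirrored intact-side ones, then optionally
    refines with ICP of the displaced segment against the mirrored template.
    Returns the plane and both registration stages; the final alignment maps
    the pre-op segment onto its planned (mirrored) position.
    """
    # the displaced-segment landmarks are asymmetric by definition; the
    # midsagittal plane must come from the stable anatomy only
    stable_landmarks = LandmarkSet(
        [lm for lm in landmarks if lm.name not in segment_landmark_names]
    )
    plane = fit_symmetry_plane(stable_landmarks)
    reflection = plane.reflection
    intact_side = "left" if displaced_side == "right" else "right"

    src = landmarks.points(names=segment_landmark_names, side=displaced_side)
    tgt_intact = landmarks.points(names=segment_landmark_names, side=intact_side)
    if len(src) != len(segment_landmark_names) or len(tgt_intact) != len(segment_landmark_names):
        raise RegistrationError(
            "segment landmarks missing on one side: "
            f"need {segment_landmark_names} on both {displaced_side!r} and {intact_side!r}"
        )
    tgt = reflection.apply(tgt_intact)
    coarse_t = landmark_align(src, tgt)
    coarse = RegistrationResult(
        transform=coarse_t,
        rms_before_mm=_rms(src, tgt),
        rms_after_mm=_rms(coarse_t.apply(src), tgt),
        iterations=1,
        converged=True,
    )
    if not run_icp:
        return plane, coarse, None
    mirrored = mirror_mesh(preop_mesh, plane)
    params = dict(DEFAULT_ICP_PARAMS, **(icp_params or {}))
    fine = icp_refine(
        segment_mesh,
        mirrored,
        init=coarse.transform,
        max_iter=params["max_iter"],
        tol_mm=params["tol_mm"],
        trim_fraction=params["trim_fraction"],
        seed=seed,
    )
    return plane, coarse, fine
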