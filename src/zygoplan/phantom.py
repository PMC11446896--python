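"""Parametric skull phantoms with a known, ground-truth zygoma malunion.

Clinical CTs for malar malunions are not publicly available, so validation
runs on synthetic phantoms: an ellipsoidal "cranium" carrying two mirror-
symmetric zygoma-like prominences, built from an implicit surface on a grid
symmetric about the midsagittal plane (x = 0).  One prominence is cut free
by an osteotomy plane pair and displaced by a configurable rigid transform —
the malunion — whose exact value is recorded as ground truth, giving every
downstream stage (segmentation, mirroring, registration, planning,
evaluation) a quantity it must recover.

The default malunion reproduces the typical clinical picture of a depressed
malar: 5 mm medial + 2 mm posterior translation with an 8 degree rotation
about the vertical axis through the segment centroid.  The phantom is built
at roughly half adult scale, which keeps desk-scale runtimes while leaving
every error metric (millimetres, degrees) on its clinical scale.

All randomness flows from the ``seed`` parameter; outputs are bit-identical
for equal parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from zygoplan._triangles import SurfaceDistanceQuery, voxelize_closed
from zygoplan.geometry import (
    GeometryError,
    Landmark,
    LandmarkSet,
    Plane,
    RigidTransform,
    apply_transform,
    make_mesh,
    write_mesh,
)
from zygoplan.planning import OsteotomySpec, SurgicalPlan, cut_segment
from zygoplan.segmentation import ScalarVolume

#: CT numbers for rasterized phantoms (cortical bone vs. air)
DEFAULT_BONE_HU = 1200.0
DEFAULT_BACKGROUND_HU = -1000.0


class PhantomError(ValueError):
    """Invalid phantom parameters or construction failure."""


def _rotation_about(axis, angle_deg: float, center) -> RigidTransform:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    center = np.asarray(center, dtype=float)
    return RigidTransform(R, center - R @ center)


@dataclass
class PhantomParams:
    """Geometry, malunion and noise parameters of a synthetic case.

    Lengths in millimetres; the frame is right-handed with +x to the
    patient's right, +y anterior, +z cranial; the midsagittal plane is x=0.
    """

    cranium_semi_axes: tuple[float, float, float] = (40.0, 50.0, 45.0)
    zygoma_radius_mm: float = 14.0
    #: outward direction (unit-normalized internally) of the right zygoma
    zygoma_direction: tuple[float, float, float] = (1.0, 0.75, -0.35)
    #: how far the prominence center sits beyond the cranium surface
    zygoma_protrusion_mm: float = 7.0
    #: malunion of the right zygoma: translation (medial, posterior) + rotation
    malunion_translation_mm: tuple[float, float, float] = (-5.0, -2.0, 0.0)
    malunion_rotation_deg: float = 8.0
    malunion_rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    vertex_noise_mm: float = 0.0
    #: marching-cubes grid pitch for phantom surface generation
    mesh_resolution_mm: float = 1.25
    soft_tissue_thickness_mm: float = 6.0
    #: maximum tolerated penetration of the displaced segment into the skull;
    #: a depressed malar is medially impacted, so the default malunion itself
    #: overlaps by about its translation magnitude
    max_overlap_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cranium_semi_axes) <= 0 or self.zygoma_radius_mm <= 0:
            raise PhantomError("phantom dimensions must be positive")
        if self.vertex_noise_mm < 0:
            raise PhantomError("vertex noise sigma must be >= 0")
        if self.mesh_resolution_mm <= 0:
            raise PhantomError("mesh resolution must be positive")

    def to_dict(self) -> dict:
        return {
            "cranium_semi_axes": list(self.cranium_semi_axes),
            "zygoma_radius_mm": self.zygoma_radius_mm,
            "zygoma_direction": list(self.zygoma_direction),
            "zygoma_protrusion_mm": self.zygoma_protrusion_mm,
            "malunion_translation_mm": list(self.malunion_translation_mm),
            "malunion_rotation_deg": self.malunion_rotation_deg,
            "malunion_rotation_axis": list(self.malunion_rotation_axis),
            "vertex_noise_mm": self.vertex_noise_mm,
            "mesh_resolution_mm": self.mesh_resolution_mm,
            "soft_tissue_thickness_mm": self.soft_tissue_thickness_mm,
            "seed": self.seed,
        }


@dataclass
class PhantomCase:
    """A generated case: meshes, ground truth, landmarks, provenance."""

    intact_mesh: trimesh.Trimesh
    preop_mesh: trimesh.Trimesh
    ground_truth_malunion: RigidTransform
    landmarks_preop: LandmarkSet
    landmarks_intact: LandmarkSet
    #: cutting planes in the intact (planned) frame
    osteotomy: OsteotomySpec
    #: the same cuts expressed on the pre-op (malunited) anatomy — what a
    #: surgeon actually draws along the healed fracture lines
    osteotomy_preop: OsteotomySpec
    #: face ids of the displaced segment within ``preop_mesh``
    segment_face_ids: np.ndarray
    params: PhantomParams
    moving_preop: trimesh.Trimesh = None
    stable: trimesh.Trimesh = None

    def segment_outer_surface(self, tol_mm: float | None = None) -> trimesh.Trimesh:
        """Outer bone surface of the displaced segment (osteotomy caps removed).

        This is the registration source: only externally visible bone exists
        on a CT-derived template, so the virtual cut cross-sections must not
        take part in surface matching.
        """
        from zygoplan.planning import strip_plane_faces

        if tol_mm is None:
            tol_mm = max(0.05, 3.0 * self.params.vertex_noise_mm)
        return strip_plane_faces(self.moving_preop, self.osteotomy_preop.planes, tol_mm)

    @property
    def segment_landmark_names(self) -> list[str]:
        names = [lm.name for lm in self.landmarks_intact if lm.name.startswith("zygoma")]
        return sorted(set(names))

    def write(self, directory: str | Path) -> Path:
        """Write the case directory (intact.stl, preop.stl, JSON sidecars)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_mesh(self.intact_mesh, d / "intact.stl")
        write_mesh(self.preop_mesh, d / "preop.stl")
        self.landmarks_preop.to_json(d / "landmarks.json")
        doc = {
            "malunion_4x4_row_major": [
                [float(v) for v in row] for row in self.ground_truth_malunion.matrix
            ],
            "osteotomy": self.osteotomy.to_record(),
            "segment_face_ids": [int(i) for i in self.segment_face_ids],
            "params": self.params.to_dict(),
        }
        (d / "ground_truth.json").write_text(json.dumps(doc, indent=2))
        return d


def _zygoma_frame(params: PhantomParams):
    """Local orthonormal frame (outward, tangent, binormal) and semi-axes of
    the right zygoma prominence.

    The prominence is a triaxial ellipsoid (not a sphere): a rotationally
    symmetric bump would leave the spin about its own axis unconstrained for
    surface registration, which no real zygoma does.
    """
    u = np.asarray(params.zygoma_direction, dtype=float)
    u = u / np.linalg.norm(u)
    tangent = np.cross(u, [0.0, 0.0, 1.0])
    tangent /= np.linalg.norm(tangent)
    binorm = np.cross(u, tangent)
    frame = np.stack([u, tangent, binorm])  # rows
    rz = params.zygoma_radius_mm
    semi = np.array([rz, 0.75 * rz, 0.55 * rz])
    return frame, semi


def _ellipsoid_surface_point(center, frame, semi, local_dir):
    d = np.asarray(local_dir, dtype=float)
    scale = 1.0 / np.sqrt(((d / semi) ** 2).sum())
    return center + (scale * d) @ frame


def _implicit_skull(params: PhantomParams):
    """Signed implicit function (negative inside) and its support box."""
    a = np.asarray(params.cranium_semi_axes, dtype=float)
    frame, semi = _zygoma_frame(params)
    u = frame[0]
    # prominence center: on the ray from the origin through u, protruding
    scale = 1.0 / np.sqrt(((u / a) ** 2).sum())
    surface_pt = scale * u
    center_r = surface_pt + (params.zygoma_protrusion_mm - semi[0] * 0.4) * u
    center_l = center_r * np.array([-1.0, 1.0, 1.0])
    mirror = np.array([-1.0, 1.0, 1.0])

    def bump(pts: np.ndarray, sign) -> np.ndarray:
        # mirror-symmetric pair: the left bump evaluates the right one's
        # implicit at the x-reflected point, so symmetry is exact
        local = (pts * sign - center_r) @ frame.T
        return (np.linalg.norm(local / semi, axis=-1) - 1.0) * semi.min()

    def f(pts: np.ndarray) -> np.ndarray:
        ell = (np.linalg.norm(pts / a, axis=-1) - 1.0) * a.min()
        return np.minimum(ell, np.minimum(bump(pts, 1.0), bump(pts, mirror)))

    lo = -(a + semi[0] + params.zygoma_protrusion_mm + 2.0)
    hi = -lo
    return f, lo, hi, center_r, surface_pt, u


def _symmetric_grid(lo, hi, h):
    """Grid coordinates symmetric about x=0 so the implicit mesh mirrors
    onto itself to floating-point precision."""
    nx = int(np.ceil(hi[0] / h))
    xs = np.arange(-nx, nx + 1) * h
    ys = np.arange(lo[1], hi[1] + h, h)
    zs = np.arange(lo[2], hi[2] + h, h)
    return xs, ys, zs


def generate_phantom(params: PhantomParams | None = None) -> PhantomCase:
    """Build a skull phantom with a known right-zygoma malunion.

    The intact surface comes from marching cubes over a mirror-symmetric
    implicit function; the pre-op surface is the intact one with the right
    prominence cut free (osteotomy plane pair) and moved by the malunion
    transform, plus optional Gaussian vertex jitter emulating CT surface
    noise.  Raises if the displaced segment would penetrate the stable
    skeleton deeper than ``max_overlap_mm``.
    """
    params = params or PhantomParams()
    f, lo, hi, center_r, base_pt, u = _implicit_skull(params)
    h = params.mesh_resolution_mm
    xs, ys, zs = _symmetric_grid(lo, hi, h)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    vol = f(grid)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0)
    verts = np.stack(
        [xs[0] + verts[:, 0] * h, ys[0] + verts[:, 1] * h, zs[0] + verts[:, 2] * h], axis=1
    )
    intact = make_mesh(verts, faces)
    if intact.volume < 0:
        intact.invert()

    # osteotomy plane pair at the prominence base, normals toward the segment
    mid = 0.5 * (base_pt + center_r)
    tangent = np.cross(u, [0.0, 0.0, 1.0])
    tangent /= np.linalg.norm(tangent)
    tilt = np.radians(12.0)
    n_ant = np.cos(tilt) * u + np.sin(tilt) * tangent
    n_post = np.cos(tilt) * u - np.sin(tilt) * tangent
    anchor = mid - 1.5 * u
    osteotomy = OsteotomySpec(
        planes=[Plane(anchor, n_ant), Plane(anchor, n_post)],
        labels=["anterior", "posterior"],
        kerf_mm=0.0,
    )

    moving, stable = cut_segment(intact, osteotomy)
    seg_centroid = moving.centroid
    t = np.asarray(params.malunion_translation_mm, dtype=float)
    malunion = RigidTransform(np.eye(3), t).compose(
        _rotation_about(params.malunion_rotation_axis, params.malunion_rotation_deg, seg_centroid)
    )
    moving_displaced = apply_transform(moving, malunion)

    # overlap check: deepest penetration of the displaced segment into the
    # stable skeleton
    if len(stable.faces) and params.malunion_rotation_deg != 0 or np.any(t != 0):
        q = SurfaceDistanceQuery(stable.vertices, stable.faces)
        signed, _, _, _ = q.signed_query(moving_displaced.vertices)
        penetration = float(max(0.0, -(signed.min())))
        if penetration > params.max_overlap_mm:
            raise PhantomError(
                f"displaced segment penetrates the skull by {penetration:.1f} mm "
                f"(limit {params.max_overlap_mm} mm); use a smaller malunion "
                "displacement"
            )

    preop = trimesh.util.concatenate([stable, moving_displaced])
    segment_face_ids = np.arange(len(stable.faces), len(preop.faces))

    if params.vertex_noise_mm > 0:
        rng = np.random.default_rng(params.seed)
        noisy = preop.vertices + rng.normal(
            scale=params.vertex_noise_mm, size=preop.vertices.shape
        )
        preop = trimesh.Trimesh(noisy, preop.faces, process=False)

    landmarks_intact = _phantom_landmarks(params, base_pt, center_r)
    moved = []
    seg_names = {lm.name for lm in landmarks_intact if lm.name.startswith("zygoma")}
    for lm in landmarks_intact:
        xyz = lm.xyz
        if lm.name in seg_names and lm.side == "right":
            xyz = malunion.apply(xyz)
        moved.append(Landmark(lm.name, lm.side, xyz))
    landmarks_preop = LandmarkSet(moved)

    osteotomy_preop = OsteotomySpec(
        planes=[p.transformed(malunion) for p in osteotomy.planes],
        labels=list(osteotomy.labels),
        kerf_mm=osteotomy.kerf_mm,
    )
    return PhantomCase(
        intact_mesh=intact,
        preop_mesh=preop,
        ground_truth_malunion=malunion,
        landmarks_preop=landmarks_preop,
        landmarks_intact=landmarks_intact,
        osteotomy=osteotomy,
        osteotomy_preop=osteotomy_preop,
        segment_face_ids=segment_face_ids,
        params=params,
        moving_preop=moving_displaced,
        stable=stable,
    )


def _phantom_landmarks(params: PhantomParams, base_pt, center_r) -> LandmarkSet:
    """Bilateral landmark pairs (symmetric to machine precision) plus
    zygoma-segment landmarks on the prominence."""
    a = np.asarray(params.cranium_semi_axes, dtype=float)

    def on_surface(direction):
        d = np.asarray(direction, dtype=float)
        return d / np.sqrt(((d / a) ** 2).sum())

    def mirrored(name, xyz):
        xyz = np.asarray(xyz, dtype=float)
        return [
            Landmark(name, "right", xyz),
            Landmark(name, "left", xyz * np.array([-1.0, 1.0, 1.0])),
        ]

    frame, semi = _zygoma_frame(params)

    lms: list[Landmark] = []
    # stable bilateral pairs, away from the osteotomized region
    lms += mirrored("orbitale", on_surface((0.45, 0.55, 0.35)))
    lms += mirrored("frontotemporale", on_surface((0.8, 0.1, 0.55)))
    lms += mirrored("gonion_analog", on_surface((0.7, -0.4, -0.5)))
    lms += mirrored("euryon", on_surface((1.0, -0.15, 0.2)))
    # midline points
    for name, d in (
        ("nasion_analog", (0.0, 1.0, 0.25)),
        ("glabella_analog", (0.0, 0.95, 0.45)),
        ("opisthocranion", (0.0, -1.0, 0.1)),
    ):
        lms.append(Landmark(name, "midline", on_surface(d)))
    # zygoma-segment landmarks: apex and three off-apex prominence points
    apex = _ellipsoid_surface_point(center_r, frame, semi, [1.0, 0.0, 0.0])
    lms += mirrored("zygoma_apex", apex)
    for i, d in enumerate(([0.8, 0.6, 0.0], [0.8, 0.0, 0.6], [0.8, 0.0, -0.6])):
        lms += mirrored(f"zygoma_p{i}", _ellipsoid_surface_point(center_r, frame, semi, d))
    return LandmarkSet(lms)


def _farthest_point_subset(points: np.ndarray, k: int, start: int = 0) -> np.ndarray:
    """Greedy farthest-point sampling; deterministic for a fixed start."""
    pts = np.asarray(points, dtype=float)
    chosen = [start]
    d = np.linalg.norm(pts - pts[start], axis=1)
    for _ in range(1, min(k, len(pts))):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return pts[chosen]


def default_hole_requests(
    case: PhantomCase,
    alignment: RigidTransform,
    n_moving: int = 3,
    n_stable: int = 3,
    diameter_mm: float = 2.0,
) -> list[dict]:
    """Spread drill-hole requests over the planned segment and the adjacent
    stable skeleton — the inputs a surgeon would click in planning software.

    Moving-hole requests sit on the repositioned segment's outer surface;
    stable-hole requests on the skeleton within plate reach of the osteotomy
    but clear of the cutting planes.  Positions are exact surface points, so
    they snap with zero residual.
    """
    outer_planned = apply_transform(case.segment_outer_surface(), alignment)
    moving_pts = _farthest_point_subset(outer_planned.vertices, n_moving)

    stable = case.stable
    anchor = case.osteotomy.planes[0].point
    d_anchor = np.linalg.norm(stable.vertices - anchor, axis=1)
    clear = np.ones(len(stable.vertices), dtype=bool)
    for p in case.osteotomy.planes:
        clear &= np.abs(p.signed_distance(stable.vertices)) > 4.0
    outward = (stable.vertex_normals * stable.vertices).sum(axis=1) > 0
    cand = stable.vertices[(d_anchor < 30.0) & (d_anchor > 8.0) & clear & outward]
    if len(cand) < n_stable:
        raise PhantomError("not enough stable surface near the osteotomy for holes")
    stable_pts = _farthest_point_subset(cand, n_stable)

    reqs = []
    for i, p in enumerate(moving_pts):
        reqs.append(
            {"position": p, "role": "moving", "diameter_mm": diameter_mm, "name": f"moving_{i}"}
        )
    for i, p in enumerate(stable_pts):
        reqs.append(
            {"position": p, "role": "stable", "diameter_mm": diameter_mm, "name": f"stable_{i}"}
        )
    return reqs


def rasterize(
    mesh: trimesh.Trimesh,
    spacing_mm: float | tuple[float, float, float],
    bone_hu: float = DEFAULT_BONE_HU,
    background_hu: float = DEFAULT_BACKGROUND_HU,
    margin_mm: float = 3.0,
) -> ScalarVolume:
    """Voxelize a closed mesh into a CT-like volume (center-inside parity).

    Voxel centers strictly inside the surface get ``bone_hu``, everything
    else ``background_hu``.  The grid origin carries an irrational sub-voxel
    offset so parity rays never pass exactly through shared triangle edges.
    """
    if not mesh.is_watertight:
        raise PhantomError("rasterization requires a closed mesh (inside is undefined)")
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).copy()
    if (spacing <= 0).any():
        raise PhantomError("voxel spacing must be positive")
    jitter = spacing * np.array(
        [(np.sqrt(2.0) - 1.0) / 4, (np.sqrt(3.0) - 1.0) / 4, (np.sqrt(5.0) - 1.0) / 4]
    )
    origin = mesh.bounds[0] - margin_mm + jitter
    shape = tuple(
        int(np.ceil((mesh.bounds[1][i] + margin_mm - origin[i]) / spacing[i])) + 1
        for i in range(3)
    )
    # voxelize closed bodies separately and take the union: ray parity over a
    # concatenation of overlapping solids would cancel inside the overlap
    # (e.g. an impacted malunion), carving a spurious cavity
    parts = mesh.split(only_watertight=True)
    if len(parts) <= 1:
        parts = [mesh]
    occ = np.zeros(shape, dtype=bool)
    for part in parts:
        occ |= voxelize_closed(part.vertices, part.faces, origin, spacing, shape)
    data = np.where(occ, np.float32(bone_hu), np.float32(background_hu))
    return ScalarVolume(data, spacing, origin)


def simulate_execution(
    case: PhantomCase,
    plan: SurgicalPlan,
    exec_rot_sigma_deg: float = 0.0,
    exec_trans_sigma_mm: float = 0.0,
    seed: int = 0,
) -> trimesh.Trimesh:
    """Produce a synthetic post-op surface by executing the plan.

    The moving segment is transformed by the plan alignment composed with a
    small random pose perturbation about the segment centroid (surgical
    execution error).  With zero noise the segment lands exactly on its
    planned position.
    """
    from zygoplan.planning import verify_plan

    report = verify_plan(plan, tol_mm=1e-6)
    if not report["pass"]:
        raise PhantomError("refusing to execute an unverified plan")
    moving = case.moving_preop
    stable = case.stable
    perturb = RigidTransform.identity()
    if exec_rot_sigma_deg > 0 or exec_trans_sigma_mm > 0:
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(scale=exec_rot_sigma_deg)
        center = plan.alignment.apply(moving.centroid)
        rot = _rotation_about(axis, angle, center)
        trans = RigidTransform(np.eye(3), rng.normal(scale=exec_trans_sigma_mm, size=3))
        perturb = trans.compose(rot)
    executed = apply_transform(moving, perturb.compose(plan.alignment))
    return trimesh.util.concatenate([stable, executed])


def soft_tissue_surface(bone: trimesh.Trimesh, thickness_mm: float) -> trimesh.Trimesh:
    """Constant-thickness outward offset surface (a soft-tissue envelope).

    Vertices move along smoothed outward vertex normals; faces whose normal
    flips during the offset (local self-intersection in concavities) are
    dropped.
    """
    if thickness_mm <= 0:
        raise PhantomError("soft-tissue thickness must be positive")
    normals = np.asarray(bone.vertex_normals, dtype=float)
    # one Laplacian smoothing pass over normals tames concave creases
    adj = bone.vertex_neighbors
    smoothed = normals.copy()
    for i, nb in enumerate(adj):
        if nb:
            smoothed[i] = normals[i] + normals[nb].mean(axis=0)
    smoothed /= np.maximum(np.linalg.norm(smoothed, axis=1)[:, None], 1e-12)
    offset_verts = bone.vertices + thickness_mm * smoothed
    out = trimesh.Trimesh(offset_verts, bone.faces.copy(), process=False)
    orig_n = bone.face_normals
    new_n = out.face_normals
    flipped = (orig_n * new_n).sum(axis=1) < 0
    if flipped.any():
        out.update_faces(~flipped)
        out.remove_unreferenced_vertices()
    return out
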