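"""Reverse-sequence surgical planning: osteotomy, repositioning, drill holes,
backward transposition, and guide generation.

The order of operations is what makes a patient-specific implant (PSI)
double as a repositioning guide:

1. the malunited segment is osteotomized virtually and moved to its planned
   (mirrored-template) position;
2. PSI drill holes are placed on the *planned* anatomy — some on the moving
   segment, some on the stable skeleton;
3. the moving-segment holes are transposed backward into the pre-operative
   frame by the inverse alignment, keeping their spatial relation to the
   segment;
4. drilling/cutting guides are built on the pre-op anatomy marking every
   hole and osteotomy slot.

Holes drilled through the guides then match the PSI hole pattern only after
the segment is repositioned correctly, which :func:`verify_plan` checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from zygoplan._slice import split_by_planes
from zygoplan._triangles import SurfaceDistanceQuery
from zygoplan.geometry import (
    GeometryError,
    Plane,
    ReflectionTransform,
    RigidTransform,
    apply_transform,
    make_mesh,
    write_mesh,
)
from zygoplan.registration import landmark_align

logger = logging.getLogger(__name__)

#: default guide dimensions (mm); the source workflow gives none
DEFAULT_FOOTPRINT_RADIUS_MM = 8.0
DEFAULT_GUIDE_THICKNESS_MM = 2.0
DEFAULT_KERF_MM = 0.5
#: a hole request must lie this close to its target surface
MAX_REQUEST_SNAP_MM = 5.0
#: holes must sit on the pre-op surface this tightly for guide generation
GUIDE_HOLE_TOL_MM = 0.5


class PlanningError(ValueError):
    """Invalid plan geometry or violated planning contract."""


@dataclass(frozen=True)
class DrillHole:
    """A planned screw hole: position, drill axis, diameter, role and frame.

    ``role`` is ``moving`` (on the osteotomized segment) or ``stable`` (on
    the uncut skeleton); ``frame`` records whether the coordinates are in the
    planned (repositioned) or pre-operative anatomy.
    """

    position: np.ndarray
    axis: np.ndarray
    diameter_mm: float
    role: str
    frame: str
    name: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float).reshape(3)
        a = np.asarray(self.axis, dtype=float).reshape(3)
        if not (np.isfinite(p).all() and np.isfinite(a).all()):
            raise PlanningError(f"non-finite drill hole {self.name!r}")
        norm = np.linalg.norm(a)
        if norm == 0:
            raise PlanningError(f"zero drill axis on hole {self.name!r}")
        if self.diameter_mm <= 0:
            raise PlanningError(f"non-positive diameter on hole {self.name!r}")
        if self.role not in ("moving", "stable"):
            raise PlanningError(f"role must be moving|stable, got {self.role!r}")
        if self.frame not in ("planned", "preop"):
            raise PlanningError(f"frame must be planned|preop, got {self.frame!r}")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "axis", a / norm)

    def transformed(self, t: RigidTransform | ReflectionTransform) -> "DrillHole":
        return replace(
            self,
            position=t.apply(self.position),
            axis=t.apply_vectors(self.axis[None])[0],
        )

    def with_frame(self, frame: str) -> "DrillHole":
        return replace(self, frame=frame)

    def to_record(self) -> dict:
        return {
            "name": self.name,
            "position_mm": [float(v) for v in self.position],
            "axis": [float(v) for v in self.axis],
            "diameter_mm": float(self.diameter_mm),
            "role": self.role,
            "frame": self.frame,
        }

    @classmethod
    def from_record(cls, r: dict) -> "DrillHole":
        return cls(
            position=np.asarray(r["position_mm"]),
            axis=np.asarray(r["axis"]),
            diameter_mm=float(r["diameter_mm"]),
            role=r["role"],
            frame=r["frame"],
            name=r.get("name", ""),
        )


@dataclass
class OsteotomySpec:
    """Cutting planes (with kerf width) releasing the malunited segment.

    Plane normals point toward the moving segment.  The anterior cut is
    guided through an intra-oral approach; the posterior cut (zygomatic
    arch) is kept in the plan but flagged access-limited, since posterior
    retraction is restricted.
    """

    planes: list[Plane]
    labels: list[str]
    kerf_mm: float = DEFAULT_KERF_MM
    access_limited: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.planes) != len(self.labels):
            raise PlanningError("one label per cutting plane required")
        if self.kerf_mm < 0:
            raise PlanningError("kerf width must be >= 0")
        if not self.access_limited:
            self.access_limited = [lbl == "posterior" for lbl in self.labels]

    def to_record(self) -> dict:
        return {
            "kerf_mm": float(self.kerf_mm),
            "planes": [
                {
                    "label": lbl,
                    "point_mm": [float(v) for v in p.point],
                    "normal": [float(v) for v in p.normal],
                    "access_limited": bool(al),
                }
                for p, lbl, al in zip(self.planes, self.labels, self.access_limited)
            ],
        }


@dataclass
class SurgicalPlan:
    """Complete plan: alignment, osteotomies, hole sets in both frames, guides.

    Invariant: every moving hole in the planned frame has exactly one pre-op
    counterpart related by the inverse alignment; stable holes are identical
    in both frames.
    """

    alignment: RigidTransform
    osteotomy: OsteotomySpec
    holes_planned: list[DrillHole]
    holes_preop: list[DrillHole]
    guides: list[trimesh.Trimesh] = field(default_factory=list)
    psi_footprints: list[trimesh.Trimesh] = field(default_factory=list)

    def moving_pairs(self) -> list[tuple[DrillHole, DrillHole]]:
        planned = {h.name: h for h in self.holes_planned if h.role == "moving"}
        preop = {h.name: h for h in self.holes_preop if h.role == "moving"}
        return [(planned[n], preop[n]) for n in sorted(planned) if n in preop]

    def to_json(self, path: str | Path, mesh_dir: str | Path | None = None) -> Path:
        doc = {
            "alignment_4x4_row_major": [[float(v) for v in row] for row in self.alignment.matrix],
            "osteotomy": self.osteotomy.to_record(),
            "holes_planned": [h.to_record() for h in self.holes_planned],
            "holes_preop": [h.to_record() for h in self.holes_preop],
            "guide_files": [],
            "psi_files": [],
        }
        if mesh_dir is not None:
            mesh_dir = Path(mesh_dir)
            mesh_dir.mkdir(parents=True, exist_ok=True)
            for i, g in enumerate(self.guides):
                f = mesh_dir / f"guide_{i}.stl"
                write_mesh(g, f)
                doc["guide_files"].append(f.name)
            for i, g in enumerate(self.psi_footprints):
                f = mesh_dir / f"psi_{i}.stl"
                write_mesh(g, f)
                doc["psi_files"].append(f.name)
        Path(path).write_text(json.dumps(doc, indent=2))
        return Path(path)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def cut_segment(
    mesh: trimesh.Trimesh,
    osteotomy: OsteotomySpec,
    keep_hint=None,
) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Split a closed mesh into (moving, stable) by the osteotomy planes.

    The moving segment is the region on the positive-normal side of every
    cutting plane.  By default it must come out as a single connected body;
    if the cuts also shave slivers off curved walls elsewhere, pass
    ``keep_hint`` (a world point on the intended segment) and the body whose
    centroid is nearest the hint becomes the moving segment while the other
    positive-side bodies rejoin the stable skeleton.  With zero kerf the
    volumes of the two outputs sum to the input volume.
    """
    if not mesh.is_watertight:
        raise PlanningError("osteotomy requires a closed input mesh")
    for plane, label in zip(osteotomy.planes, osteotomy.labels):
        d = plane.signed_distance(mesh.vertices)
        if d.min() > 0 or d.max() < 0:
            raise PlanningError(f"cutting plane {label!r} does not intersect the mesh")
    moving, stable_parts = split_by_planes(mesh, osteotomy.planes, kerf_mm=osteotomy.kerf_mm)
    if moving.is_empty:
        raise PlanningError("no volume on the moving side of the osteotomy planes")
    components = moving.split(only_watertight=False)
    if len(components) > 1:
        if keep_hint is None:
            vols = ", ".join(f"{abs(c.volume):.1f} mm^3" for c in components)
            raise PlanningError(
                f"osteotomy splits the moving side into {len(components)} bodies "
                f"(volumes: {vols}); adjust the cutting planes or pass a "
                "segment hint point"
            )
        hint = np.asarray(keep_hint, dtype=float).reshape(3)
        dists = [np.linalg.norm(c.centroid - hint) for c in components]
        pick = int(np.argmin(dists))
        moving = components[pick]
        stable_parts = stable_parts + [c for i, c in enumerate(components) if i != pick]
    if not stable_parts:
        raise PlanningError("osteotomy leaves no stable skeleton")
    stable = trimesh.util.concatenate(stable_parts)
    return moving, stable


def reposition(moving: trimesh.Trimesh, alignment: RigidTransform) -> trimesh.Trimesh:
    """Move the osteotomized segment to its planned position."""
    return apply_transform(moving, alignment)


def strip_plane_faces(
    mesh: trimesh.Trimesh, planes: list[Plane], tol_mm: float = 0.05
) -> trimesh.Trimesh:
    """Remove faces whose centroid lies on any of the given planes.

    Used to discard osteotomy cross-section caps before surface
    registration: the cut faces exist only on the virtual model, so keeping
    them would bias an ICP against an uncut template.
    """
    centroids = mesh.triangles_center
    on_plane = np.zeros(len(centroids), dtype=bool)
    for p in planes:
        on_plane |= np.abs(p.signed_distance(centroids)) <= tol_mm
    if on_plane.all():
        raise PlanningError("stripping cut faces would leave an empty mesh")
    out = trimesh.Trimesh(mesh.vertices.copy(), mesh.faces[~on_plane], process=False)
    out.remove_unreferenced_vertices()
    return out


def place_drill_holes(
    moving_planned: trimesh.Trimesh,
    stable: trimesh.Trimesh,
    requests: list[dict],
) -> list[DrillHole]:
    """Snap hole requests onto the planned anatomy.

    Each request ``{"position": xyz, "role": "moving"|"stable",
    "diameter_mm": d[, "name": str]}`` is projected to the nearest point of
    the mesh matching its role; the drill axis is the inward surface normal
    there.  Requests farther than 5 mm from their surface and hole pairs
    closer than 1.5x the larger diameter are rejected.
    """
    queries = {
        "moving": SurfaceDistanceQuery(moving_planned.vertices, moving_planned.faces),
        "stable": SurfaceDistanceQuery(stable.vertices, stable.faces),
    }
    holes: list[DrillHole] = []
    for i, req in enumerate(requests):
        role = req["role"]
        if role not in queries:
            raise PlanningError(f"request {i}: role must be moving|stable, got {role!r}")
        pos = np.asarray(req["position"], dtype=float).reshape(3)
        dist, face, closest = queries[role].query(pos[None])
        if dist[0] > MAX_REQUEST_SNAP_MM:
            raise PlanningError(
                f"hole request {req.get('name', i)!r} is {dist[0]:.2f} mm from the "
                f"{role} surface (limit {MAX_REQUEST_SNAP_MM} mm)"
            )
        axis = -queries[role].face_normals[face[0]]
        holes.append(
            DrillHole(
                position=closest[0],
                axis=axis,
                diameter_mm=float(req["diameter_mm"]),
                role=role,
                frame="planned",
                name=str(req.get("name", f"hole_{i}")),
            )
        )
    for a in range(len(holes)):
        for b in range(a + 1, len(holes)):
            gap = np.linalg.norm(holes[a].position - holes[b].position)
            limit = 1.5 * max(holes[a].diameter_mm, holes[b].diameter_mm)
            if gap < limit:
                raise PlanningError(
                    f"holes {holes[a].name!r} and {holes[b].name!r} are {gap:.2f} mm "
                    f"apart (minimum {limit:.2f} mm)"
                )
    return holes


def backward_transpose(holes: list[DrillHole], alignment: RigidTransform) -> list[DrillHole]:
    """Map planned-frame holes into the pre-operative frame.

    Moving holes travel with the segment through the inverse alignment
    (positions and axes); stable holes are copied unchanged.  All outputs
    are tagged ``frame='preop'``.
    """
    if any(h.frame != "planned" for h in holes):
        bad = next(h for h in holes if h.frame != "planned")
        raise PlanningError(
            f"backward transposition expects planned-frame holes; {bad.name!r} "
            f"is in frame {bad.frame!r}"
        )
    inv = alignment.inverse()
    out = []
    for h in holes:
        moved = h.transformed(inv) if h.role == "moving" else h
        out.append(moved.with_frame("preop"))
    return out


def _patch_boundary_edges(vertices, faces) -> np.ndarray:
    """Directed edges used by exactly one face of an open patch."""
    m = trimesh.Trimesh(vertices, faces, process=False)
    edges = m.edges_sorted
    order = np.lexsort(edges.T[::-1])
    se = edges[order]
    dup = np.zeros(len(se), dtype=bool)
    dup[1:] |= (se[1:] == se[:-1]).all(axis=1)
    dup[:-1] |= (se[:-1] == se[1:]).all(axis=1)
    return m.edges[order][~dup]


def _guide_shell(
    preop_mesh: trimesh.Trimesh,
    holes: list[DrillHole],
    osteotomy: OsteotomySpec | None,
    footprint_radius: float,
    thickness: float,
) -> trimesh.Trimesh:
    """Offset shell over the faces near a hole group, plus hole cylinders
    and osteotomy-slot markers."""
    from zygoplan._triangles import closest_point_on_triangles

    tris = preop_mesh.triangles
    near = np.zeros(len(tris), dtype=bool)
    for h in holes:
        pts = np.broadcast_to(h.position, (len(tris), 3))
        cp = closest_point_on_triangles(pts, tris)
        near |= np.linalg.norm(cp - h.position, axis=1) <= footprint_radius
    if not near.any():
        raise PlanningError("guide footprint contains no surface faces")
    patch_faces = preop_mesh.faces[near]

    # excise bowtie vertices (where two boundary loops touch): their vertical
    # wall edge would be shared by four faces, breaking closedness
    for _ in range(10):
        boundary = _patch_boundary_edges(preop_mesh.vertices, patch_faces)
        deg = np.bincount(boundary.ravel(), minlength=len(preop_mesh.vertices))
        bowties = np.where(deg > 2)[0]
        if len(bowties) == 0:
            break
        keep = ~np.isin(patch_faces, bowties).any(axis=1)
        if not keep.any():
            raise PlanningError("guide footprint degenerates while removing bowties")
        patch_faces = patch_faces[keep]

    used, inverse = np.unique(patch_faces, return_inverse=True)
    verts = preop_mesh.vertices[used]
    faces = inverse.reshape(-1, 3)
    normals = preop_mesh.vertex_normals[used]

    # prism between the surface patch and its outward offset
    n = len(verts)
    top = verts + thickness * normals
    all_verts = np.vstack([verts, top])
    bottom_faces = faces[:, ::-1]  # outward = into the bone side
    top_faces = faces + n
    # stitch the open rim
    boundary = _patch_boundary_edges(verts, faces)
    walls = []
    for a, b in boundary:
        walls.append([a, b, b + n])
        walls.append([a, b + n, a + n])
    shell_faces = np.vstack([bottom_faces, top_faces, np.asarray(walls, dtype=np.int64)])
    parts = [make_mesh(all_verts, shell_faces)]

    # through-cylinder marker per hole
    for h in holes:
        cyl = trimesh.creation.cylinder(
            radius=h.diameter_mm / 2.0, height=thickness * 2.5, sections=24
        )
        z = np.array([0.0, 0.0, 1.0])
        rot = trimesh.geometry.align_vectors(z, h.axis)
        cyl.apply_transform(rot)
        cyl.apply_translation(h.position + 0.5 * thickness * (-h.axis))
        parts.append(cyl)

    # kerf-wide slot strip per osteotomy plane crossing the footprint
    if osteotomy is not None:
        bbox_r = footprint_radius + thickness
        center = np.mean([h.position for h in holes], axis=0)
        for plane, label in zip(osteotomy.planes, osteotomy.labels):
            if abs(plane.signed_distance(center)) > bbox_r:
                continue
            slot = trimesh.creation.box(
                extents=(2 * bbox_r, 2 * bbox_r, max(osteotomy.kerf_mm, 0.2))
            )
            rot = trimesh.geometry.align_vectors(np.array([0.0, 0.0, 1.0]), plane.normal)
            slot.apply_transform(rot)
            anchor = center - plane.signed_distance(center) * plane.normal
            slot.apply_translation(anchor)
            parts.append(slot)
    return trimesh.util.concatenate(parts)


def build_guides(
    preop_mesh: trimesh.Trimesh,
    holes_preop: list[DrillHole],
    osteotomy: OsteotomySpec | None = None,
    footprint_radius_mm: float = DEFAULT_FOOTPRINT_RADIUS_MM,
    thickness_mm: float = DEFAULT_GUIDE_THICKNESS_MM,
    group_gap_mm: float = 25.0,
) -> list[trimesh.Trimesh]:
    """Generate drilling/cutting guide meshes seated on the pre-op anatomy.

    Every hole must lie on the pre-op surface (within 0.5 mm) — a hole left
    in the planned frame fails here, which is exactly the mistake the
    backward-transposition step exists to prevent.  Holes are grouped into
    guides by proximity (single-linkage with ``group_gap_mm``); each guide is
    an offset shell of the nearby surface carrying a through-cylinder per
    hole and a kerf-wide slot per osteotomy plane crossing it.
    """
    if not holes_preop:
        raise PlanningError("no drill holes supplied for guide generation")
    if any(h.frame != "preop" for h in holes_preop):
        raise PlanningError("guides are built in the pre-op frame; transpose holes first")
    query = SurfaceDistanceQuery(preop_mesh.vertices, preop_mesh.faces)
    pos = np.array([h.position for h in holes_preop])
    dist, _, _ = query.query(pos)
    off = np.where(dist > GUIDE_HOLE_TOL_MM)[0]
    if len(off):
        h = holes_preop[off[0]]
        raise PlanningError(
            f"hole {h.name!r} lies {dist[off[0]]:.2f} mm off the pre-op surface "
            f"(tolerance {GUIDE_HOLE_TOL_MM} mm); was it backward-transposed?"
        )
    # single-linkage grouping of holes into guides
    groups: list[list[int]] = []
    for i in range(len(holes_preop)):
        merged = None
        for g in groups:
            if any(np.linalg.norm(pos[i] - pos[j]) <= group_gap_mm for j in g):
                if merged is None:
                    g.append(i)
                    merged = g
                else:
                    merged.extend(g)
                    g.clear()
        if merged is None:
            groups.append([i])
    groups = [g for g in groups if g]
    return [
        _guide_shell(
            preop_mesh,
            [holes_preop[i] for i in g],
            osteotomy,
            footprint_radius_mm,
            thickness_mm,
        )
        for g in groups
    ]


def psi_footprint(
    planned_mesh: trimesh.Trimesh,
    holes: list[DrillHole],
    footprint_radius_mm: float = DEFAULT_FOOTPRINT_RADIUS_MM,
    thickness_mm: float = 1.5,
) -> trimesh.Trimesh:
    """Surface footprint of a fixation plate on the planned anatomy.

    The PSI is represented by its hole pattern plus this contact shell; the
    freeform plate sculpting of a CAD workflow is out of scope.
    """
    return _guide_shell(planned_mesh, holes, None, footprint_radius_mm, thickness_mm)


def verify_plan(plan: SurgicalPlan, tol_mm: float = 1e-6) -> dict:
    """Check the hole-matching contract of the plan.

    For every moving hole the pre-op counterpart, pushed through the
    alignment, must land on the planned hole; stable holes must be identical
    in both frames.  Returns a report dict with per-hole deviations.
    """
    report: dict = {"hole_deviations_mm": {}, "structural_failures": [], "tol_mm": tol_mm}
    planned_moving = {h.name: h for h in plan.holes_planned if h.role == "moving"}
    preop_moving = {h.name: h for h in plan.holes_preop if h.role == "moving"}
    for name in sorted(set(planned_moving) | set(preop_moving)):
        if name not in planned_moving or name not in preop_moving:
            report["structural_failures"].append(
                f"moving hole {name!r} missing a counterpart "
                f"({'planned' if name not in planned_moving else 'preop'} frame)"
            )
            continue
        dev = float(
            np.linalg.norm(
                plan.alignment.apply(preop_moving[name].position)
                - planned_moving[name].position
            )
        )
        report["hole_deviations_mm"][name] = dev
    planned_stable = {h.name: h for h in plan.holes_planned if h.role == "stable"}
    preop_stable = {h.name: h for h in plan.holes_preop if h.role == "stable"}
    for name in sorted(set(planned_stable) | set(preop_stable)):
        if name not in planned_stable or name not in preop_stable:
            report["structural_failures"].append(
                f"stable hole {name!r} missing a counterpart"
            )
            continue
        if not np.allclose(
            planned_stable[name].position, preop_stable[name].position, atol=1e-12
        ):
            report["structural_failures"].append(
                f"stable hole {name!r} differs between frames"
            )
    devs = list(report["hole_deviations_mm"].values())
    report["max_deviation_mm"] = max(devs) if devs else 0.0
    report["pass"] = (
        not report["structural_failures"] and report["max_deviation_mm"] <= tol_mm
    )
    return report


# ---------------------------------------------------------------------------
# plan assembly and the two-PSI simulation study
# ---------------------------------------------------------------------------


def make_plan(
    preop_mesh: trimesh.Trimesh,
    alignment: RigidTransform,
    osteotomy: OsteotomySpec,
    hole_requests: list[dict],
    footprint_radius_mm: float = DEFAULT_FOOTPRINT_RADIUS_MM,
    guide_thickness_mm: float = DEFAULT_GUIDE_THICKNESS_MM,
    build_guide_meshes: bool = True,
    keep_hint=None,
    precut: tuple[trimesh.Trimesh, trimesh.Trimesh] | None = None,
) -> tuple[SurgicalPlan, trimesh.Trimesh, trimesh.Trimesh]:
    """Run the reverse planning sequence end to end.

    ``precut`` supplies an already-osteotomized ``(moving, stable)`` pair
    (e.g. from a phantom whose cut is exact); otherwise the pre-op mesh is
    cut here.  Returns ``(plan, moving_preop, stable)``; the plan's holes
    satisfy the backward-transposition invariant by construction.
    """
    if precut is not None:
        moving_preop, stable = precut
    else:
        moving_preop, stable = cut_segment(preop_mesh, osteotomy, keep_hint=keep_hint)
    moving_planned = reposition(moving_preop, alignment)
    holes_planned = place_drill_holes(moving_planned, stable, hole_requests)
    holes_preop = backward_transpose(holes_planned, alignment)
    plan = SurgicalPlan(
        alignment=alignment,
        osteotomy=osteotomy,
        holes_planned=holes_planned,
        holes_preop=holes_preop,
    )
    if build_guide_meshes:
        plan.guides = build_guides(
            preop_mesh,
            holes_preop,
            osteotomy,
            footprint_radius_mm=footprint_radius_mm,
            thickness_mm=guide_thickness_mm,
        )
        moving_holes = [h for h in holes_planned if h.role == "moving"]
        stable_holes = [h for h in holes_planned if h.role == "stable"]
        planned_assembly = trimesh.util.concatenate([moving_planned, stable])
        plan.psi_footprints = [
            psi_footprint(planned_assembly, hs, footprint_radius_mm)
            for hs in (moving_holes, stable_holes)
            if hs
        ]
    return plan, moving_preop, stable


def simulate_hole_execution_study(
    hole_sets: dict[str, np.ndarray],
    noise_sigma_mm: float = 0.3,
    n_seeds: int = 200,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Monte-Carlo study of pose error vs. drill-hole layout.

    Each trial perturbs every hole position with isotropic Gaussian noise
    (per-hole execution error) and recovers the segment pose by rigid
    least-squares of the nominal pattern onto the perturbed one.  Returns the
    orientation error (degrees) per trial for each named layout.  With equal
    hole counts, two spatially separated clusters constrain rotation better
    than one compact cluster — the geometric reason to fixate with two
    plates rather than one.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name, holes in hole_sets.items():
        holes = np.asarray(holes, dtype=float).reshape(-1, 3)
        errs = np.empty(n_seeds)
        for i in range(n_seeds):
            noisy = holes + rng.normal(scale=noise_sigma_mm, size=holes.shape)
            t = landmark_align(holes, noisy)
            errs[i] = t.rotation_angle_deg()
        out[name] = errs
    return out
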