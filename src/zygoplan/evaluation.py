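"""Cloud-to-mesh distance analysis of planned vs. achieved positions.

Accuracy of the repositioning is quantified the way open mesh-comparison
tools do it: sample one surface as a point cloud, measure each point's exact
nearest distance to the reference surface (Hausdorff machinery), and report
the mean absolute distance as the headline statistic alongside RMS, maxima,
percentiles and a histogram.  Signed distances color heat maps: positive
(outward projection) renders orange, negative (medial/inward) blue.

Comparing CT-derived bone surfaces is only meaningful on the externally
visible bone, so :func:`extract_outer_shell` removes interior walls (sinus,
canals) by multi-directional visibility before comparison.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from zygoplan._triangles import SurfaceDistanceQuery, first_hit_faces
from zygoplan.geometry import make_mesh, write_mesh
from zygoplan.registration import icp_refine, sample_mesh_points

#: default surface sampling density for mesh-vs-mesh comparison
DEFAULT_SAMPLES_PER_MM2 = 10.0
#: default histogram bin width — resolves sub-millimetre differences
DEFAULT_BIN_WIDTH_MM = 0.25


class EvaluationError(ValueError):
    """Invalid distance-analysis input."""


@dataclass
class DistanceField:
    """Per-point signed nearest distances to a reference surface.

    Sign convention: positive when the sample lies on the outward-normal
    side of its nearest reference triangle (outward projection), negative
    on the inward/medial side.
    """

    points: np.ndarray
    signed_mm: np.ndarray
    reference: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.signed_mm = np.asarray(self.signed_mm, dtype=float).reshape(-1)
        if len(self.points) != len(self.signed_mm) or len(self.points) == 0:
            raise EvaluationError("distance field needs matching, nonempty arrays")

    @property
    def absolute_mm(self) -> np.ndarray:
        return np.abs(self.signed_mm)


@dataclass
class DistanceSummary:
    """Headline statistics of a distance field."""

    mean_abs_mm: float
    mean_signed_mm: float
    rms_mm: float
    max_mm: float
    p50_mm: float
    p90_mm: float
    p95_mm: float
    bin_edges_mm: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not (self.max_mm >= self.p95_mm >= self.p50_mm >= 0):
            raise EvaluationError("summary percentile ordering violated")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_abs_mm": self.mean_abs_mm,
            "mean_signed_mm": self.mean_signed_mm,
            "rms_mm": self.rms_mm,
            "max_mm": self.max_mm,
            "p50_mm": self.p50_mm,
            "p90_mm": self.p90_mm,
            "p95_mm": self.p95_mm,
        }

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
        return Path(path)

    def histogram_to_csv(self, path: str | Path) -> Path:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["bin_left_mm", "bin_right_mm", "count"])
            for i, c in enumerate(self.counts):
                w.writerow([self.bin_edges_mm[i], self.bin_edges_mm[i + 1], int(c)])
        return Path(path)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def extract_outer_shell(
    mesh: trimesh.Trimesh, n_directions: int = 32, ray_pitch_mm: float | None = None
) -> trimesh.Trimesh:
    """Keep only faces visible from outside the mesh.

    Orthographic ray grids are cast along ``n_directions`` directions spread
    uniformly on the sphere (Fibonacci lattice); faces that are never the
    first hit — interior sinus walls, canal linings — are dropped.  The
    output face set is always a subset of the input's.
    """
    if mesh.is_empty:
        raise EvaluationError("cannot extract the outer shell of an empty mesh")
    if n_directions < 6:
        raise EvaluationError("outer-shell extraction needs >= 6 view directions")
    if ray_pitch_mm is None:
        edges = mesh.edges_unique_length
        ray_pitch_mm = max(float(np.median(edges)) * 0.5, 1e-3)
    i = np.arange(n_directions)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_directions
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.stack([r * np.cos(golden * i), r * np.sin(golden * i), z], axis=1)
    visible = np.zeros(len(mesh.faces), dtype=bool)
    for d in dirs:
        hit = first_hit_faces(mesh.vertices, mesh.faces, d, ray_pitch_mm)
        visible[hit] = True
    out = trimesh.Trimesh(mesh.vertices.copy(), mesh.faces[visible], process=False)
    out.remove_unreferenced_vertices()
    return out


def cloud_to_mesh_distance(
    points: np.ndarray, reference: trimesh.Trimesh, signed: bool = True, name: str = ""
) -> DistanceField:
    """Exact nearest distance of each point to the reference surface.

    Nearest point on any triangle (never nearest-vertex).  Unsigned mode
    returns nonnegative values in ``signed_mm``.
    """
    if reference.is_empty:
        raise EvaluationError("empty reference mesh")
    query = SurfaceDistanceQuery(reference.vertices, reference.faces)
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if signed:
        signed_d, _, _, _ = query.signed_query(pts)
    else:
        signed_d, _, _ = query.query(pts)
    return DistanceField(pts, signed_d, reference=name)


def hausdorff(
    a: np.ndarray | trimesh.Trimesh,
    b: trimesh.Trimesh,
    samples_per_mm2: float = DEFAULT_SAMPLES_PER_MM2,
    seed: int = 0,
) -> dict:
    """Directed and symmetric Hausdorff statistics between two surfaces.

    ``directed_max`` and ``mean`` measure cloud ``a`` against mesh ``b``;
    the symmetric max samples ``b`` (at ``samples_per_mm2``) against ``a``
    when ``a`` is a mesh, otherwise against the cloud's own hull of points.
    """
    if isinstance(a, trimesh.Trimesh):
        n = max(100, int(a.area * samples_per_mm2))
        a_pts = sample_mesh_points(a, n, seed)
        a_mesh = a
    else:
        a_pts = np.asarray(a, dtype=float).reshape(-1, 3)
        a_mesh = None
    if len(a_pts) == 0 or b.is_empty:
        raise EvaluationError("hausdorff needs nonempty inputs")
    d_ab = cloud_to_mesh_distance(a_pts, b, signed=False).absolute_mm
    result = {
        "directed_max_mm": float(d_ab.max()),
        "mean_mm": float(d_ab.mean()),
    }
    nb = max(100, int(b.area * samples_per_mm2))
    b_pts = sample_mesh_points(b, nb, seed + 1)
    if a_mesh is not None:
        d_ba = cloud_to_mesh_distance(b_pts, a_mesh, signed=False).absolute_mm
        back = float(d_ba.max())
    else:
        from scipy.spatial import cKDTree

        back = float(cKDTree(a_pts).query(b_pts)[0].max())
    result["symmetric_max_mm"] = max(result["directed_max_mm"], back)
    return result


def summarize(field: DistanceField, bin_width_mm: float = DEFAULT_BIN_WIDTH_MM) -> DistanceSummary:
    """Histogram + robust statistics of a distance field.

    The histogram is over signed distances with the stated bin width; the
    mean, RMS and percentiles are over absolute distances.  Bin counts sum
    to the sample count exactly.
    """
    if bin_width_mm <= 0:
        raise EvaluationError("histogram bin width must be positive")
    s = field.signed_mm
    a = field.absolute_mm
    lo = np.floor(s.min() / bin_width_mm) * bin_width_mm
    hi = np.ceil(s.max() / bin_width_mm) * bin_width_mm
    if hi <= lo:
        hi = lo + bin_width_mm
    nbins = int(round((hi - lo) / bin_width_mm))
    edges = lo + bin_width_mm * np.arange(nbins + 1)
    counts, _ = np.histogram(s, bins=edges)
    return DistanceSummary(
        mean_abs_mm=float(a.mean()),
        mean_signed_mm=float(s.mean()),
        rms_mm=float(np.sqrt(np.mean(a**2))),
        max_mm=float(a.max()),
        p50_mm=float(np.percentile(a, 50)),
        p90_mm=float(np.percentile(a, 90)),
        p95_mm=float(np.percentile(a, 95)),
        bin_edges_mm=edges,
        counts=counts,
    )


def compare_meshes(
    test: trimesh.Trimesh,
    reference: trimesh.Trimesh,
    samples_per_mm2: float = DEFAULT_SAMPLES_PER_MM2,
    bin_width_mm: float = DEFAULT_BIN_WIDTH_MM,
    seed: int = 0,
    name: str = "",
) -> tuple[DistanceField, DistanceSummary]:
    """Sample ``test`` and measure it against ``reference``."""
    n = max(100, int(test.area * samples_per_mm2))
    pts = sample_mesh_points(test, n, seed)
    field = cloud_to_mesh_distance(pts, reference, signed=True, name=name)
    return field, summarize(field, bin_width_mm)


def landmark_displacement(landmark_pre, landmark_post) -> dict:
    """Three-axis and absolute displacement of a tracked point."""
    pre = np.asarray(landmark_pre, dtype=float).reshape(3)
    post = np.asarray(landmark_post, dtype=float).reshape(3)
    if not (np.isfinite(pre).all() and np.isfinite(post).all()):
        raise EvaluationError("non-finite landmark coordinates")
    d = post - pre
    return {
        "dx_mm": float(d[0]),
        "dy_mm": float(d[1]),
        "dz_mm": float(d[2]),
        "absolute_mm": float(np.linalg.norm(d)),
    }


def compare_soft_tissue(
    pre_scan: trimesh.Trimesh,
    post_scan: trimesh.Trimesh,
    roi_center=None,
    roi_radius_mm: float | None = None,
    prealign: bool = False,
    samples_per_mm2: float = DEFAULT_SAMPLES_PER_MM2,
    bin_width_mm: float = DEFAULT_BIN_WIDTH_MM,
    seed: int = 0,
) -> tuple[DistanceField, DistanceSummary]:
    """Distance analysis of soft-tissue surfaces before/after repositioning.

    Surface-scanner output has no shared CT frame, so ``prealign`` runs a
    trimmed ICP of the post scan onto the pre scan first (the unchanged
    regions dominate the trimmed fit).  The analysis may be restricted to a
    spherical malar region of interest.
    """
    post = post_scan
    if prealign:
        result = icp_refine(post_scan, pre_scan, trim_fraction=0.4, seed=seed)
        post = post_scan.copy()
        post.apply_transform(result.transform.matrix)
    n = max(100, int(post.area * samples_per_mm2))
    pts = sample_mesh_points(post, n, seed)
    if roi_center is not None:
        if roi_radius_mm is None or roi_radius_mm <= 0:
            raise EvaluationError("ROI requires a positive radius")
        keep = np.linalg.norm(pts - np.asarray(roi_center, dtype=float), axis=1) <= roi_radius_mm
        if not keep.any():
            raise EvaluationError("region of interest contains no sample points")
        pts = pts[keep]
    field = cloud_to_mesh_distance(pts, pre_scan, signed=True, name="soft_tissue_pre")
    return field, summarize(field, bin_width_mm)


# ---------------------------------------------------------------------------
# heat-map export
# ---------------------------------------------------------------------------


def heatmap_mesh(
    test: trimesh.Trimesh, reference: trimesh.Trimesh, limit_mm: float | None = None
) -> trimesh.Trimesh:
    """Per-vertex signed distances of ``test`` against ``reference``.

    Returns a copy of ``test`` whose scalar channel holds the signed
    distances, with a diverging blue (inward) to orange (outward) vertex
    colormap, saturating at ``limit_mm`` (default: 95th percentile).
    """
    field = cloud_to_mesh_distance(test.vertices, reference, signed=True)
    s = field.signed_mm
    if limit_mm is None:
        limit_mm = max(float(np.percentile(np.abs(s), 95)), 1e-6)
    out = make_mesh(test.vertices, test.faces, vertex_scalars=s)
    out.visual.vertex_colors = _diverging_colors(s, limit_mm)
    return out


def write_heatmap(
    test: trimesh.Trimesh, reference: trimesh.Trimesh, path: str | Path,
    limit_mm: float | None = None,
) -> Path:
    """Write a heat-map PLY (scalar channel + RGB) for external viewers."""
    hm = heatmap_mesh(test, reference, limit_mm)
    return write_mesh(hm, path, "ply", vertex_colors=hm.visual.vertex_colors)


def _diverging_colors(values: np.ndarray, limit: float) -> np.ndarray:
    """Blue -> white -> orange diverging map on [-limit, +limit]."""
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "inward_outward", [(0.1, 0.3, 0.9), (1.0, 1.0, 1.0), (1.0, 0.55, 0.0)]
    )
    t = np.clip((values + limit) / (2 * limit), 0.0, 1.0)
    rgba = cmap(t)
    return (rgba * 255).astype(np.uint8)
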