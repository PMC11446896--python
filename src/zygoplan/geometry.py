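"""Shared geometric types, rigid/reflection transform algebra and mesh I/O.

All coordinates are in millimetres in a right-handed world frame.  Surfaces
are carried as :class:`trimesh.Trimesh` objects; helpers here construct them
with degenerate-face cleanup and move them through the transform types used
everywhere else in the package.

Rigid transforms (proper rotations, det = +1) and reflections (det = -1) are
deliberately distinct types: a reflection is never representable as a
``RigidTransform``, which keeps the group invariants enforceable.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh

logger = logging.getLogger(__name__)

#: tolerance for orthogonality / involution checks (mm, relative)
_GROUP_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid geometric object or operation."""


class MeshIOError(IOError):
    """Malformed or unsupported mesh file."""


def _as_points(x, name: str = "points") -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[-1] != 3:
        raise GeometryError(f"{name} must be (n, 3), got shape {pts.shape}")
    if not np.isfinite(pts).all():
        bad = np.argwhere(~np.isfinite(pts).all(axis=-1))[0]
        raise GeometryError(
            f"non-finite coordinates in {name} at index {int(bad[0])}: "
            f"{pts[tuple(bad)]}"
        )
    return pts


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation ``R``, translation ``t``).

    ``R`` must be orthogonal with determinant +1 to within 1e-9.  Instances
    are immutable; :meth:`compose` and :meth:`inverse` stay in the group.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.isfinite(R).all() and np.isfinite(t).all()):
            raise GeometryError("non-finite entries in rigid transform")
        if not np.allclose(R @ R.T, np.eye(3), atol=_GROUP_TOL):
            raise GeometryError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_GROUP_TOL):
            raise GeometryError(
                "rotation determinant is not +1; reflections must use "
                "ReflectionTransform"
            )
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- group operations ---------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major)."""
        m = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other``: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def apply_vectors(self, vectors) -> np.ndarray:
        """Map direction vectors by the linear (rotation) part only."""
        v = np.asarray(vectors, dtype=float)
        out = v @ self.rotation.T
        return out

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def __call__(self, points) -> np.ndarray:
        return self.apply(points)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """``compose(a, b)(x) == a(b(x))``."""
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.inverse()


@dataclass(frozen=True)
class Plane:
    """Plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        if not (np.isfinite(p).all() and np.isfinite(n).all()):
            raise GeometryError("non-finite plane parameters")
        norm = np.linalg.norm(n)
        if norm == 0:
            raise GeometryError("plane normal must be nonzero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points) -> np.ndarray:
        pts = _as_points(points)
        d = (pts - self.point) @ self.normal
        return d[0] if np.asarray(points).ndim == 1 else d

    def offset(self, distance_mm: float) -> "Plane":
        """Parallel plane shifted along the normal."""
        return Plane(self.point + distance_mm * self.normal, self.normal)

    def transformed(self, t: "RigidTransform | ReflectionTransform") -> "Plane":
        return Plane(t.apply(self.point), t.apply_vectors(self.normal[None])[0])


@dataclass(frozen=True)
class ReflectionTransform:
    """Reflection across a plane: an improper (det = -1) isometry.

    Applying it twice is the identity; its fixed points are exactly the
    mirror plane.  Kept as its own type so rigid-transform invariants never
    see a determinant of -1.
    """

    plane: Plane

    @property
    def linear(self) -> np.ndarray:
        n = self.plane.normal
        return np.eye(3) - 2.0 * np.outer(n, n)

    @property
    def offset(self) -> np.ndarray:
        n = self.plane.normal
        return 2.0 * float(self.plane.point @ n) * n

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.linear
        m[:3, 3] = self.offset
        return m

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        out = pts @ self.linear.T + self.offset
        return out[0] if np.asarray(points).ndim == 1 else out

    def apply_vectors(self, vectors) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.linear.T

    def __call__(self, points) -> np.ndarray:
        return self.apply(points)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

_SIDES = ("left", "right", "midline")


@dataclass
class Landmark:
    name: str
    side: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise GeometryError(f"landmark side must be one of {_SIDES}")
        self.xyz = _as_points(self.xyz, f"landmark {self.name!r}")[0]


@dataclass
class LandmarkSet:
    """Named anatomical points with laterality tags.

    Bilateral pairs share a base name (e.g. ``zygion`` left + right); the
    (name, side) combination is unique.
    """

    landmarks: list[Landmark] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(lm.name, lm.side) for lm in self.landmarks]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise GeometryError(f"duplicate landmark {dup}")

    def __len__(self) -> int:
        return len(self.landmarks)

    def __iter__(self):
        return iter(self.landmarks)

    def get(self, name: str, side: str) -> np.ndarray:
        for lm in self.landmarks:
            if lm.name == name and lm.side == side:
                return lm.xyz
        raise KeyError(f"no landmark {name!r} on side {side!r}")

    def by_side(self, side: str) -> "LandmarkSet":
        return LandmarkSet([lm for lm in self.landmarks if lm.side == side])

    def bilateral_pairs(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, left xyz, right xyz) for every complete bilateral pair."""
        left = {lm.name: lm.xyz for lm in self.landmarks if lm.side == "left"}
        right = {lm.name: lm.xyz for lm in self.landmarks if lm.side == "right"}
        return [(n, left[n], right[n]) for n in sorted(left) if n in right]

    def points(self, names: Sequence[str] | None = None, side: str | None = None) -> np.ndarray:
        sel = [
            lm
            for lm in self.landmarks
            if (side is None or lm.side == side)
            and (names is None or lm.name in names)
        ]
        if names is not None:  # keep caller-specified order
            order = {n: i for i, n in enumerate(names)}
            sel.sort(key=lambda lm: order[lm.name])
        return np.array([lm.xyz for lm in sel], dtype=float).reshape(-1, 3)

    def transformed(self, t: "RigidTransform | ReflectionTransform") -> "LandmarkSet":
        out = []
        for lm in self.landmarks:
            side = lm.side
            if isinstance(t, ReflectionTransform) and side in ("left", "right"):
                side = "right" if side == "left" else "left"
            out.append(Landmark(lm.name, side, t.apply(lm.xyz)))
        return LandmarkSet(out)

    # -- JSON I/O -----------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        records = [
            {"name": lm.name, "side": lm.side, "xyz": [float(v) for v in lm.xyz]}
            for lm in self.landmarks
        ]
        Path(path).write_text(json.dumps(records, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        records = json.loads(Path(path).read_text())
        return cls([Landmark(r["name"], r["side"], np.asarray(r["xyz"])) for r in records])


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def make_mesh(vertices, faces, vertex_scalars=None) -> trimesh.Trimesh:
    """Construct a surface mesh, dropping degenerate (zero-area) triangles.

    Marching-cubes output routinely contains slivers; they are removed with a
    log entry rather than raised, so downstream area/normal computations stay
    well defined.
    """
    v = _as_points(vertices, "vertices")
    f = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    if f.size and (f.min() < 0 or f.max() >= len(v)):
        raise GeometryError("face indices out of range")
    mesh = trimesh.Trimesh(vertices=v, faces=f, process=False)
    areas = mesh.area_faces
    degenerate = areas <= 0.0
    if degenerate.any():
        logger.info("removing %d degenerate faces", int(degenerate.sum()))
        mesh.update_faces(~degenerate)
        mesh.remove_unreferenced_vertices()
    if vertex_scalars is not None:
        scal = np.asarray(vertex_scalars, dtype=float).reshape(-1)
        if len(scal) != len(mesh.vertices):
            raise GeometryError("vertex scalar channel length mismatch")
        mesh.vertex_attributes["scalar"] = scal
    return mesh


def mesh_scalars(mesh: trimesh.Trimesh) -> np.ndarray | None:
    return mesh.vertex_attributes.get("scalar")


def apply_transform(geometry, t: RigidTransform | ReflectionTransform):
    """Map a mesh, point array, or drill-hole sequence through a transform.

    Reflections flip triangle winding so outward normals remain outward;
    drill-hole axes are mapped by the linear part only.
    """
    if not isinstance(t, (RigidTransform, ReflectionTransform)):
        raise GeometryError(f"unsupported transform type {type(t).__name__}")
    if isinstance(geometry, trimesh.Trimesh):
        verts = t.apply(_as_points(geometry.vertices, "mesh vertices"))
        faces = geometry.faces.copy()
        if isinstance(t, ReflectionTransform):
            faces = faces[:, ::-1]
        out = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        for key, val in geometry.vertex_attributes.items():
            out.vertex_attributes[key] = np.array(val)
        return out
    if hasattr(geometry, "position") and hasattr(geometry, "axis"):
        return geometry.transformed(t)
    if isinstance(geometry, (list, tuple)) and geometry and hasattr(geometry[0], "axis"):
        return type(geometry)(h.transformed(t) for h in geometry)
    pts = _as_points(geometry)
    out = t.apply(pts)
    return out[0] if np.asarray(geometry).ndim == 1 else out


# ---------------------------------------------------------------------------
# mesh file I/O
# ---------------------------------------------------------------------------

_STL_HEADER = 80
_STL_RECORD = 50  # 12 floats * 4 bytes + 2-byte attribute count


def _validate_binary_stl(raw: bytes, path: str) -> None:
    if len(raw) < _STL_HEADER + 4:
        raise MeshIOError(
            f"{path}: truncated STL, file ends at byte {len(raw)} "
            f"inside the {_STL_HEADER + 4}-byte header"
        )
    (n_tri,) = struct.unpack_from("<I", raw, _STL_HEADER)
    expected = _STL_HEADER + 4 + n_tri * _STL_RECORD
    if len(raw) != expected:
        raise MeshIOError(
            f"{path}: binary STL declares {n_tri} triangles "
            f"({expected} bytes) but file has {len(raw)} bytes; "
            f"parse error at byte {min(len(raw), expected)}"
        )


def read_mesh(path: str | Path, file_format: str | None = None) -> trimesh.Trimesh:
    """Read an STL (binary or ASCII) or PLY surface into a mesh.

    PLY vertices may carry a per-vertex ``scalar`` channel (any extra float
    property) which is preserved on the returned mesh.
    """
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise MeshIOError(f"unsupported mesh format {fmt!r} (use STL or PLY)")
    raw = path.read_bytes()
    if fmt == "stl":
        is_ascii = raw[:6].strip().lower().startswith(b"solid") and b"facet" in raw[:1000]
        if not is_ascii:
            _validate_binary_stl(raw, str(path))
        loaded = trimesh.load(path, file_type="stl", process=False)
        if loaded.is_empty:
            raise MeshIOError(f"{path}: no triangles parsed")
        # STL is a triangle soup; weld exactly coincident vertices back
        loaded.merge_vertices()
        return make_mesh(loaded.vertices, loaded.faces)
    verts, faces, scalars = _read_ply(raw, str(path))
    return make_mesh(verts, faces, vertex_scalars=scalars)


def write_mesh(
    mesh: trimesh.Trimesh,
    path: str | Path,
    file_format: str | None = None,
    *,
    ascii_stl: bool = False,
    vertex_colors: np.ndarray | None = None,
) -> Path:
    """Write STL (binary by default) or PLY (ASCII, with scalar/color channels)."""
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt == "stl":
        data = mesh.export(file_type="stl_ascii" if ascii_stl else "stl")
        path.write_bytes(data.encode() if isinstance(data, str) else data)
    elif fmt == "ply":
        scal = mesh_scalars(mesh)
        path.write_bytes(_write_ply(mesh.vertices, mesh.faces, scal, vertex_colors))
    else:
        raise MeshIOError(f"unsupported mesh format {fmt!r} (use STL or PLY)")
    return path


# -- minimal PLY codec (trimesh does not round-trip custom vertex scalars) --


def _write_ply(vertices, faces, scalars=None, colors=None) -> bytes:
    v = np.asarray(vertices, dtype=np.float32)
    f = np.asarray(faces, dtype=np.int32)
    props = ["property float x", "property float y", "property float z"]
    if scalars is not None:
        props.append("property float scalar")
    if colors is not None:
        colors = np.asarray(colors, dtype=np.uint8)[:, :3]
        props += [f"property uchar {c}" for c in ("red", "green", "blue")]
    header = (
        ["ply", "format ascii 1.0", f"element vertex {len(v)}"]
        + props
        + [f"element face {len(f)}", "property list uchar int vertex_indices", "end_header"]
    )
    lines = ["\n".join(header)]
    for i in range(len(v)):
        parts = [f"{x:.8g}" for x in v[i]]
        if scalars is not None:
            parts.append(f"{float(scalars[i]):.8g}")
        if colors is not None:
            parts += [str(int(c)) for c in colors[i]]
        lines.append(" ".join(parts))
    for tri in f:
        lines.append("3 " + " ".join(str(int(i)) for i in tri))
    return ("\n".join(lines) + "\n").encode()


def _read_ply(raw: bytes, path: str):
    """Parse ASCII or binary_little_endian PLY with x,y,z[,scalar][,rgb]."""
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise MeshIOError(f"{path}: not a PLY file (parse error at byte 0)")
    header = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end + len(b"end_header") + 1 :]

    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    for line in header[1:]:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property" and elements:
            if tok[1] == "list":
                elements[-1][2].append((tok[-1], "list"))
            else:
                elements[-1][2].append((tok[2], tok[1]))  # (name, type)
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshIOError(f"{path}: unsupported PLY format {fmt!r}")

    np_types = {
        "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
        "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
        "short": "<i2", "int16": "<i2", "ushort": "<u2", "uint16": "<u2",
        "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
    }

    verts = faces = scalars = None
    if fmt == "ascii":
        rows = body.decode("ascii", errors="replace").split("\n")
        cursor = 0
        for name, count, props in elements:
            chunk = [r.split() for r in rows[cursor : cursor + count]]
            cursor += count
            if name == "vertex":
                cols = [p for p, _ in props]
                arr = np.array([[float(x) for x in r[: len(cols)]] for r in chunk])
                verts = arr[:, [cols.index("x"), cols.index("y"), cols.index("z")]]
                extra = [c for c in cols if c in ("scalar", "quality", "distance")]
                if extra:
                    scalars = arr[:, cols.index(extra[0])]
            elif name == "face":
                faces = np.array([[int(x) for x in r[1:4]] for r in chunk])
    else:
        offset = 0
        for name, count, props in elements:
            if name == "vertex":
                dtype = np.dtype([(p, np_types[t]) for p, t in props])
                arr = np.frombuffer(body, dtype=dtype, count=count, offset=offset)
                offset += dtype.itemsize * count
                verts = np.stack([arr["x"], arr["y"], arr["z"]], axis=1).astype(float)
                for extra in ("scalar", "quality", "distance"):
                    if extra in arr.dtype.names:
                        scalars = arr[extra].astype(float)
                        break
            elif name == "face":
                # assume uchar count + int32 indices, triangles only
                rec = np.dtype([("n", "u1"), ("idx", "<i4", (3,))])
                arr = np.frombuffer(body, dtype=rec, count=count, offset=offset)
                offset += rec.itemsize * count
                if (arr["n"] != 3).any():
                    raise MeshIOError(f"{path}: non-triangular PLY faces")
                faces = arr["idx"].astype(np.int64)
    if verts is None or faces is None:
        raise MeshIOError(f"{path}: PLY missing vertex or face element")
    return verts, faces, scalars
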