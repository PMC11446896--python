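"""Plane slicing of closed meshes with cap triangulation.

``trimesh`` performs the slice itself; the cross-section caps are
triangulated here with ear clipping on each boundary loop (the slice of a
watertight mesh yields simple closed polygons).  Caps are oriented so the
kept solid stays consistently outward-facing and watertight.
"""

from __future__ import annotations

import numpy as np
import trimesh

from zygoplan.geometry import GeometryError, Plane, make_mesh


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Closed loops of vertex indices along open (boundary) edges."""
    edges = mesh.edges_sorted
    order = np.lexsort(edges.T[::-1])
    se = edges[order]
    dup = np.zeros(len(se), dtype=bool)
    dup[1:] |= (se[1:] == se[:-1]).all(axis=1)
    dup[:-1] |= (se[:-1] == se[1:]).all(axis=1)
    open_edges = mesh.edges[order][~dup]
    if len(open_edges) == 0:
        return []
    nxt: dict[int, list[int]] = {}
    for a, b in open_edges:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    unused = {tuple(sorted(e)) for e in open_edges.tolist()}
    loops = []
    while unused:
        a, b = next(iter(unused))
        loop = [a, b]
        unused.discard((min(a, b), max(a, b)))
        while True:
            cur = loop[-1]
            prev = loop[-2]
            cands = [
                v
                for v in nxt.get(cur, [])
                if v != prev and (min(cur, v), max(cur, v)) in unused
            ]
            if not cands:
                break
            v = cands[0]
            unused.discard((min(cur, v), max(cur, v)))
            if v == loop[0]:
                break
            loop.append(v)
        if len(loop) >= 3:
            loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def _ear_clip(poly2d: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple 2D polygon (CCW or CW) by ear clipping."""
    n = len(poly2d)
    if n < 3:
        return []
    idx = list(range(n))
    area2 = 0.0
    for i in range(n):
        x0, y0 = poly2d[i]
        x1, y1 = poly2d[(i + 1) % n]
        area2 += x0 * y1 - x1 * y0
    ccw = area2 >= 0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        guard += 1
        n_cur = len(idx)
        clipped = False
        for k in range(n_cur):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % n_cur]
            a, b, c = poly2d[i0], poly2d[i1], poly2d[i2]
            turn = cross(a, b, c)
            if (turn <= 0) if ccw else (turn >= 0):
                continue  # reflex corner
            # no other polygon vertex inside the candidate ear
            ok = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                p = poly2d[j]
                s1, s2, s3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
                if ccw:
                    inside = s1 >= 0 and s2 >= 0 and s3 >= 0
                else:
                    inside = s1 <= 0 and s2 <= 0 and s3 <= 0
                if inside:
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
        if not clipped:  # numerically stuck: fall back to a fan
            for k in range(1, len(idx) - 1):
                tris.append((idx[0], idx[k], idx[k + 1]))
            return tris
    tris.append((idx[0], idx[1], idx[2]))
    return tris


def slice_closed(mesh: trimesh.Trimesh, plane: Plane, keep: str = "positive") -> trimesh.Trimesh:
    """Cut a closed mesh by a plane and cap the cross-section.

    ``keep='positive'`` retains the half-space the plane normal points into.
    Returns a closed mesh; returns an empty mesh if the kept side is empty.
    """
    normal = plane.normal if keep == "positive" else -plane.normal
    part = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=normal, plane_origin=plane.point, cap=False
    )
    if part is None or part.is_empty:
        return trimesh.Trimesh()
    part = trimesh.Trimesh(part.vertices, part.faces, process=False)
    # the slice duplicates vertices along the cut; weld them so the
    # cross-section boundary forms closed loops
    part.merge_vertices()
    loops = _boundary_loops(part)
    if not loops:
        return part

    # 2D basis in the cut plane
    helper = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)

    verts = part.vertices
    cap_faces = []
    for loop in loops:
        pts = verts[loop]
        poly2d = np.stack([pts @ e1, pts @ e2], axis=1)
        for i0, i1, i2 in _ear_clip(poly2d):
            cap_faces.append((loop[i0], loop[i1], loop[i2]))
    if cap_faces:
        cap_faces = np.asarray(cap_faces, dtype=np.int64)
        # orient cap outward: away from the kept half-space (along -normal)
        tri = verts[cap_faces]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        flip = (fn @ normal) > 0
        cap_faces[flip] = cap_faces[flip][:, ::-1]
        faces = np.vstack([part.faces, cap_faces])
    else:
        faces = part.faces
    out = make_mesh(verts, faces)
    return out


def split_by_planes(
    mesh: trimesh.Trimesh, planes: list[Plane], kerf_mm: float = 0.0
) -> tuple[trimesh.Trimesh, list[trimesh.Trimesh]]:
    """Partition a closed mesh: the region on the positive side of *all*
    planes (the moving segment) vs. everything else.

    Each plane may remove a slab of width ``kerf_mm`` (the saw kerf),
    centred on the plane.  Returns ``(moving, stable_parts)`` where the
    stable side may be several closed pieces (one per cutting plane).
    """
    if not mesh.is_watertight:
        raise GeometryError("mesh must be closed to be cut")
    half = kerf_mm / 2.0
    rest = mesh
    stable_parts: list[trimesh.Trimesh] = []
    for plane in planes:
        neg = slice_closed(rest, plane.offset(-half), keep="negative")
        if not neg.is_empty:
            stable_parts.append(neg)
        rest = slice_closed(rest, plane.offset(half), keep="positive")
        if rest.is_empty:
            break
    return rest, stable_parts
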