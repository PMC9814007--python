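"""Low-level triangulated-surface geometry kernels.

All positions are in millimetres in a fixed laboratory frame: apex of the
ventricle at the origin, long axis along +z toward the base.  These kernels
are shared by the kinematics, valve, overset and transport modules.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "enclosed_volume",
    "boundary_edge_count",
    "triangle_areas",
    "vertex_normals",
    "vertex_areas",
    "rotation_about_axis",
    "points_inside",
    "grid_column_inside",
    "point_triangle_distance",
    "triangles_intersect",
    "self_intersections",
]


class OpenSurfaceError(ValueError):
    """Raised when an operation requires a closed surface but finds boundary edges."""

    def __init__(self, n_boundary_edges: int):
        self.n_boundary_edges = n_boundary_edges
        super().__init__(
            f"surface is not closed: {n_boundary_edges} boundary edge(s) found"
        )


def boundary_edge_count(faces: np.ndarray) -> int:
    """Number of edges that belong to exactly one triangle (0 for a closed surface)."""
    faces = np.asarray(faces, dtype=np.int64)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts == 1))


def enclosed_volume(vertices: np.ndarray, faces: np.ndarray, *, check_closed: bool = True):
    """Signed divergence-theorem volume of a closed triangulated surface.

    Returns ``(volume, inverted)`` where ``volume`` is the positive enclosed
    volume and ``inverted`` is True when the input orientation points inward
    (negative signed volume).  Units follow the vertex units cubed.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if check_closed:
        nb = boundary_edge_count(faces)
        if nb:
            raise OpenSurfaceError(nb)
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    signed = np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0
    return abs(signed), signed < 0


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = vertices[faces[:, 0]]
    n = np.cross(vertices[faces[:, 1]] - a, vertices[faces[:, 2]] - a)
    return 0.5 * np.linalg.norm(n, axis=1)


def vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Barycentric vertex areas (one third of each incident triangle); sums to the total area."""
    ta = triangle_areas(vertices, faces) / 3.0
    va = np.zeros(len(vertices))
    for k in range(3):
        np.add.at(va, faces[:, k], ta)
    return va


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted outward vertex normals (unit length; zero-norm guarded)."""
    a = vertices[faces[:, 0]]
    fn = np.cross(vertices[faces[:, 1]] - a, vertices[faces[:, 2]] - a)
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def rotation_about_axis(point_a: np.ndarray, point_b: np.ndarray, angle_deg: float):
    """Rodrigues rotation by ``angle_deg`` about the axis through ``point_a`` → ``point_b``.

    Returns ``(R, t)`` so that a point ``p`` maps to ``R @ p + t``.
    Raises ValueError for a degenerate (zero-length) axis.
    """
    a = np.asarray(point_a, dtype=float)
    b = np.asarray(point_b, dtype=float)
    axis = b - a
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("degenerate rotation axis: points coincide")
    k = axis / n
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    t = a - R @ a
    return R, t


# ---------------------------------------------------------------------------
# inside/outside classification: ray parity along +z
# ---------------------------------------------------------------------------

def _project_triangles(vertices, faces):
    p0 = vertices[faces[:, 0]]
    p1 = vertices[faces[:, 1]]
    p2 = vertices[faces[:, 2]]
    return p0, p1, p2


def points_inside(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray,
                  *, jitter: float = 1e-9, chunk: int = 4096) -> np.ndarray:
    """Ray-parity inside test for arbitrary query points against a closed surface.

    Casts a +z ray from each point; odd crossing parity means inside.  Ties at
    exact edge/vertex hits are resolved by a deterministic ``jitter`` (mm) of
    the ray's x/y station.
    """
    points = np.asarray(points, dtype=float)
    p0, p1, p2 = _project_triangles(np.asarray(vertices, float), np.asarray(faces))
    # 2D edge vectors of the xy-projected triangles
    ax, ay = p0[:, 0], p0[:, 1]
    bx, by = p1[:, 0], p1[:, 1]
    cx, cy = p2[:, 0], p2[:, 1]
    denom = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
    ok = np.abs(denom) > 1e-30  # drop triangles degenerate in projection
    inside = np.zeros(len(points), dtype=bool)
    for s in range(0, len(points), chunk):
        q = points[s:s + chunk]
        qx = q[:, 0:1] + jitter
        qy = q[:, 1:2] + jitter * 0.5
        w0 = ((by - cy) * (qx - cx) + (cx - bx) * (qy - cy)) / np.where(ok, denom, 1.0)
        w1 = ((cy - ay) * (qx - cx) + (ax - cx) * (qy - cy)) / np.where(ok, denom, 1.0)
        w2 = 1.0 - w0 - w1
        hit = ok & (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        zhit = w0 * p0[:, 2] + w1 * p1[:, 2] + w2 * p2[:, 2]
        above = hit & (zhit > q[:, 2:3])
        inside[s:s + chunk] = (above.sum(axis=1) % 2).astype(bool)
    return inside


def grid_column_inside(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray,
                       vertices: np.ndarray, faces: np.ndarray,
                       *, jitter: float = 1e-9) -> np.ndarray:
    """Inside mask for a full Cartesian lattice, shape (len(xs), len(ys), len(zs)).

    Exploits the shared (x, y) columns of the lattice: each column needs one
    ray cast, after which every z station is classified by crossing parity.
    """
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    cols = np.column_stack([X.ravel() + jitter, Y.ravel() + jitter * 0.5])
    p0, p1, p2 = _project_triangles(vertices, faces)
    denom = ((p1[:, 1] - p2[:, 1]) * (p0[:, 0] - p2[:, 0])
             + (p2[:, 0] - p1[:, 0]) * (p0[:, 1] - p2[:, 1]))
    ok = np.abs(denom) > 1e-30
    denom = np.where(ok, denom, 1.0)
    qx = cols[:, 0:1]
    qy = cols[:, 1:2]
    w0 = ((p1[:, 1] - p2[:, 1]) * (qx - p2[:, 0]) + (p2[:, 0] - p1[:, 0]) * (qy - p2[:, 1])) / denom
    w1 = ((p2[:, 1] - p0[:, 1]) * (qx - p2[:, 0]) + (p0[:, 0] - p2[:, 0]) * (qy - p2[:, 1])) / denom
    w2 = 1.0 - w0 - w1
    hit = ok & (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
    zhit = w0 * p0[:, 2] + w1 * p1[:, 2] + w2 * p2[:, 2]
    zhit = np.where(hit, zhit, np.inf)
    # parity for every z station: crossings strictly above z must be odd
    zhit_sorted = np.sort(zhit, axis=1)
    nhits = hit.sum(axis=1)
    idx = np.sum(zhit_sorted[:, :, None] <= np.asarray(zs)[None, None, :], axis=1)
    counts_above = nhits[:, None] - idx
    inside = (counts_above % 2).astype(bool)
    return inside.reshape(len(xs), len(ys), len(zs))


# ---------------------------------------------------------------------------
# point–triangle distance and triangle–triangle intersection
# ---------------------------------------------------------------------------

def point_triangle_distance(points: np.ndarray, vertices: np.ndarray,
                            faces: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Unsigned minimum distance from each query point to a triangulated surface."""
    points = np.asarray(points, float)
    p0, p1, p2 = _project_triangles(np.asarray(vertices, float), np.asarray(faces))
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        q = points[s:s + chunk][:, None, :]  # (n,1,3)
        d = _pt_tri(q, p0[None], p1[None], p2[None])
        out[s:s + chunk] = d.min(axis=1)
    return out


def _pt_tri(p, a, b, c):
    # Ericson's real-time collision detection closest-point-on-triangle, vectorized
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-30, 1.0, denom)
    v = np.clip(vb / denom, 0, 1)
    w = np.clip(vc / denom, 0, 1)
    closest = a + ab * v[..., None] + ac * w[..., None]
    # clamp to edges/vertices for exterior Voronoi regions
    cl = closest.copy()
    m = (d1 <= 0) & (d2 <= 0)
    cl[m] = np.broadcast_to(a, cl.shape)[m]
    m = (d3 >= 0) & (d4 <= d3)
    cl[m] = np.broadcast_to(b, cl.shape)[m]
    m = (d6 >= 0) & (d5 <= d6)
    cl[m] = np.broadcast_to(c, cl.shape)[m]
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = np.where(np.abs(d1 - d3) < 1e-30, 0.0, d1 / np.where(np.abs(d1 - d3) < 1e-30, 1.0, d1 - d3))
    pe = a + ab * np.clip(t, 0, 1)[..., None]
    cl[m] = pe[m]
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t = np.where(np.abs(d2 - d6) < 1e-30, 0.0, d2 / np.where(np.abs(d2 - d6) < 1e-30, 1.0, d2 - d6))
    pe = a + ac * np.clip(t, 0, 1)[..., None]
    cl[m] = pe[m]
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    den = (d4 - d3) + (d5 - d6)
    t = np.where(np.abs(den) < 1e-30, 0.0, (d4 - d3) / np.where(np.abs(den) < 1e-30, 1.0, den))
    pe = b + (c - b) * np.clip(t, 0, 1)[..., None]
    cl[m] = pe[m]
    return np.linalg.norm(p - cl, axis=-1)


def triangles_intersect(t1: np.ndarray, t2: np.ndarray, eps: float = 1e-9) -> bool:
    """Exact-ish triangle–triangle overlap test (Möller's interval method).

    Triangles sharing a vertex within ``eps`` are treated as non-intersecting
    (mesh adjacency, not a collision).
    """
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    for p in t1:
        for q in t2:
            if np.linalg.norm(p - q) < eps:
                return False

    n2 = np.cross(t2[1] - t2[0], t2[2] - t2[0])
    d2 = -np.dot(n2, t2[0])
    dv1 = t1 @ n2 + d2
    if np.all(dv1 > eps) or np.all(dv1 < -eps):
        return False
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    d1 = -np.dot(n1, t1[0])
    dv2 = t2 @ n1 + d1
    if np.all(dv2 > eps) or np.all(dv2 < -eps):
        return False
    dvec = np.cross(n1, n2)
    axis = int(np.argmax(np.abs(dvec)))
    if np.linalg.norm(dvec) < eps:  # coplanar: conservative AABB overlap
        return bool(np.all(t1.min(0) <= t2.max(0) + eps) and np.all(t2.min(0) <= t1.max(0) + eps))

    def interval(tri, dv):
        proj = tri[:, axis]
        pos = dv > eps
        neg = dv < -eps
        if pos.sum() == 1:
            lone, other = np.where(pos)[0][0], np.where(~pos)[0]
        elif neg.sum() == 1:
            lone, other = np.where(neg)[0][0], np.where(~neg)[0]
        else:  # a vertex lies on the plane
            on = np.where(np.abs(dv) <= eps)[0]
            lone, other = on[0], np.delete(np.arange(3), on[0])
        ts = []
        for o in other:
            denom = dv[lone] - dv[o]
            if abs(denom) < 1e-30:
                ts.append(proj[o])
            else:
                ts.append(proj[o] + (proj[lone] - proj[o]) * dv[o] / (dv[o] - dv[lone]))
        return min(ts), max(ts)

    a0, a1 = interval(t1, dv1)
    b0, b1 = interval(t2, dv2)
    return bool(a0 <= b1 - eps and b0 <= a1 - eps)


def self_intersections(vertices: np.ndarray, faces: np.ndarray,
                       max_report: int = 10) -> list[tuple[int, int]]:
    """Brute-force (AABB-prefiltered) list of intersecting non-adjacent triangle pairs."""
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces)
    tris = vertices[faces]  # (m,3,3)
    lo = tris.min(axis=1)
    hi = tris.max(axis=1)
    m = len(faces)
    found: list[tuple[int, int]] = []
    shared = [set(f) for f in faces]
    for i in range(m):
        overlap = np.where(np.all(lo[i + 1:] <= hi[i], axis=1)
                           & np.all(hi[i + 1:] >= lo[i], axis=1))[0] + i + 1
        for j in overlap:
            if shared[i] & shared[j]:
                continue
            if triangles_intersect(tris[i], tris[j]):
                found.append((i, int(j)))
                if len(found) >= max_report:
                    return found
    return found
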