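"""Triangle-mesh primitives shared by the whole pipeline.

Provides an indexed triangle surface with a semantic role, spherical-cap
constructors used by the synthetic joint generator, vectorised ray casting
(Moller-Trumbore), and PLY/STL serialisation.  Everything is plain numpy;
no external mesh library is required.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TriSurface",
    "sphere_cap",
    "stitch_cap_solid",
    "ray_hits",
    "first_hit_distances",
    "points_inside",
    "fit_sphere",
    "write_ply",
    "read_ply",
    "write_stl",
]


@dataclass
class TriSurface:
    """Indexed triangle mesh carrying a semantic role.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    role : free-form label, e.g. ``"bone"``, ``"subchondral"``, ``"cartilage"``
    vertex_data : optional named per-vertex scalar fields
    """

    vertices: np.ndarray
    faces: np.ndarray
    role: str = ""
    vertex_data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalized:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_areas(self) -> np.ndarray:
        """Barycentric lumping: one third of each incident triangle's area."""
        fa = self.face_areas()
        va = np.zeros(self.n_vertices)
        np.add.at(va, self.faces.ravel(), np.repeat(fa / 3.0, 3))
        return va

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        fn = self.face_normals(normalized=False)  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    def mean_edge_length(self) -> float:
        tri = self.triangles()
        e = np.concatenate(
            [
                np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1),
                np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1),
                np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1),
            ]
        )
        return float(e.mean())

    # -- transforms ---------------------------------------------------------

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriSurface":
        """Rigidly map vertices: v -> R v + t (returns a new surface)."""
        rotation = np.asarray(rotation, dtype=np.float64)
        translation = np.asarray(translation, dtype=np.float64)
        v = self.vertices @ rotation.T + translation
        return TriSurface(v, self.faces.copy(), self.role, dict(self.vertex_data))

    def flipped(self) -> "TriSurface":
        """Reverse face winding (flips outward normals)."""
        return TriSurface(
            self.vertices.copy(), self.faces[:, ::-1].copy(), self.role, dict(self.vertex_data)
        )

    def copy(self) -> "TriSurface":
        return TriSurface(
            self.vertices.copy(), self.faces.copy(), self.role, dict(self.vertex_data)
        )


# ---------------------------------------------------------------------------
# constructors


def _axis_basis(axis: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal basis whose third column is ``axis``."""
    z = np.asarray(axis, dtype=np.float64)
    z = z / np.linalg.norm(z)
    helper = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def cap_directions(
    half_angle_deg: float, n_polar: int, n_azimuth: int, axis=(0.0, 0.0, 1.0)
) -> np.ndarray:
    """Unit directions of the structured cap grid: pole + n_polar rings.

    Vertex 0 is the pole; ring ``i`` (1-based) occupies indices
    ``1 + (i-1)*n_azimuth .. i*n_azimuth``.
    """
    basis = _axis_basis(axis)
    theta = np.linspace(0.0, np.deg2rad(half_angle_deg), n_polar + 1)[1:]
    phi = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)
    t, p = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.column_stack(
        [
            (np.sin(t) * np.cos(p)).ravel(),
            (np.sin(t) * np.sin(p)).ravel(),
            np.cos(t).ravel(),
        ]
    )
    dirs = np.vstack([[0.0, 0.0, 1.0], dirs])
    return dirs @ basis.T


def _cap_faces(n_polar: int, n_azimuth: int) -> np.ndarray:
    faces = []
    # pole fan
    for j in range(n_azimuth):
        faces.append([0, 1 + j, 1 + (j + 1) % n_azimuth])
    # quad strips
    for i in range(n_polar - 1):
        r0 = 1 + i * n_azimuth
        r1 = r0 + n_azimuth
        for j in range(n_azimuth):
            a, b = r0 + j, r0 + (j + 1) % n_azimuth
            c, d = r1 + j, r1 + (j + 1) % n_azimuth
            faces.append([a, c, d])
            faces.append([a, d, b])
    return np.asarray(faces, dtype=np.int64)


def sphere_cap(
    radius,
    half_angle_deg: float,
    center=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
    n_polar: int = 24,
    n_azimuth: int = 48,
    concave: bool = False,
    role: str = "",
) -> TriSurface:
    """Spherical cap mesh about ``axis``.

    ``radius`` is a scalar or a callable mapping unit directions (n, 3) to
    per-direction radii, which lets the caller impose a smooth thickness
    field.  ``concave=True`` flips the winding so outward normals point
    toward the sphere centre (socket-side articular surfaces).
    """
    dirs = cap_directions(half_angle_deg, n_polar, n_azimuth, axis)
    r = radius(dirs) if callable(radius) else np.full(len(dirs), float(radius))
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("cap radii must be strictly positive")
    vertices = np.asarray(center, dtype=np.float64) + dirs * r[:, None]
    faces = _cap_faces(n_polar, n_azimuth)
    surf = TriSurface(vertices, faces, role=role)
    return surf.flipped() if concave else surf


def boundary_ring(n_polar: int, n_azimuth: int) -> np.ndarray:
    """Vertex indices of the outermost ring of a structured cap."""
    r0 = 1 + (n_polar - 1) * n_azimuth
    return np.arange(r0, r0 + n_azimuth, dtype=np.int64)


def stitch_cap_solid(outer: TriSurface, inner: TriSurface, n_polar: int, n_azimuth: int) -> TriSurface:
    """Close two same-topology caps into a watertight solid with a side wall.

    Both caps must come from :func:`sphere_cap` with identical
    ``(n_polar, n_azimuth)`` so that boundary rings correspond vertexwise.
    """
    if outer.n_vertices != inner.n_vertices:
        raise ValueError("caps must share topology")
    n = outer.n_vertices
    verts = np.vstack([outer.vertices, inner.vertices])
    ring = boundary_ring(n_polar, n_azimuth)
    wall = []
    for j in range(n_azimuth):
        a, b = ring[j], ring[(j + 1) % n_azimuth]
        wall.append([a, b, b + n])
        wall.append([a, b + n, a + n])
    faces = np.vstack([outer.faces, inner.faces[:, ::-1] + n, np.asarray(wall, dtype=np.int64)])
    return TriSurface(verts, faces, role="solid")


# ---------------------------------------------------------------------------
# ray casting

_RAY_CHUNK = 256


def ray_hits(surface: TriSurface, origins: np.ndarray, directions: np.ndarray, t_min: float = 1e-9):
    """All positive ray/triangle intersections (Moller-Trumbore).

    Returns ``(ray_idx, t)`` arrays sorted by ray then by distance.
    ``directions`` need not be unit length; ``t`` is in direction units.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    directions = np.atleast_2d(np.asarray(directions, dtype=np.float64))
    if directions.shape[0] == 1 and origins.shape[0] > 1:
        directions = np.broadcast_to(directions, origins.shape)
    tri = surface.triangles()
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0

    idx_out, t_out = [], []
    for start in range(0, len(origins), _RAY_CHUNK):
        o = origins[start : start + _RAY_CHUNK]
        d = directions[start : start + _RAY_CHUNK]
        # (r, m, 3) broadcasting
        pvec = np.cross(d[:, None, :], e2[None, :, :])
        det = np.einsum("mk,rmk->rm", e1, pvec)
        ok = np.abs(det) > 1e-12
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o[:, None, :] - v0[None, :, :]
        u = np.einsum("rmk,rmk->rm", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("rmk,rmk->rm", d[:, None, :], qvec) * inv_det
        t = np.einsum("mk,rmk->rm", e2, qvec) * inv_det
        eps = 1e-10
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t > t_min)
        r_idx, _ = np.nonzero(hit)
        idx_out.append(r_idx + start)
        t_out.append(t[hit])
    ray_idx = np.concatenate(idx_out) if idx_out else np.empty(0, dtype=np.int64)
    t = np.concatenate(t_out) if t_out else np.empty(0)
    order = np.lexsort((t, ray_idx))
    return ray_idx[order], t[order]


def first_hit_distances(
    surface: TriSurface, origins: np.ndarray, directions: np.ndarray, t_min: float = 1e-9
) -> np.ndarray:
    """Per-ray distance to the first intersection; NaN where the ray misses."""
    origins = np.atleast_2d(origins)
    ray_idx, t = ray_hits(surface, origins, directions, t_min)
    out = np.full(len(origins), np.nan)
    # rays are sorted, so reversed assignment keeps the smallest t
    for i, ti in zip(ray_idx[::-1], t[::-1]):
        out[i] = ti
    return out


_PARITY_DIR = np.array([0.2371864, 0.6132817, 0.7534291])
_PARITY_DIR = _PARITY_DIR / np.linalg.norm(_PARITY_DIR)


def points_inside(solid: TriSurface, points: np.ndarray) -> np.ndarray:
    """Even/odd parity inside test against a watertight solid."""
    points = np.atleast_2d(points)
    ray_idx, _ = ray_hits(solid, points, _PARITY_DIR[None, :])
    counts = np.bincount(ray_idx, minlength=len(points))
    return counts % 2 == 1


# ---------------------------------------------------------------------------
# fitting / resampling


def fit_sphere(points: np.ndarray):
    """Algebraic least-squares sphere fit; returns (center, radius, rms)."""
    p = np.asarray(points, dtype=np.float64)
    if len(p) < 4:
        raise ValueError("sphere fit needs >= 4 points")
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = (p**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    rms = float(np.sqrt(np.mean((np.linalg.norm(p - center, axis=1) - radius) ** 2)))
    return center, radius, rms


def _closest_point_on_triangles(tri: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Closest point of each triangle (n, 3, 3) to each point (n, 3).

    Vectorised barycentric-region clamping (Ericson, *Real-Time Collision
    Detection*, 5.1.5).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    assign(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


def closest_surface_points(surface: TriSurface, points: np.ndarray, k: int = 8):
    """Nearest point on the triangulated surface for each query point.

    Candidate triangles come from a KD-tree over centroids (``k`` nearest);
    returns ``(closest_points, distances)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = surface.triangles()
    tree = cKDTree(tri.mean(axis=1))
    k = min(k, len(tri))
    _, cand = tree.query(points, k=k)
    cand = cand.reshape(len(points), k)
    best_d = np.full(len(points), np.inf)
    best_p = np.zeros_like(points)
    for j in range(k):
        cp = _closest_point_on_triangles(tri[cand[:, j]], points)
        d = np.linalg.norm(cp - points, axis=1)
        sel = d < best_d
        best_d[sel] = d[sel]
        best_p[sel] = cp[sel]
    return best_p, best_d


def nearest_vertex_map(src: TriSurface, dst: TriSurface) -> np.ndarray:
    """For each vertex of ``dst``, index of the nearest vertex of ``src``."""
    tree = cKDTree(src.vertices)
    _, idx = tree.query(dst.vertices)
    return idx


# ---------------------------------------------------------------------------
# serialisation


def write_ply(path, surface: TriSurface, binary: bool = True) -> None:
    """PLY writer (binary little-endian by default) with per-vertex scalars."""
    props = list(surface.vertex_data.keys())
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"comment role {surface.role or 'unset'}")
    header.append(f"element vertex {surface.n_vertices}")
    header += [f"property double {c}" for c in ("x", "y", "z")]
    header += [f"property double {p}" for p in props]
    header.append(f"element face {surface.n_faces}")
    header.append("property list uchar int vertex_indices")
    header.append("end_header")

    vcols = [surface.vertices] + [
        np.asarray(surface.vertex_data[p], dtype=np.float64).reshape(-1, 1) for p in props
    ]
    vdata = np.hstack(vcols)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(vdata.astype("<f8").tobytes())
            counts = np.full((surface.n_faces, 1), 3, dtype=np.uint8)
            for row, cnt in zip(surface.faces, counts):
                fh.write(cnt.tobytes() + row.astype("<i4").tobytes())
        else:
            for row in vdata:
                fh.write((" ".join(f"{x:.10g}" for x in row) + "\n").encode("ascii"))
            for row in surface.faces:
                fh.write(f"3 {row[0]} {row[1]} {row[2]}\n".encode("ascii"))


def read_ply(path) -> TriSurface:
    """Reader for the subset of PLY this package writes."""
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.index(b"end_header\n") + len(b"end_header\n")
    header = raw[:end].decode("ascii").splitlines()
    body = raw[end:]
    binary = any("binary_little_endian" in ln for ln in header)
    role = ""
    n_vertex = n_face = 0
    vprops: list[str] = []
    element = None
    for ln in header:
        parts = ln.split()
        if not parts:
            continue
        if parts[0] == "comment" and len(parts) >= 3 and parts[1] == "role":
            role = parts[2] if parts[2] != "unset" else ""
        elif parts[0] == "element":
            element = parts[1]
            if element == "vertex":
                n_vertex = int(parts[2])
            elif element == "face":
                n_face = int(parts[2])
        elif parts[0] == "property" and element == "vertex" and parts[1] != "list":
            vprops.append(parts[2])

    n_props = len(vprops)
    if binary:
        vbytes = n_vertex * n_props * 8
        vdata = np.frombuffer(body[:vbytes], dtype="<f8").reshape(n_vertex, n_props)
        faces = np.empty((n_face, 3), dtype=np.int64)
        off = vbytes
        for i in range(n_face):
            cnt = body[off]
            off += 1
            faces[i] = np.frombuffer(body[off : off + 4 * cnt], dtype="<i4")[:3]
            off += 4 * cnt
    else:
        lines = body.decode("ascii").splitlines()
        vdata = np.array([[float(x) for x in ln.split()] for ln in lines[:n_vertex]])
        faces = np.array(
            [[int(x) for x in ln.split()[1:4]] for ln in lines[n_vertex : n_vertex + n_face]],
            dtype=np.int64,
        )
    vertices = vdata[:, :3]
    extra = {p: vdata[:, 3 + i].copy() for i, p in enumerate(vprops[3:])}
    return TriSurface(vertices, faces, role=role, vertex_data=extra)


def write_stl(path, surface: TriSurface) -> None:
    """Binary STL writer."""
    tri = surface.triangles()
    normals = surface.face_normals()
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 80)
        fh.write(struct.pack("<I", surface.n_faces))
        for n, t in zip(normals, tri):
            fh.write(np.asarray(n, dtype="<f4").tobytes())
            fh.write(np.asarray(t, dtype="<f4").tobytes())
            fh.write(b"\x00\x00")
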