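"""Surface validation: rigid ICP alignment, cropping and signed distances.

Mirrors the clinical validation workflow: the FEM-predicted skin surface
is rigidly aligned to the reference (postoperative) surface with
iterative closest point, regions unaffected by the surgery are sliced
away, and the per-vertex signed distance to the reference surface is
summarized (mean, SD) and exported as a colormap.

The distance is point-to-*triangle* (nearest point on the triangulated
reference surface, not nearest vertex), signed by the reference facet
normal: positive where the predicted surface lies outside the reference.
A vertex-to-vertex variant is available via ``method="vertex"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree


class CompareError(ValueError):
    """Degenerate surfaces or invalid comparison request."""


@dataclass
class SurfaceMesh:
    """Triangulated surface with optional per-vertex scalar field (mm)."""

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    scalar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if len(self.vertices) < 3:
            raise CompareError("surface needs at least 3 vertices")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise CompareError("face index out of range")
        if np.linalg.matrix_rank(self.vertices - self.vertices.mean(axis=0)) < 2:
            raise CompareError("surface vertices are collinear")

    def save(self, path) -> None:
        """Write STL or PLY (by extension) via trimesh, vertex order preserved."""
        trimesh.Trimesh(self.vertices, self.faces, process=False).export(str(path))

    @classmethod
    def load(cls, path) -> "SurfaceMesh":
        tm = trimesh.load(str(path), process=False, force="mesh")
        return cls(vertices=np.asarray(tm.vertices, dtype=float), faces=np.asarray(tm.faces))

    def face_normals(self) -> np.ndarray:
        v = self.vertices[self.faces]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return n


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (R orthonormal, det +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-10:
            raise CompareError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise CompareError("reflection is not a rigid transform")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_rotvec(rotvec).as_matrix(), np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self . other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class ICPResult:
    """Best rigid transform plus the per-iteration RMS trace."""

    transform: RigidTransform
    rms_history: list[float] = field(default_factory=list)

    @property
    def rms(self) -> float:
        return self.rms_history[-1]


def _kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform taking P onto Q (SVD)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, qc - R @ pc)


def icp_align(
    moving: SurfaceMesh,
    fixed: SurfaceMesh,
    max_iter: int = 100,
    tol: float = 1e-6,
    init: RigidTransform | None = None,
) -> ICPResult:
    """Point-to-point ICP of ``moving`` onto ``fixed``.

    Correspondences by nearest fixed vertex (KD-tree); the rigid update
    is the closed-form Kabsch fit, restricted to proper rotations.
    Initialized by centroid alignment unless ``init`` is given; stops
    when the RMS improves by less than ``tol`` mm or after ``max_iter``
    iterations. The RMS trace is non-increasing.
    """
    if len(moving.vertices) < 3 or len(fixed.vertices) < 3:
        raise CompareError("ICP needs at least 3 vertices on each surface")
    tree = cKDTree(fixed.vertices)
    P = moving.vertices
    if init is None:
        T = RigidTransform(np.eye(3), fixed.vertices.mean(axis=0) - P.mean(axis=0))
    else:
        T = init
    history: list[float] = []
    for _ in range(max_iter):
        _, idx = tree.query(T.apply(P))
        T = _kabsch(P, fixed.vertices[idx])
        rms = float(np.sqrt(np.mean(np.sum((T.apply(P) - fixed.vertices[idx]) ** 2, axis=1))))
        history.append(rms)
        if len(history) > 1 and history[-2] - history[-1] < tol:
            break
    return ICPResult(transform=T, rms_history=history)


def crop_unaffected(
    surface: SurfaceMesh, displacements: np.ndarray, threshold: float = 0.1
) -> tuple[SurfaceMesh, np.ndarray]:
    """Slice away surface regions unaffected by the surgical displacement.

    Keeps vertices whose displacement magnitude is >= ``threshold`` mm
    and the triangles whose three vertices all survive. Returns the
    cropped surface and the indices of the surviving vertices.
    """
    u = np.asarray(displacements, dtype=float)
    mag = np.linalg.norm(u, axis=1) if u.ndim == 2 else np.abs(u)
    if len(mag) != len(surface.vertices):
        raise CompareError("displacement field must be defined on all surface vertices")
    keep = mag >= threshold
    if keep.sum() < 3:
        raise CompareError(f"no affected surface at threshold {threshold} mm")
    remap = -np.ones(len(surface.vertices), dtype=np.int64)
    kept_idx = np.flatnonzero(keep)
    remap[kept_idx] = np.arange(len(kept_idx))
    face_keep = keep[surface.faces].all(axis=1)
    scalar = surface.scalar[kept_idx] if surface.scalar is not None else None
    cropped = SurfaceMesh(
        vertices=surface.vertices[kept_idx],
        faces=remap[surface.faces[face_keep]],
        scalar=scalar,
    )
    return cropped, kept_idx


@dataclass
class DistanceMap:
    """Per-vertex signed distance (mm) with its mean / sample-SD summary."""

    distances: np.ndarray
    mean: float
    sd: float

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "DistanceMap":
        d = np.asarray(d, dtype=float)
        sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
        return cls(distances=d, mean=float(d.mean()), sd=sd)

    @property
    def n_vertices(self) -> int:
        return len(self.distances)


def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distances from each point to each triangle, plus closest points.

    ``tri`` is (m, 3, 3). Returns (n, m) distances and (n, m, 3) closest
    points. The nearest point on a triangle is the in-plane projection
    when its barycentric coordinates are inside, otherwise the nearest
    point on one of the three edges.
    """
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    n = np.cross(v1 - v0, v2 - v0)  # (m, 3)
    nn = np.einsum("ij,ij->i", n, n)
    w = points[:, None, :] - v0[None, :, :]  # (n, m, 3)
    # plane projection and barycentric inside test
    dist_plane = np.einsum("nmj,mj->nm", w, n) / nn  # signed height / |n|^2 * |n|... scaled
    proj = points[:, None, :] - dist_plane[:, :, None] * n[None, :, :]
    # barycentric coordinates of proj
    d00 = np.einsum("mj,mj->m", v1 - v0, v1 - v0)
    d01 = np.einsum("mj,mj->m", v1 - v0, v2 - v0)
    d11 = np.einsum("mj,mj->m", v2 - v0, v2 - v0)
    pw = proj - v0[None, :, :]
    d20 = np.einsum("nmj,mj->nm", pw, v1 - v0)
    d21 = np.einsum("nmj,mj->nm", pw, v2 - v0)
    denom = d00 * d11 - d01 * d01
    bv = (d11 * d20 - d01 * d21) / denom
    bw = (d00 * d21 - d01 * d20) / denom
    inside = (bv >= 0) & (bw >= 0) & (bv + bw <= 1)

    best = np.where(inside, np.linalg.norm(points[:, None, :] - proj, axis=2), np.inf)
    closest = np.where(inside[:, :, None], proj, np.nan)
    # edges
    for a, b in ((v0, v1), (v1, v2), (v2, v0)):
        ab = b - a  # (m, 3)
        t = np.einsum("nmj,mj->nm", points[:, None, :] - a[None, :, :], ab) / np.einsum(
            "mj,mj->m", ab, ab
        )
        t = np.clip(t, 0.0, 1.0)
        cand = a[None, :, :] + t[:, :, None] * ab[None, :, :]
        d = np.linalg.norm(points[:, None, :] - cand, axis=2)
        better = d < best
        best = np.where(better, d, best)
        closest = np.where(better[:, :, None], cand, closest)
    return best, closest


def signed_distance(
    pred: SurfaceMesh, ref: SurfaceMesh, method: str = "triangle", chunk: int = 256
) -> DistanceMap:
    """Signed distance from each predicted vertex to the reference surface.

    ``method="triangle"`` (default) finds the nearest point on the
    reference triangulation; ``method="vertex"`` uses nearest reference
    vertices only. The sign is that of the offset along the reference
    facet normal at the nearest point: positive outside. Degenerate
    (zero-area) reference triangles are skipped.
    """
    points = pred.vertices
    if method == "vertex":
        tree = cKDTree(ref.vertices)
        dist, idx = tree.query(points)
        # sign from area-weighted vertex normals
        fn = ref.face_normals()
        vn = np.zeros_like(ref.vertices)
        for k in range(3):
            np.add.at(vn, ref.faces[:, k], fn)
        offset = points - ref.vertices[idx]
        sign = np.where(np.einsum("ij,ij->i", offset, vn[idx]) < 0, -1.0, 1.0)
        return DistanceMap.from_distances(sign * dist)
    if method != "triangle":
        raise CompareError(f"unknown method {method!r}")

    tri = ref.vertices[ref.faces]
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    ok = areas > 1e-12
    if not ok.any():
        raise CompareError("all reference triangles are degenerate")
    tri = tri[ok]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    out = np.empty(len(points))
    for start in range(0, len(points), chunk):
        pts = points[start : start + chunk]
        d, cp = _point_triangle_distances(pts, tri)
        j = np.argmin(d, axis=1)
        rows = np.arange(len(pts))
        nearest = cp[rows, j]
        offset = pts - nearest
        sign = np.where(np.einsum("ij,ij->i", offset, normals[j]) < 0, -1.0, 1.0)
        out[start : start + chunk] = sign * d[rows, j]
    return DistanceMap.from_distances(out)


# ---------------------------------------------------------------------------
# colormap export


def _diverging_colors(values: np.ndarray, limit: float) -> np.ndarray:
    """Symmetric diverging RGB colors about zero, uint8."""
    import matplotlib
    from matplotlib import colors

    norm = colors.Normalize(vmin=-limit, vmax=limit)
    rgba = matplotlib.colormaps["RdBu_r"](norm(values))
    return (rgba[:, :3] * 255).astype(np.uint8)


def export_colormap(
    surface: SurfaceMesh,
    dmap: DistanceMap,
    ply_path,
    vtk_path=None,
    csv_path=None,
    limit: float | None = None,
) -> None:
    """Write the surface with its signed-distance map.

    The PLY carries a per-vertex ``quality`` scalar (the distance, mm)
    plus diverging colors on a symmetric scale about zero (limits default
    to +/- max |d|); optional legacy-VTK and CSV (vertex_id, d_mm)
    companions.
    """
    if len(dmap.distances) != len(surface.vertices):
        raise CompareError("distance map is not defined on every surface vertex")
    if limit is None:
        limit = float(np.abs(dmap.distances).max()) or 1.0
    colors = _diverging_colors(dmap.distances, limit)
    with open(ply_path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(surface.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write(f"element face {len(surface.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, q, c in zip(surface.vertices, dmap.distances, colors):
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {q:.9g} {c[0]} {c[1]} {c[2]}\n")
        for f in surface.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    if vtk_path is not None:
        from .io import write_vtk_surface

        write_vtk_surface(surface, vtk_path, point_scalars={"signed_distance_mm": dmap.distances})
    if csv_path is not None:
        import pandas as pd

        pd.DataFrame(
            {"vertex_id": np.arange(len(dmap.distances)), "d_mm": dmap.distances}
        ).to_csv(csv_path, index=False)


def read_ply_quality(path) -> tuple[SurfaceMesh, np.ndarray]:
    """Read back a PLY written by :func:`export_colormap` (scalar round-trip)."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise CompareError(f"{path} is not a PLY file")
        n_vert = n_face = 0
        while True:
            line = fh.readline().strip()
            if line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.empty((n_vert, 3))
        quality = np.empty(n_vert)
        for i in range(n_vert):
            parts = fh.readline().split()
            verts[i] = [float(p) for p in parts[:3]]
            quality[i] = float(parts[3])
        faces = np.empty((n_face, 3), dtype=np.int64)
        for i in range(n_face):
            faces[i] = [int(p) for p in fh.readline().split()[1:4]]
    return SurfaceMesh(vertices=verts, faces=faces, scalar=quality), quality
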