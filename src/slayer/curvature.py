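"""Discrete Gaussian curvature on cell-surface triangle meshes.

Gaussian curvature K — the product of the two principal curvatures — is
zero on developable regions (the cylindrical cell body), positive on
sphere-like caps (the poles), and concentrates crystal-lattice defects
where |K| is large.  On a triangle mesh K is estimated per vertex by the
angle-deficit scheme

    K_v = (2 pi - sum of incident triangle angles at v) / A_v

with A_v the barycentric vertex area (one third of the incident triangle
areas).  The scheme satisfies the discrete Gauss-Bonnet theorem exactly:
on a closed genus-0 mesh the area-weighted total curvature is 4 pi to
machine precision, independent of the triangulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


@dataclass
class CurvedMesh:
    """Triangle mesh (nm) with optional per-vertex Gaussian curvature."""

    vertices: np.ndarray               # (V, 3) nm
    faces: np.ndarray                  # (F, 3) int
    K: np.ndarray | None = None        # 1/nm^2 per vertex
    vertex_area: np.ndarray | None = None   # nm^2 per vertex
    is_closed: bool = True
    boundary_vertices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))

    @property
    def euler_characteristic(self) -> int:
        edges = np.sort(np.vstack([self.faces[:, [0, 1]],
                                   self.faces[:, [1, 2]],
                                   self.faces[:, [2, 0]]]), axis=1)
        n_edges = np.unique(edges, axis=0).shape[0]
        return self.vertices.shape[0] - n_edges + self.faces.shape[0]

    @property
    def total_curvature(self) -> float:
        """Area-weighted integral of K (4 pi on closed genus-0 meshes)."""
        if self.K is None:
            raise ValueError("curvature not computed")
        return float(np.nansum(self.K * self.vertex_area))

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


def from_trimesh(mesh: trimesh.Trimesh) -> CurvedMesh:
    """Wrap a validated trimesh object (no curvature yet)."""
    boundary = _boundary_vertices(mesh.faces)
    return CurvedMesh(np.asarray(mesh.vertices, dtype=float),
                      np.asarray(mesh.faces, dtype=int),
                      is_closed=bool(mesh.is_watertight),
                      boundary_vertices=boundary)


def load_mesh(path) -> CurvedMesh:
    """Load and validate a PLY/OFF/OBJ surface mesh.

    Non-manifold or unreadable files raise ``ValueError`` naming the
    defect; meshes with boundary load but are flagged non-closed (boundary
    vertices then use the pi angle-deficit convention).
    """
    try:
        mesh = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:
        raise ValueError(f"unreadable mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or mesh.faces.shape[0] == 0:
        raise ValueError(f"{path}: no triangle faces found")
    # manifold check: every edge in at most two faces
    edges = np.sort(mesh.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts > 2):
        raise ValueError(f"{path}: non-manifold (edge shared by > 2 faces)")
    if not mesh.is_winding_consistent:
        raise ValueError(f"{path}: inconsistent face winding")
    return from_trimesh(mesh)


def _boundary_vertices(faces) -> np.ndarray:
    faces = np.asarray(faces)
    edges = np.sort(np.vstack([faces[:, [0, 1]], faces[:, [1, 2]],
                               faces[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


def gaussian_curvature(mesh: CurvedMesh,
                       area_scheme: str = "barycentric") -> CurvedMesh:
    """Per-vertex angle-deficit Gaussian curvature (in place, returned).

    Interior vertices use ``K = (2 pi - sum angles) / A``; boundary
    vertices use pi in place of 2 pi (geodesic curvature convention).
    ``area_scheme`` is ``"barycentric"`` (default; exact Gauss-Bonnet) or
    ``"mixed"`` (Meyer-style Voronoi area with obtuse-triangle fallback).
    Vertices with a zero-area star get ``K = nan``.
    """
    V = mesh.vertices
    F = mesh.faces
    nv = V.shape[0]

    tri = V[F]                                   # (F, 3, 3)
    angles = np.empty((F.shape[0], 3))
    for i in range(3):
        a = tri[:, (i + 1) % 3] - tri[:, i]
        b = tri[:, (i + 2) % 3] - tri[:, i]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.einsum("ij,ij->i", a, b) / np.maximum(na * nb, 1e-300)
        angles[:, i] = np.arccos(np.clip(cosang, -1.0, 1.0))
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    f_area = 0.5 * np.linalg.norm(cross, axis=1)

    angle_sum = np.zeros(nv)
    np.add.at(angle_sum, F.ravel(), angles.ravel())

    area = np.zeros(nv)
    if area_scheme == "barycentric":
        np.add.at(area, F.ravel(), np.repeat(f_area / 3.0, 3))
    elif area_scheme == "mixed":
        area = _mixed_voronoi_area(tri, angles, f_area, F, nv)
    else:
        raise ValueError(f"unknown area scheme {area_scheme!r}")

    full_angle = np.full(nv, 2.0 * np.pi)
    full_angle[mesh.boundary_vertices] = np.pi
    deficit = full_angle - angle_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(area > 0, deficit / area, np.nan)
    mesh.K = K
    mesh.vertex_area = area
    return mesh


def _mixed_voronoi_area(tri, angles, f_area, F, nv):
    """Meyer mixed area: Voronoi for non-obtuse triangles, else T/2 or T/4."""
    area = np.zeros(nv)
    cot = 1.0 / np.tan(np.clip(angles, 1e-12, np.pi - 1e-12))
    obtuse = angles.max(axis=1) > np.pi / 2.0
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        e_ij = np.sum((tri[:, i] - tri[:, j]) ** 2, axis=1)
        e_ik = np.sum((tri[:, i] - tri[:, k]) ** 2, axis=1)
        voronoi = (e_ij * cot[:, k] + e_ik * cot[:, j]) / 8.0
        obtuse_at_i = obtuse & (angles[:, i] > np.pi / 2.0)
        contrib = np.where(~obtuse, voronoi,
                           np.where(obtuse_at_i, f_area / 2.0, f_area / 4.0))
        np.add.at(area, F[:, i], contrib)
    return area


def curvature_profile(mesh: CurvedMesh, axis=(1.0, 0.0, 0.0),
                      n_bins: int = 40) -> np.ndarray:
    """Area-weighted mean |K| in equi-length bins along an axis direction.

    Uses the same 40-bin normalized-axis convention as the image profile
    pipeline; bins with no vertices are NaN.
    """
    if mesh.K is None:
        raise ValueError("compute gaussian_curvature first")
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    s = mesh.vertices @ u
    s = (s - s.min()) / max(s.max() - s.min(), 1e-300)
    bins = np.minimum((s * n_bins).astype(int), n_bins - 1)
    prof = np.full(n_bins, np.nan)
    w = mesh.vertex_area
    absk = np.abs(mesh.K)
    ok = np.isfinite(absk)
    for b in range(n_bins):
        sel = (bins == b) & ok
        if sel.any():
            prof[b] = float(np.sum(absk[sel] * w[sel]) / np.sum(w[sel]))
    return prof
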