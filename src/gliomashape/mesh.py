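"""Triangle-mesh container and geometry kernels.

All coordinates are world millimetres.  Meshes come from iso-surfacing
binary masks (:func:`gliomashape.shape_metrics.extract_surface`) but the
operations here are generic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = ["SurfaceMesh", "point_triangle_distance", "point_mesh_distance"]

#: triangles with area below this (mm^2) are dropped as degenerate
DEGENERATE_AREA = 1e-12


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface in millimetre world coordinates.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Vertex-index triples; consistent outward winding is assumed for
        signed-volume computation.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- derived quantities -------------------------------------------------

    @cached_property
    def _corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        f = self.faces
        return self.vertices[f[:, 0]], self.vertices[f[:, 1]], self.vertices[f[:, 2]]

    @cached_property
    def triangle_areas(self) -> np.ndarray:
        a, b, c = self._corners
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @cached_property
    def triangle_centroids(self) -> np.ndarray:
        a, b, c = self._corners
        return (a + b + c) / 3.0

    @cached_property
    def triangle_normals(self) -> np.ndarray:
        """Unit normals; direction follows the face winding."""
        a, b, c = self._corners
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(norm > 0, norm, 1.0)

    @property
    def area(self) -> float:
        """Total surface area, mm^2."""
        return float(self.triangle_areas.sum())

    @property
    def volume(self) -> float:
        """Enclosed volume by the divergence theorem, mm^3 (needs closed mesh)."""
        a, b, c = self._corners
        return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)

    # -- topology -----------------------------------------------------------

    @cached_property
    def _edges(self) -> np.ndarray:
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        return np.sort(e, axis=1)

    def is_closed(self) -> bool:
        """True iff every edge is shared by exactly two triangles."""
        if not len(self.faces):
            return False
        _, counts = np.unique(self._edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def n_components(self) -> int:
        e = self._edges
        g = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])),
            shape=(len(self.vertices), len(self.vertices)),
        )
        n, labels = connected_components(g, directed=False)
        # count only components that own at least one face vertex
        used = np.unique(self.faces)
        return int(np.unique(labels[used]).size)

    def cleaned(self) -> "SurfaceMesh":
        """Drop degenerate (near-zero-area) triangles."""
        keep = self.triangle_areas > DEGENERATE_AREA
        if keep.all():
            return self
        return SurfaceMesh(self.vertices, self.faces[keep])


def point_triangle_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Euclidean distance from each point to its paired triangle (a, b, c).

    Vectorized closest-point-on-triangle (Ericson, *Real-Time Collision
    Detection*, 5.1.5).  All inputs are (n, 3).
    """
    points = np.atleast_2d(points)
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)
    vc = d1 * d4 - d3 * d2
    m_ab = ~(m_a | m_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    vb = d5 * d2 - d1 * d6
    m_ac = ~(m_a | m_c | m_ab) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    va = d3 * d6 - d5 * d4
    m_bc = ~(m_b | m_c | m_ab | m_ac) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    q = np.empty_like(points)
    q[m_a] = a[m_a]
    q[m_b] = b[m_b]
    q[m_c] = c[m_c]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
        q[m_ab] = a[m_ab] + t[m_ab, None] * ab[m_ab]
        t = d2 / (d2 - d6)
        q[m_ac] = a[m_ac] + t[m_ac, None] * ac[m_ac]
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        q[m_bc] = b[m_bc] + t[m_bc, None] * (c[m_bc] - b[m_bc])
        interior = ~(m_a | m_b | m_c | m_ab | m_ac | m_bc)
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    q[interior] = a[interior] + v[interior, None] * ab[interior] + w[interior, None] * ac[interior]
    return np.linalg.norm(points - q, axis=1)


def point_mesh_distance(
    points: np.ndarray, mesh: SurfaceMesh, max_dist: float = np.inf
) -> np.ndarray:
    """Distance from each point to the nearest point on ``mesh``.

    Exact within ``max_dist``; points farther than that from the surface
    get ``inf`` (cheap KD-tree pruning on triangle centroids).
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    cent = mesh.triangle_centroids
    tree = cKDTree(cent)
    # farthest centroid-to-corner distance bounds the pruning radius
    corners = np.stack(mesh._corners, axis=1)
    tri_radius = float(np.max(np.linalg.norm(corners - cent[:, None, :], axis=2)))

    out = np.full(len(points), np.inf)
    d_cent, _ = tree.query(points, k=1)
    # a point within max_dist of some triangle has a centroid within
    # max_dist + tri_radius
    if np.isfinite(max_dist):
        candidates = np.where(d_cent <= max_dist + tri_radius)[0]
        radius = max_dist + tri_radius
    else:
        candidates = np.arange(len(points))
        radius = float(d_cent.max()) + tri_radius + 1e-9

    if not len(candidates):
        return out
    a, b, c = mesh._corners
    neighbor_lists = tree.query_ball_point(points[candidates], r=radius)
    # flatten into (point, triangle) pairs for one vectorized kernel call
    pair_pt, pair_tri = [], []
    for i, lst in zip(candidates, neighbor_lists):
        pair_pt.extend([i] * len(lst))
        pair_tri.extend(lst)
    if not pair_pt:
        return out
    pair_pt = np.asarray(pair_pt)
    pair_tri = np.asarray(pair_tri)
    d = point_triangle_distance(points[pair_pt], a[pair_tri], b[pair_tri], c[pair_tri])
    np.minimum.at(out, pair_pt, d)
    return out
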