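"""Exact nearest-point queries against a triangle mesh.

Implements the standard closest-point-on-triangle projection (region
classification via barycentric signs, cf. Ericson, *Real-Time Collision
Detection*), vectorized over all point/triangle pairs in chunks.  Meshes in
this package are small (a few thousand faces), so exhaustive per-triangle
search is both exact and fast enough; no spatial index is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MeshQuery", "QueryResult", "closest_point_on_triangles"]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray):
    """Closest point on each of ``triangles`` (M, 3, 3) to each of
    ``points`` (P, 3).

    Returns ``(closest, dist2)`` with shapes (P, M, 3) and (P, M).
    """
    p = np.asarray(points, dtype=float)[:, None, :]           # (P,1,3)
    a = np.asarray(triangles, dtype=float)[None, :, 0, :]     # (1,M,3)
    b = np.asarray(triangles, dtype=float)[None, :, 1, :]
    c = np.asarray(triangles, dtype=float)[None, :, 2, :]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("pmi,pmi->pm", np.broadcast_arrays(ab, ap)[0], ap)
    d2 = np.einsum("pmi,pmi->pm", np.broadcast_arrays(ac, ap)[0], ap)

    bp = p - b
    d3 = np.einsum("pmi,pmi->pm", np.broadcast_arrays(ab, bp)[0], bp)
    d4 = np.einsum("pmi,pmi->pm", np.broadcast_arrays(ac, bp)[0], bp)

    cp = p - c
    d5 = np.einsum("pmi,pmi->pm", np.broadcast_arrays(ab, cp)[0], cp)
    d6 = np.einsum("pmi,pmi->pm", np.broadcast_arrays(ac, cp)[0], cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
        den = va + vb + vc
        v_in = np.where(den != 0, vb / den, 0.0)
        w_in = np.where(den != 0, vc / den, 0.0)

    # interior projection as the fallback, then overwrite edge/vertex regions
    closest = a + v_in[..., None] * ab + w_in[..., None] * ac

    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    cand = b + w_bc[..., None] * (c - b)
    closest = np.where(m_bc[..., None], cand, closest)

    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    cand = a + w_ac[..., None] * ac
    closest = np.where(m_ac[..., None], cand, closest)

    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    cand = a + v_ab[..., None] * ab
    closest = np.where(m_ab[..., None], cand, closest)

    m_c = (d6 >= 0) & (d5 <= d6)
    closest = np.where(m_c[..., None], np.broadcast_arrays(c, closest)[0], closest)
    m_b = (d3 >= 0) & (d4 <= d3)
    closest = np.where(m_b[..., None], np.broadcast_arrays(b, closest)[0], closest)
    m_a = (d1 <= 0) & (d2 <= 0)
    closest = np.where(m_a[..., None], np.broadcast_arrays(a, closest)[0], closest)

    diff = p - closest
    dist2 = np.einsum("pmi,pmi->pm", diff, diff)
    return closest, dist2


@dataclass
class QueryResult:
    """Nearest-surface-point query result for a batch of points."""

    closest: np.ndarray       # (P, 3) nearest point on the surface
    distance: np.ndarray      # (P,) unsigned distance, mm
    face_index: np.ndarray    # (P,) triangle hit
    barycentric: np.ndarray   # (P, 3) coordinates of the hit within its face
    on_boundary: np.ndarray   # (P,) True if the hit lies on a boundary edge


class MeshQuery:
    """Closest-point queries against a fixed triangle mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        if len(self.faces) == 0:
            raise ValueError("mesh has no faces")
        self.triangles = self.vertices[self.faces]            # (M, 3, 3)
        n = np.cross(self.triangles[:, 1] - self.triangles[:, 0],
                     self.triangles[:, 2] - self.triangles[:, 0])
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        self.face_normals = n / np.maximum(norms, 1e-300)
        self._boundary_edges = self._find_boundary_edges()

    def _find_boundary_edges(self) -> set:
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return {tuple(edge) for edge in uniq[counts == 1]}

    def query(self, points: np.ndarray, chunk: int = 128) -> QueryResult:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        closest = np.empty((n, 3))
        dist = np.empty(n)
        fidx = np.empty(n, dtype=np.int64)
        for lo in range(0, n, chunk):
            sub = pts[lo:lo + chunk]
            c, d2 = closest_point_on_triangles(sub, self.triangles)
            j = np.argmin(d2, axis=1)
            rows = np.arange(len(sub))
            closest[lo:lo + chunk] = c[rows, j]
            dist[lo:lo + chunk] = np.sqrt(d2[rows, j])
            fidx[lo:lo + chunk] = j
        bary = self._barycentric(closest, fidx)
        on_boundary = self._boundary_hits(bary, fidx)
        return QueryResult(closest, dist, fidx, bary, on_boundary)

    def _barycentric(self, pts: np.ndarray, fidx: np.ndarray) -> np.ndarray:
        tri = self.triangles[fidx]
        v0 = tri[:, 1] - tri[:, 0]
        v1 = tri[:, 2] - tri[:, 0]
        v2 = pts - tri[:, 0]
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d20 = np.einsum("ij,ij->i", v2, v0)
        d21 = np.einsum("ij,ij->i", v2, v1)
        den = d00 * d11 - d01 * d01
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(den != 0, (d11 * d20 - d01 * d21) / den, 1 / 3)
            w = np.where(den != 0, (d00 * d21 - d01 * d20) / den, 1 / 3)
        v = np.clip(v, 0.0, 1.0)
        w = np.clip(w, 0.0, 1.0 - v)
        return np.column_stack([1.0 - v - w, v, w])

    def _boundary_hits(self, bary: np.ndarray, fidx: np.ndarray,
                       tol: float = 1e-6) -> np.ndarray:
        """True where the hit lies on an open (boundary) edge of the mesh."""
        out = np.zeros(len(bary), dtype=bool)
        # barycentric ~ 0 on coordinate k means the hit is on the edge
        # opposite vertex k of its triangle
        opposite = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
        for k in range(3):
            on_edge = bary[:, k] <= tol
            if not on_edge.any():
                continue
            i0, i1 = opposite[k]
            fa = self.faces[fidx]
            for row in np.flatnonzero(on_edge):
                edge = tuple(sorted((fa[row, i0], fa[row, i1])))
                if edge in self._boundary_edges:
                    out[row] = True
        return out
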