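"""Low-level triangle-surface queries: closest point and ray casting.

These are the two geometric primitives the rest of the package needs from a
tagged boundary triangulation: projecting a point onto the surface (for
growing cables along the endocardium) and casting a ray through the wall
(for transmural extension of PVJ stems).  Both are vectorized over query
batches; candidate triangles for closest-point queries come from a k-d tree
over triangle centroids.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_point_on_triangles", "SurfaceMesh"]


def _closest_on_tri(p, a, b, c):
    """Closest point on triangles (a, b, c) to points p, all (n, 3).

    Standard region-classification algorithm (Voronoi regions of the
    triangle); fully vectorized, no degenerate-triangle guard beyond the
    caller filtering zero-area faces.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    result = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex region A
    m = (d1 <= 0) & (d2 <= 0)
    result[m] = a[m]
    done |= m

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    result[m] = b[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    result[m] = a[m] + v[m, None] * ab[m]
    done |= m

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    result[m] = c[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    result[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    result[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    result[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return result


def closest_point_on_triangles(points, tri_a, tri_b, tri_c):
    """Exact closest point of each query point over a *common* triangle set.

    Brute force over all triangles; used as the fallback and for small
    batches.  Returns (closest_points, distances, face_index).
    """
    points = np.atleast_2d(points)
    n, f = len(points), len(tri_a)
    best_d = np.full(n, np.inf)
    best_p = np.zeros((n, 3))
    best_f = np.zeros(n, dtype=np.intp)
    for j in range(f):
        a = np.broadcast_to(tri_a[j], (n, 3))
        b = np.broadcast_to(tri_b[j], (n, 3))
        c = np.broadcast_to(tri_c[j], (n, 3))
        q = _closest_on_tri(points, a, b, c)
        d = np.linalg.norm(points - q, axis=1)
        m = d < best_d
        best_d[m] = d[m]
        best_p[m] = q[m]
        best_f[m] = j
    return best_p, best_d, best_f


class SurfaceMesh:
    """A triangle surface with per-face tags supporting proximity and ray queries.

    Parameters
    ----------
    vertices : (V, 3) float array
    faces : (F, 3) int array, wound so the right-hand normal points outward
    """

    def __init__(self, vertices, faces):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.intp)
        tri = self.vertices[self.faces]
        self._a = tri[:, 0]
        self._b = tri[:, 1]
        self._c = tri[:, 2]
        cr = np.cross(self._b - self._a, self._c - self._a)
        self.face_areas = 0.5 * np.linalg.norm(cr, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.face_normals = cr / np.linalg.norm(cr, axis=1, keepdims=True)
        self.face_normals = np.nan_to_num(self.face_normals)
        self.centroids = (self._a + self._b + self._c) / 3.0
        self._tree = cKDTree(self.centroids)
        # how far any face can reach from its own centroid
        reach = np.stack(
            [
                np.linalg.norm(self._a - self.centroids, axis=1),
                np.linalg.norm(self._b - self.centroids, axis=1),
                np.linalg.norm(self._c - self.centroids, axis=1),
            ]
        )
        self._max_reach = float(reach.max()) if reach.size else 0.0

    # ---------------------------------------------------------------- proximity
    def closest_point(self, points, k=24):
        """Closest surface point for each query point.

        Candidate faces from the centroid k-d tree; a query is re-run against
        a larger candidate set when the best candidate distance cannot be
        certified (candidate centroid ball does not dominate the face reach).
        Returns (points_on_surface, distances, face_indices).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        f = len(self.faces)
        k = min(k, f)
        _, idx = self._tree.query(points, k=k)
        idx = np.atleast_2d(idx)
        flat_p = np.repeat(points, k, axis=0)
        flat_f = idx.ravel()
        q = _closest_on_tri(flat_p, self._a[flat_f], self._b[flat_f], self._c[flat_f])
        d = np.linalg.norm(flat_p - q, axis=1).reshape(n, k)
        j = np.argmin(d, axis=1)
        rows = np.arange(n)
        best_d = d[rows, j]
        best_f = idx[rows, j]
        best_p = q.reshape(n, k, 3)[rows, j]
        if k < f:
            # certification: a face whose centroid is farther than
            # best_d + max_reach cannot contain a closer point
            worst_centroid = np.linalg.norm(
                points - self.centroids[idx[:, -1]], axis=1
            )
            bad = worst_centroid < best_d + self._max_reach
            if np.any(bad):
                p2, d2, f2 = closest_point_on_triangles(
                    points[bad], self._a, self._b, self._c
                )
                best_p[bad] = p2
                best_d[bad] = d2
                best_f[bad] = f2
        return best_p, best_d, best_f

    # ---------------------------------------------------------------- rays
    def ray_hits(self, origins, directions, min_t=1e-9):
        """First intersection of each ray with the surface (Moller-Trumbore).

        Returns (hit_points, t_values, face_indices); rays that miss get
        t = inf and face = -1.  Vectorized rays x faces, chunked over rays.
        """
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        n = len(origins)
        out_t = np.full(n, np.inf)
        out_f = np.full(n, -1, dtype=np.intp)
        e1 = self._b - self._a
        e2 = self._c - self._a
        chunk = max(1, int(2e6 / max(1, len(self.faces))))
        for s in range(0, n, chunk):
            o = origins[s : s + chunk][:, None, :]
            d = directions[s : s + chunk][:, None, :]
            h = np.cross(d, e2[None, :, :])
            det = np.einsum("rfk,fk->rf", h, e1)
            with np.errstate(invalid="ignore", divide="ignore"):
                inv = 1.0 / det
            sv = o - self._a[None, :, :]
            u = np.einsum("rfk,rfk->rf", sv, h) * inv
            qv = np.cross(sv, e1[None, :, :])
            v = np.einsum("rfk,rfk->rf", qv, np.broadcast_to(d, qv.shape)) * inv
            t = np.einsum("rfk,fk->rf", qv, e2) * inv
            eps = 1e-12
            valid = (
                (np.abs(det) > eps)
                & (u >= -1e-9)
                & (v >= -1e-9)
                & (u + v <= 1 + 1e-9)
                & (t > min_t)
            )
            t = np.where(valid, t, np.inf)
            jf = np.argmin(t, axis=1)
            rr = np.arange(t.shape[0])
            tt = t[rr, jf]
            out_t[s : s + chunk] = tt
            out_f[s : s + chunk] = np.where(np.isfinite(tt), jf, -1)
        hit = origins + out_t[:, None] * directions
        return hit, out_t, out_f
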