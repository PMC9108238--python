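"""Low-level mesh geometry kernels.

Vectorized ray/triangle intersection (Möller–Trumbore) and closest-point-on-
triangle queries with KD-tree candidate pruning. These back the surface
correspondence and centerline code; they are internal and operate on raw
vertex/face arrays in mm.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

_EPS = 1e-12


def polygon_area_centroid_2d(pts: np.ndarray) -> tuple[float, np.ndarray]:
    """Shoelace area (positive, orientation-independent) and area centroid of a
    simple closed polygon given as (n, 2) vertices (unclosed or closed)."""
    p = np.asarray(pts, dtype=float)
    if np.allclose(p[0], p[-1]):
        p = p[:-1]
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a2 = cross.sum()
    if abs(a2) < _EPS:
        return 0.0, p.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (3.0 * a2)
    cy = ((y + yn) * cross).sum() / (3.0 * a2)
    return abs(a2) / 2.0, np.array([cx, cy])


def plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed orthonormal (u, v) spanning the plane with the given normal."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def to_plane_coords(points3d: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    u, v = plane_basis(normal)
    rel = np.asarray(points3d, dtype=float) - np.asarray(origin, dtype=float)
    return np.column_stack([rel @ u, rel @ v])


class TriangleQuery:
    """Ray-casting and closest-point queries against a fixed triangle soup.

    Candidate triangles are pruned with a KD-tree over triangle centroids; the
    pruning radius accounts for the largest triangle circumradius so no hit
    inside the query radius can be missed.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tri = self.vertices[self.faces]  # (m, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        radii = np.sqrt(((self.tri - self.centroids[:, None, :]) ** 2).sum(axis=2)).max(axis=1)
        self._tri_radius = float(radii.max())
        # oversized triangles (cap fans etc.) would inflate the pruning
        # radius; keep them as unconditional candidates instead
        cut = 3.0 * max(float(np.median(radii)), 1e-9)
        self._big = np.flatnonzero(radii > cut)
        if len(self._big) > 0.05 * len(radii):  # too many to special-case
            self._big = np.empty(0, dtype=np.int64)
            self._prune_radius = self._tri_radius
        else:
            small = radii <= cut
            self._prune_radius = float(radii[small].max()) if small.any() else self._tri_radius
        self._tree = cKDTree(self.centroids)

    # -- Möller–Trumbore -------------------------------------------------
    def _ray_hits(self, origin: np.ndarray, direction: np.ndarray, cand: np.ndarray,
                  two_sided: bool = False):
        """Return (t values, triangle ids, barycentric (w0,w1,w2)) of all hits
        with t >= -eps among candidate triangles (any t if ``two_sided``)."""
        tri = self.tri[cand]
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        pvec = np.cross(direction, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > _EPS
        inv = np.zeros_like(det)
        inv[ok] = 1.0 / det[ok]
        tvec = origin - tri[:, 0]
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = (qvec @ direction) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        bary_eps = 1e-9
        hit = ok & (u >= -bary_eps) & (v >= -bary_eps) & (u + v <= 1.0 + bary_eps)
        if not two_sided:
            hit &= t >= -1e-9
        return t[hit], cand[hit], np.column_stack([1.0 - u[hit] - v[hit], u[hit], v[hit]])

    def ray_nearest(self, origin: np.ndarray, direction: np.ndarray, max_dist: float):
        """Nearest intersection along ``origin + t*direction`` with 0 <= t <= max_dist.

        Returns (t, face_id, barycentric) or None. ``direction`` must be unit.
        """
        # candidate triangles: centroid within max_dist of the segment
        n_samp = max(2, int(np.ceil(max_dist / max(self._tri_radius, 1e-6))) + 1)
        samples = origin[None, :] + np.linspace(0.0, max_dist, n_samp)[:, None] * direction[None, :]
        cand_lists = self._tree.query_ball_point(samples, self._tri_radius * 1.5 + max_dist / (n_samp - 1))
        cand = np.unique(np.concatenate([np.asarray(c, dtype=np.int64) for c in cand_lists])) \
            if any(len(c) for c in cand_lists) else np.empty(0, dtype=np.int64)
        if cand.size == 0:
            return None
        t, fid, bary = self._ray_hits(origin, direction, cand)
        keep = t <= max_dist + 1e-9
        if not np.any(keep):
            return None
        t, fid, bary = t[keep], fid[keep], bary[keep]
        i = int(np.argmin(t))
        return float(t[i]), int(fid[i]), bary[i]

    # -- closest point ---------------------------------------------------
    def closest_point(self, points: np.ndarray):
        """Closest point on the surface for each query point.

        Returns (points_on_surface (n,3), distances (n,), face_ids (n,),
        barycentric (n,3)). Brute force over KD-pruned candidates.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        out_p = np.empty((n, 3))
        out_d = np.empty(n)
        out_f = np.empty(n, dtype=np.int64)
        out_b = np.empty((n, 3))
        d_near, _ = self._tree.query(pts)
        for i, (p, dn) in enumerate(zip(pts, d_near)):
            r = dn + 2.0 * self._tri_radius
            cand = np.asarray(self._tree.query_ball_point(p, r), dtype=np.int64)
            if cand.size == 0:  # pragma: no cover - radius always finds >=1
                cand = np.arange(len(self.tri))
            cp, bary = _closest_on_triangles(self.tri[cand], p)
            d = np.linalg.norm(cp - p, axis=1)
            j = int(np.argmin(d))
            out_p[i], out_d[i], out_f[i], out_b[i] = cp[j], d[j], cand[j], bary[j]
        return out_p, out_d, out_f, out_b

    def signed_normal_distance(self, origins: np.ndarray, normals: np.ndarray,
                               cutoff: float):
        """Signed distance to the surface along ±normal for each origin.

        Positive when the nearest hit lies along +normal. Falls back to the
        (normal-sign-signed) closest point beyond ``cutoff``; fallback entries
        are flagged. Returns (signed_d, face_ids, barycentric, fallback_mask).
        """
        origins = np.asarray(origins, dtype=float)
        normals = np.asarray(normals, dtype=float)
        n = len(origins)
        d = np.full(n, np.nan)
        fid = np.zeros(n, dtype=np.int64)
        bary = np.full((n, 3), 1.0 / 3.0)
        fallback = np.ones(n, dtype=bool)
        cand_all = self._tree.query_ball_point(
            origins, cutoff + 1.5 * self._prune_radius, return_sorted=False)
        big = self._big
        counts = np.array([len(c) + len(big) for c in cand_all])
        if counts.sum() > 0:
            flat_cand = np.concatenate(
                [np.concatenate([np.asarray(c, dtype=np.int64), big])
                 for c in cand_all])
            row_origin = np.repeat(np.arange(n), counts)
            best_t = np.full(n, np.inf)  # |t| of current best
            chunk = 500_000
            for lo in range(0, len(flat_cand), chunk):
                sl = slice(lo, lo + chunk)
                rows = row_origin[sl]
                t, b, valid = _mt_flat(origins[rows], normals[rows],
                                       self.tri[flat_cand[sl]])
                valid &= np.abs(t) <= cutoff
                if not np.any(valid):
                    continue
                rows_v = rows[valid]
                t_v = t[valid]
                b_v = b[valid]
                c_v = flat_cand[sl][valid]
                # nearest |t| per origin within this chunk, then merge
                order = np.lexsort((np.abs(t_v), rows_v))
                first = np.ones(len(order), dtype=bool)
                first[1:] = rows_v[order][1:] != rows_v[order][:-1]
                pick = order[first]
                rows_p = rows_v[pick]
                better = np.abs(t_v[pick]) < best_t[rows_p]
                upd = rows_p[better]
                best_t[upd] = np.abs(t_v[pick][better])
                d[upd] = t_v[pick][better]
                fid[upd] = c_v[pick][better]
                bary[upd] = b_v[pick][better]
                fallback[upd] = False
        if np.any(fallback):
            idx = np.flatnonzero(fallback)
            cp, dist, f, b = self.closest_point(origins[idx])
            sign = np.sign(np.einsum("ij,ij->i", cp - origins[idx], normals[idx]))
            sign[sign == 0] = 1.0
            d[idx] = sign * dist
            fid[idx] = f
            bary[idx] = b
        return d, fid, bary, fallback


def _mt_flat(origins: np.ndarray, directions: np.ndarray, tri: np.ndarray):
    """Row-wise Möller–Trumbore: ray i (origin, unit direction) against
    triangle i. Returns (t, barycentric (m,3), valid) with t signed (hits
    behind the origin have t < 0)."""
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(directions, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > _EPS
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    tvec = origins - tri[:, 0]
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,ij->i", qvec, directions) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    bary_eps = 1e-9
    valid = ok & (u >= -bary_eps) & (v >= -bary_eps) & (u + v <= 1.0 + bary_eps)
    bary = np.column_stack([1.0 - u - v, u, v])
    return t, bary, valid


def _closest_on_triangles(tri: np.ndarray, p: np.ndarray):
    """Closest point to ``p`` on each triangle of ``tri`` (m,3,3).

    Returns (points (m,3), barycentric (m,3)). Ericson's region method,
    vectorized.
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
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)

    m = len(tri)
    bary = np.zeros((m, 3))
    done = np.zeros(m, dtype=bool)

    # vertex regions
    reg = (d1 <= 0) & (d2 <= 0)
    bary[reg] = [1.0, 0.0, 0.0]
    done |= reg
    reg = (~done) & (d3 >= 0) & (d4 <= d3)
    bary[reg] = [0.0, 1.0, 0.0]
    done |= reg
    reg = (~done) & (d6 >= 0) & (d5 <= d6)
    bary[reg] = [0.0, 0.0, 1.0]
    done |= reg

    # edge AB
    vc = d1 * d4 - d3 * d2
    reg = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(np.abs(d1 - d3) > _EPS, d1 / (d1 - d3), 0.0)
    bary[reg, 0] = 1.0 - v[reg]
    bary[reg, 1] = v[reg]
    done |= reg
    # edge AC
    vb = d5 * d2 - d1 * d6
    reg = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(np.abs(d2 - d6) > _EPS, d2 / (d2 - d6), 0.0)
    bary[reg, 0] = 1.0 - w[reg]
    bary[reg, 2] = w[reg]
    done |= reg
    # edge BC
    va = d3 * d6 - d5 * d4
    reg = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(np.abs(denom) > _EPS, (d4 - d3) / denom, 0.0)
    bary[reg, 1] = 1.0 - w[reg]
    bary[reg, 2] = w[reg]
    done |= reg

    # interior
    reg = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(np.abs(denom) > _EPS, vb / denom, 1.0 / 3.0)
        w = np.where(np.abs(denom) > _EPS, vc / denom, 1.0 / 3.0)
    bary[reg, 0] = 1.0 - v[reg] - w[reg]
    bary[reg, 1] = v[reg]
    bary[reg, 2] = w[reg]

    pts = bary[:, 0:1] * a + bary[:, 1:2] * b + bary[:, 2:3] * c
    return pts, bary
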