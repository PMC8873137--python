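"""Low-level geometric kernels shared across modules.

All routines are vectorised numpy working in millimetres. Queries against a
mesh are brute force over all triangles: the meshes handled here (icosphere
phantoms, segmented-surface stand-ins) are a few thousand faces, for which a
spatial index buys nothing.
"""

from __future__ import annotations

import numpy as np
from trimesh.triangles import closest_point as _tri_closest_point

__all__ = [
    "closest_point_on_mesh",
    "rays_occluded",
    "point_to_segments_distance",
    "polyline_min_distance",
    "segment_to_segment_distance",
    "rotation_about_axis",
]

_EPS = 1e-12


def closest_point_on_mesh(
    vertices: np.ndarray, faces: np.ndarray, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest point on a triangle mesh for each query point.

    Parameters
    ----------
    vertices, faces
        Mesh arrays, ``(V, 3)`` float and ``(F, 3)`` int.
    points
        Query points ``(N, 3)``.

    Returns
    -------
    (closest, distance, face_index)
        ``closest`` is ``(N, 3)``, ``distance`` ``(N,)``, ``face_index`` ``(N,)``
        the index of the triangle realising the minimum.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    triangles = vertices[faces]  # (F, 3, 3)
    n_tri = len(triangles)
    out_pts = np.empty_like(points)
    out_dist = np.empty(len(points))
    out_face = np.empty(len(points), dtype=np.int64)
    # per-query sweep over all triangles; chunk queries to bound memory
    for i, p in enumerate(points):
        cand = _tri_closest_point(triangles, np.broadcast_to(p, (n_tri, 3)))
        d2 = np.einsum("ij,ij->i", cand - p, cand - p)
        j = int(np.argmin(d2))
        out_pts[i] = cand[j]
        out_dist[i] = np.sqrt(d2[j])
        out_face[i] = j
    return out_pts, out_dist, out_face


def _moller_trumbore(
    origins: np.ndarray, directions: np.ndarray, triangles: np.ndarray
) -> np.ndarray:
    """Ray/triangle hit parameters.

    Returns ``t`` of shape ``(n_rays, n_tri)`` with ``np.inf`` where a ray
    misses the triangle. Rays are parameterised ``o + t*d`` with ``t >= eps``.
    """
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    # (R, T, 3) broadcasting
    d = directions[:, None, :]
    pvec = np.cross(d, e2[None, :, :])
    det = np.einsum("rtk,tk->rt", pvec, e1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = np.where(np.abs(det) > _EPS, 1.0 / det, np.nan)
        tvec = origins[:, None, :] - v0[None, :, :]
        u = np.einsum("rtk,rtk->rt", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("rk,rtk->rt", directions, qvec) * inv_det
        t = np.einsum("tk,rtk->rt", e2, qvec) * inv_det
    hit = (
        np.isfinite(t)
        & (u >= -1e-9)
        & (v >= -1e-9)
        & (u + v <= 1.0 + 1e-9)
        & (t > 1e-9)
    )
    return np.where(hit, t, np.inf)


def rays_occluded(
    vertices: np.ndarray,
    faces: np.ndarray,
    origins: np.ndarray,
    targets: np.ndarray,
    chunk: int = 256,
) -> np.ndarray:
    """Whether the open segment origin→target intersects the mesh.

    Returns a boolean array of length ``n_rays``; ``True`` means occluded.
    An empty mesh occludes nothing.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if len(faces) == 0:
        return np.zeros(len(origins), dtype=bool)
    triangles = vertices[faces]
    seg = targets - origins
    seg_len = np.linalg.norm(seg, axis=1)
    directions = seg / np.maximum(seg_len, _EPS)[:, None]
    occluded = np.zeros(len(origins), dtype=bool)
    for lo in range(0, len(origins), chunk):
        hi = lo + chunk
        t = _moller_trumbore(origins[lo:hi], directions[lo:hi], triangles)
        tmin = t.min(axis=1)
        occluded[lo:hi] = tmin < seg_len[lo:hi] - 1e-9
    return occluded


def point_to_segments_distance(
    points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray
) -> np.ndarray:
    """Distance from each point to the nearest of the given segments.

    ``points`` is ``(N, 3)``; ``seg_a``/``seg_b`` are ``(S, 3)`` segment
    endpoints. Returns ``(N,)`` minimum distances.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ab = seg_b - seg_a  # (S, 3)
    ab2 = np.maximum(np.einsum("ij,ij->i", ab, ab), _EPS)
    ap = points[:, None, :] - seg_a[None, :, :]  # (N, S, 3)
    t = np.clip(np.einsum("nsk,sk->ns", ap, ab) / ab2, 0.0, 1.0)
    proj = seg_a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def polyline_min_distance(points: np.ndarray, polyline: np.ndarray, closed: bool) -> np.ndarray:
    """Exact minimum distance from each point to a polyline (mm)."""
    polyline = np.asarray(polyline, dtype=float)
    if len(polyline) == 1:
        return np.linalg.norm(np.atleast_2d(points) - polyline[0], axis=1)
    a = polyline[:-1]
    b = polyline[1:]
    if closed:
        a = np.vstack([a, polyline[-1:]])
        b = np.vstack([b, polyline[:1]])
    return point_to_segments_distance(points, a, b)


def segment_to_segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between two 3D segments (Ericson clamp scheme)."""
    p1, q1, p2, q2 = (np.asarray(x, dtype=float) for x in (p1, q1, p2, q2))
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    if a <= _EPS and e <= _EPS:
        return float(np.linalg.norm(r))
    if a <= _EPS:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= _EPS:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > _EPS else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    return float(np.linalg.norm(p1 + s * d1 - (p2 + t * d2)))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis by an angle in degrees (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(th) * k + (1.0 - np.cos(th)) * (k @ k)
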