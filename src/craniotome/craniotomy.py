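"""Freehand craniotomy on a skull mesh.

The drawn polyline is projected onto the skull's outer surface, walked
along the mesh to collect the *barrier edges* it crosses, and the enclosed
patch is selected by breadth-first region growing from a seed face that
never crosses a barrier edge. The selected patch can then be excised.

Only the outer table of the skull participates: clinically the bone flap
is removed from the outside, and on the phantom shell the outer surface is
identified by face-centroid radius above the mean shell radius. For
arbitrary meshes a caller-supplied face selection replaces that heuristic.

The barrier is realised on mesh edges rather than by re-meshing along the
exact curve: region selection is face-granular, which is well below the
millimetre precision scale of freehand drawing.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ContourNotClosedError,
    GrowthLeakError,
    ProjectionError,
    SeedInvalidError,
    ValidationError,
)
from .geom import closest_point_on_mesh, point_to_segments_distance
from .geometry_io import SurfaceContour, TriangleMesh

DEFAULT_SNAP_TOL_MM = 0.5
DEFAULT_LEAK_FRACTION = 0.5

Edge = tuple[int, int]


@dataclass
class ProjectedContour:
    """A drawn contour snapped to the skull surface.

    ``barrier_edges`` are the mesh edges (sorted vertex-index pairs)
    crossed by the projected path; when the contour is closed they separate
    the outer surface into an inside and an outside component.
    """

    contour: SurfaceContour
    barrier_edges: frozenset[Edge]
    closed: bool
    snap_tol_mm: float = DEFAULT_SNAP_TOL_MM
    path_faces: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


@dataclass
class CraniotomyRegion:
    """Faces of the outer surface enclosed by a projected contour."""

    face_ids: frozenset[int]
    seed_face: int
    area_mm2: float

    def __post_init__(self) -> None:
        # an empty region (no-op excision) carries seed_face = -1
        if self.face_ids and self.seed_face not in self.face_ids:
            raise ValidationError("seed face must belong to the region")


def outer_surface_faces(skull: TriangleMesh, face_labels: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of outer-table faces.

    With ``face_labels`` given (boolean per face) it is used directly;
    otherwise faces whose centroid radius (about the vertex centroid)
    exceeds the mean centroid radius are taken as the outer surface — the
    shell-phantom heuristic.
    """
    if face_labels is not None:
        mask = np.asarray(face_labels, dtype=bool)
        if mask.shape != (len(skull.faces),):
            raise ValidationError("face_labels must have one entry per face")
        return mask
    centre = skull.vertices.mean(axis=0)
    radii = np.linalg.norm(skull.face_centroids() - centre, axis=1)
    return radii > radii.mean()


def _face_adjacency(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """(pairs, shared_edges): adjacent face index pairs and their shared edge."""
    tm = mesh.to_trimesh()
    return np.asarray(tm.face_adjacency), np.sort(np.asarray(tm.face_adjacency_edges), axis=1)


def _adjacency_map(
    pairs: np.ndarray, edges: np.ndarray, allowed: np.ndarray
) -> dict[int, list[tuple[int, Edge]]]:
    adj: dict[int, list[tuple[int, Edge]]] = {}
    for (f0, f1), (v0, v1) in zip(pairs, edges):
        if not (allowed[f0] and allowed[f1]):
            continue
        e = (int(v0), int(v1))
        adj.setdefault(int(f0), []).append((int(f1), e))
        adj.setdefault(int(f1), []).append((int(f0), e))
    return adj


def _nearest_on_submesh(
    skull: TriangleMesh, face_idx: np.ndarray, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest point restricted to a subset of faces; returns global face ids."""
    proj, dist, local = closest_point_on_mesh(
        skull.vertices, skull.faces[face_idx], points
    )
    return proj, dist, face_idx[local]


def _segment_pair_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs min distance between segments (a[i], b[i]). Vectorised clamp."""
    d1 = b - a
    n = len(a)
    r = a[:, None, :] - a[None, :, :]  # r_ij = a_i - a_j
    A = np.einsum("ik,ik->i", d1, d1)  # squared lengths
    B = np.einsum("ik,jk->ij", d1, d1)
    C = np.einsum("ik,ijk->ij", d1, r)
    F = np.einsum("jk,ijk->ij", d1, r)
    Ai = np.maximum(A[:, None], 1e-12)
    Ej = np.maximum(A[None, :], 1e-12)
    denom = Ai * Ej - B * B
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 1e-12, np.clip((B * F - C * Ej) / denom, 0.0, 1.0), 0.0)
        t = (B * s + F) / Ej
        s = np.where(t < 0.0, np.clip(-C / Ai, 0.0, 1.0), s)
        s = np.where(t > 1.0, np.clip((B - C) / Ai, 0.0, 1.0), s)
        t = np.clip(t, 0.0, 1.0)
    p = a[:, None, :] + s[:, :, None] * d1[:, None, :]
    q = a[None, :, :] + t[:, :, None] * d1[None, :, :]
    return np.linalg.norm(p - q, axis=2)


def _check_self_intersection(samples: np.ndarray, closed: bool, snap_tol: float) -> None:
    """Reject paths that cross (or graze within snap_tol/2) themselves.

    Pairs close together along the path (within a window scaled to the
    sampling and snap tolerance) are exempt, so tightly curved but
    non-crossing contours pass.
    """
    a, b = samples[:-1], samples[1:]
    if closed:
        a = np.vstack([a, samples[-1:]])
        b = np.vstack([b, samples[:1]])
    n = len(a)
    if n < 4:
        return
    seg_len = np.linalg.norm(b - a, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    mid_s = 0.5 * (cum[:-1] + cum[1:])
    ds = np.abs(mid_s[:, None] - mid_s[None, :])
    if closed:
        ds = np.minimum(ds, total - ds)
    dist = _segment_pair_distances(a, b)
    window = max(5.0 * snap_tol, 2.5 * float(seg_len.max()))
    faraway = ds > window
    np.fill_diagonal(faraway, False)
    if np.any(dist[faraway] < 0.5 * snap_tol):
        raise ValidationError("projected contour self-intersects")


def project_contour(
    skull: TriangleMesh,
    raw: SurfaceContour,
    snap_tol_mm: float = DEFAULT_SNAP_TOL_MM,
    outer_faces: np.ndarray | None = None,
    check_self_intersection: bool = True,
) -> ProjectedContour:
    """Snap a drawn polyline to the skull outer surface and collect barriers.

    Each drawn point is replaced by its nearest point on the outer surface;
    consecutive projected points are connected by chords subdivided until
    every chord midpoint lies within ``snap_tol_mm`` of the surface (and
    no chord exceeds half the local edge length, so face transitions are
    not skipped). The mesh edges crossed by the walk become barrier edges.

    Raises :class:`ProjectionError` if a drawn point is farther than
    10×``snap_tol_mm`` from the surface, :class:`ValidationError` on
    self-intersecting paths.
    """
    if snap_tol_mm <= 0:
        raise ValidationError("snap_tol_mm must be positive")
    if len(raw.points) < 3:
        raise ValidationError("drawn contour needs at least 3 points")
    if len(skull.faces) == 0:
        raise ValidationError("empty skull mesh")
    mask = outer_surface_faces(skull, outer_faces)
    face_idx = np.flatnonzero(mask)
    if len(face_idx) == 0:
        raise ValidationError("no outer-surface faces identified")

    proj, dist, faces0 = _nearest_on_submesh(skull, face_idx, raw.points)
    if np.any(dist > 10.0 * snap_tol_mm):
        k = int(np.argmax(dist))
        raise ProjectionError(
            f"drawn point {k} is {dist[k]:.2f} mm from the surface "
            f"(limit {10.0 * snap_tol_mm:.2f} mm)"
        )

    closed = bool(np.linalg.norm(proj[0] - proj[-1]) <= snap_tol_mm) or raw.closed
    edge_vec = skull.vertices[skull.faces[face_idx][:, 1]] - skull.vertices[
        skull.faces[face_idx][:, 0]
    ]
    max_chord = 0.5 * float(np.median(np.linalg.norm(edge_vec, axis=1)))

    def refine(p: np.ndarray, q: np.ndarray, depth: int = 0) -> list[np.ndarray]:
        """Points strictly between p and q, all snapped to the surface."""
        chord = np.linalg.norm(q - p)
        if chord < 1e-9 or depth > 24:
            return []
        mid = 0.5 * (p + q)
        mid_proj, mid_dist, _ = _nearest_on_submesh(skull, face_idx, mid[None])
        if mid_dist[0] <= snap_tol_mm and chord <= max_chord:
            return []
        m = mid_proj[0]
        return refine(p, m, depth + 1) + [m] + refine(m, q, depth + 1)

    pairs = list(zip(proj[:-1], proj[1:]))
    if closed:
        pairs.append((proj[-1], proj[0]))
    samples: list[np.ndarray] = [proj[0]]
    for p, q in pairs:
        samples.extend(refine(p, q))
        samples.append(q)
    samples_arr = np.asarray(samples)
    if closed:
        samples_arr = samples_arr[:-1]  # wrap point duplicates the start

    if check_self_intersection:
        _check_self_intersection(samples_arr, closed, snap_tol_mm)

    _, _, sample_faces = _nearest_on_submesh(skull, face_idx, samples_arr)

    adj_pairs, adj_edges = _face_adjacency(skull)
    adj = _adjacency_map(adj_pairs, adj_edges, mask)

    barrier: set[Edge] = set()
    seq = list(sample_faces)
    if closed:
        seq.append(sample_faces[0])
    for f_prev, f_cur in zip(seq[:-1], seq[1:]):
        if f_prev == f_cur:
            continue
        barrier.update(_dual_path_edges(adj, int(f_prev), int(f_cur)))

    contour = SurfaceContour(samples_arr, closed=closed, name=raw.name, host_mesh=skull)
    return ProjectedContour(
        contour=contour,
        barrier_edges=frozenset(barrier),
        closed=closed,
        snap_tol_mm=snap_tol_mm,
        path_faces=np.asarray(sample_faces, dtype=np.int64),
    )


def _dual_path_edges(
    adj: dict[int, list[tuple[int, Edge]]], start: int, goal: int
) -> list[Edge]:
    """Shared edges along the shortest dual-graph path start→goal (BFS).

    For adjacent faces this is just their common edge; when a path sample
    skipped across a vertex the BFS bridges the gap so the barrier stays
    gap-free.
    """
    if start == goal:
        return []
    prev: dict[int, tuple[int, Edge]] = {}
    queue = deque([start])
    seen = {start}
    while queue:
        f = queue.popleft()
        for g, e in adj.get(f, ()):
            if g in seen:
                continue
            seen.add(g)
            prev[g] = (f, e)
            if g == goal:
                queue.clear()
                break
            queue.append(g)
    if goal not in prev:
        return []
    edges = []
    f = goal
    while f != start:
        f, e = prev[f]
        edges.append(e)
    return edges


def region_grow(
    skull: TriangleMesh,
    contour: ProjectedContour,
    seed_point: np.ndarray,
    leak_fraction: float = DEFAULT_LEAK_FRACTION,
    outer_faces: np.ndarray | None = None,
) -> CraniotomyRegion:
    """Breadth-first face growth from the seed, bounded by barrier edges.

    The growth aborts with :class:`GrowthLeakError` once it covers more
    than ``leak_fraction`` of the outer-surface area — the signature of a
    gap in the barrier (open or leaky contour).
    """
    if not contour.closed:
        raise ContourNotClosedError("region growing requires a closed contour")
    if not (0.0 < leak_fraction <= 1.0):
        raise ValidationError("leak_fraction must be in (0, 1]")
    mask = outer_surface_faces(skull, outer_faces)
    face_idx = np.flatnonzero(mask)
    seed_point = np.asarray(seed_point, dtype=float).reshape(3)

    proj, dist, seed_face = _nearest_on_submesh(skull, face_idx, seed_point[None])
    if dist[0] > contour.snap_tol_mm:
        raise SeedInvalidError(
            f"seed point is {dist[0]:.2f} mm from the outer surface"
        )
    seed_face = int(seed_face[0])
    if contour.barrier_edges:
        be = np.asarray(sorted(contour.barrier_edges))
        d_barrier = point_to_segments_distance(
            proj[:1], skull.vertices[be[:, 0]], skull.vertices[be[:, 1]]
        )[0]
        if d_barrier < 1e-6:
            raise SeedInvalidError("seed point lies on a barrier edge")

    areas = skull.face_areas()
    total_outer = float(areas[mask].sum())
    limit = leak_fraction * total_outer

    adj_pairs, adj_edges = _face_adjacency(skull)
    adj = _adjacency_map(adj_pairs, adj_edges, mask)
    barrier = contour.barrier_edges

    visited = {seed_face}
    queue = deque([seed_face])
    area = float(areas[seed_face])
    while queue:
        f = queue.popleft()
        for g, e in adj.get(f, ()):
            if g in visited or e in barrier:
                continue
            visited.add(g)
            area += float(areas[g])
            if area > limit:
                raise GrowthLeakError(
                    f"growth reached {area:.0f} mm² (> {limit:.0f} mm²); "
                    "the contour barrier has a gap"
                )
            queue.append(g)
    return CraniotomyRegion(frozenset(visited), seed_face, area)


def excise(skull: TriangleMesh, region: CraniotomyRegion) -> TriangleMesh:
    """Remove the region's faces from the skull (bone-flap removal).

    Vertices are kept (indices stay valid against the input mesh); the new
    boundary of the output traces the barrier cycle of the contour.
    """
    if not region.face_ids:
        return skull.copy()
    ids = np.asarray(sorted(region.face_ids), dtype=np.int64)
    if ids.min() < 0 or ids.max() >= len(skull.faces):
        raise ValidationError("region references faces outside the skull mesh")
    keep = np.ones(len(skull.faces), dtype=bool)
    keep[ids] = False
    return TriangleMesh(skull.vertices.copy(), skull.faces[keep], name=skull.name + "_cut")


def through_cut(
    skull: TriangleMesh,
    region: CraniotomyRegion,
    outer_faces: np.ndarray | None = None,
) -> TriangleMesh:
    """Excise the region through the full bone thickness.

    :func:`excise` removes only the outer table (the drawn patch); on a
    two-layer shell the inner table would then still occlude every sight
    line. This helper additionally removes inner-table faces lying
    radially beneath the region — the face subset whose centroid, pushed
    out to the outer surface along the radial direction from the shell
    centre, lands on a region face. Intended for the shell phantom, where
    "radially beneath" is well defined.
    """
    mask = outer_surface_faces(skull, outer_faces)
    outer_cut = excise(skull, region)
    inner_idx = np.flatnonzero(~mask)
    if len(inner_idx) == 0:
        return outer_cut
    centre = skull.vertices.mean(axis=0)
    cent = skull.face_centroids()[inner_idx]
    radial = cent - centre
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    outer_r = np.linalg.norm(
        skull.face_centroids()[np.flatnonzero(mask)] - centre, axis=1
    ).mean()
    probes = centre + radial * outer_r
    face_idx = np.flatnonzero(mask)
    _, _, nearest_outer = _nearest_on_submesh(skull, face_idx, probes)
    under = inner_idx[np.isin(nearest_outer, np.asarray(sorted(region.face_ids)))]
    if len(under) == 0:
        return outer_cut
    drop = frozenset(region.face_ids) | frozenset(int(f) for f in under)
    keep = np.ones(len(skull.faces), dtype=bool)
    keep[np.asarray(sorted(drop))] = False
    return TriangleMesh(
        skull.vertices.copy(), skull.faces[keep], name=skull.name + "_cut"
    )
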