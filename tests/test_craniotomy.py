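import networkx as nx
import numpy as np
import pytest

from craniotome import (
    CraniotomyRegion,
    SurfaceContour,
    excise,
    outer_surface_faces,
    project_contour,
    region_grow,
    through_cut,
)
from craniotome.craniotomy import ProjectedContour, _face_adjacency
from craniotome.errors import (
    ContourNotClosedError,
    GrowthLeakError,
    ProjectionError,
    SeedInvalidError,
    ValidationError,
)
from craniotome.geom import closest_point_on_mesh


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_closest_point_triangle(p, a, b, c):
    """Closest point on one triangle, written independently (region tests)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        return a + (d1 / (d1 - d3)) * ab
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        return a + (d2 / (d2 - d6)) * ac
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b)
    denom = 1.0 / (va + vb + vc)
    return a + (vb * denom) * ab + (vc * denom) * ac


def oracle_flood_fill(mesh, outer_mask, barrier, seed_face):
    """Connected component on the face graph minus barrier edges (networkx)."""
    pairs, edges = _face_adjacency(mesh)
    g = nx.Graph()
    g.add_nodes_from(np.flatnonzero(outer_mask))
    for (f0, f1), (v0, v1) in zip(pairs, np.sort(edges, axis=1)):
        if outer_mask[f0] and outer_mask[f1] and (int(v0), int(v1)) not in barrier:
            g.add_edge(int(f0), int(f1))
    return nx.node_connected_component(g, int(seed_face))


def surface_circle_contour(radius, axis, half_angle_deg, n=24, name="c"):
    """Raw circle around ``axis`` on a sphere of ``radius`` (not yet snapped)."""
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    alpha = np.deg2rad(half_angle_deg)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = radius * (
        np.cos(alpha) * axis
        + np.sin(alpha) * (np.cos(t)[:, None] * u + np.sin(t)[:, None] * v)
    )
    return SurfaceContour(pts, closed=True, name=name)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

class TestProjectContour:
    def test_points_on_surface_are_fixed_points(self, icosphere):
        sphere = icosphere(2)
        mask = np.ones(len(sphere.faces), dtype=bool)
        pts = sphere.face_centroids()[[3, 40, 77]]
        proj = project_contour(
            sphere, SurfaceContour(pts, closed=False), outer_faces=mask
        )
        # original vertices of the walk are retained among the samples
        for p in pts:
            d = np.linalg.norm(proj.contour.points - p, axis=1).min()
            assert d < 1e-9

    def test_radial_projection_onto_sphere(self, icosphere):
        sphere = icosphere(4)
        mask = np.ones(len(sphere.faces), dtype=bool)
        direction = np.array([0.3, -0.5, 0.81])
        direction /= np.linalg.norm(direction)
        raw = np.array([90.0 * direction, 90.0 * np.roll(direction, 1), [0, 0, 90.0]])
        proj = project_contour(
            sphere, SurfaceContour(raw, closed=False), snap_tol_mm=2.0,
            outer_faces=mask,
        )
        first = proj.contour.points[0]
        assert np.linalg.norm(first) == pytest.approx(85.0, abs=0.2)
        assert first @ direction / np.linalg.norm(first) > 0.999

    def test_nearest_points_match_brute_force_oracle(self, icosphere):
        sphere = icosphere(2)
        rng = np.random.default_rng(42)
        dirs = rng.normal(size=(50, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = dirs * rng.uniform(80, 90, size=(50, 1))
        got, dist, _ = closest_point_on_mesh(sphere.vertices, sphere.faces, pts)
        tri = sphere.triangles
        for k, p in enumerate(pts):
            best = min(
                (oracle_closest_point_triangle(p, *t) for t in tri),
                key=lambda q: np.linalg.norm(q - p),
            )
            assert np.linalg.norm(got[k] - p) == pytest.approx(
                np.linalg.norm(best - p), abs=1e-9
            )

    def test_far_point_raises_projection_error(self, icosphere):
        sphere = icosphere(1)
        raw = SurfaceContour(
            np.array([[0, 0, 300.0], [85, 0, 0], [0, 85, 0]]), closed=True
        )
        with pytest.raises(ProjectionError):
            project_contour(sphere, raw, outer_faces=np.ones(len(sphere.faces), bool))

    def test_closure_detected_from_endpoint_gap(self, icosphere):
        sphere = icosphere(3)
        mask = np.ones(len(sphere.faces), dtype=bool)
        contour = surface_circle_contour(85.0, [0, 0, 1], 30.0)
        proj = project_contour(sphere, contour, outer_faces=mask)
        assert proj.closed
        assert len(proj.barrier_edges) > 0

    def test_self_intersecting_path_rejected(self, icosphere):
        sphere = icosphere(3)
        mask = np.ones(len(sphere.faces), dtype=bool)
        # bowtie: the A->B and C->D walks both run across the pole and cross
        theta = np.deg2rad(20.0)
        azims = np.deg2rad([0.0, 180.0, 90.0, 270.0])
        pts = 85.0 * np.column_stack(
            [np.sin(theta) * np.cos(azims), np.sin(theta) * np.sin(azims),
             np.cos(theta) * np.ones(4)]
        )
        with pytest.raises(ValidationError):
            project_contour(
                sphere, SurfaceContour(pts, closed=True), outer_faces=mask
            )


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------

class TestRegionGrow:
    def test_matches_flood_fill_oracle_latitude_circle(self, icosphere):
        sphere = icosphere(3)
        mask = np.ones(len(sphere.faces), dtype=bool)
        contour = surface_circle_contour(85.0, [0, 0, 1], 35.0)
        proj = project_contour(sphere, contour, outer_faces=mask)
        region = region_grow(sphere, proj, np.array([0, 0, 85.0]), outer_faces=mask)
        expected = oracle_flood_fill(sphere, mask, proj.barrier_edges, region.seed_face)
        assert region.face_ids == frozenset(expected)

    def test_open_contour_rejected(self, icosphere):
        sphere = icosphere(2)
        mask = np.ones(len(sphere.faces), dtype=bool)
        arc = surface_circle_contour(85.0, [0, 0, 1], 30.0).points[:12]
        proj = project_contour(sphere, SurfaceContour(arc, closed=False), outer_faces=mask)
        assert not proj.closed
        with pytest.raises(ContourNotClosedError):
            region_grow(sphere, proj, np.array([0, 0, 85.0]), outer_faces=mask)

    def test_barrier_gap_leaks(self, icosphere):
        sphere = icosphere(3)
        mask = np.ones(len(sphere.faces), dtype=bool)
        contour = surface_circle_contour(85.0, [0, 0, 1], 30.0)
        proj = project_contour(sphere, contour, outer_faces=mask)
        # knock a hole in the barrier: growth must escape and be detected
        broken = ProjectedContour(
            contour=proj.contour,
            barrier_edges=frozenset(list(proj.barrier_edges)[4:]),
            closed=True,
            snap_tol_mm=proj.snap_tol_mm,
        )
        with pytest.raises(GrowthLeakError):
            region_grow(sphere, broken, np.array([0, 0, 85.0]), outer_faces=mask)

    def test_single_face_region(self, icosphere):
        sphere = icosphere(2)
        mask = np.ones(len(sphere.faces), dtype=bool)
        face = 100
        vs = sphere.vertices[sphere.faces[face]]
        edges = frozenset(
            tuple(sorted((int(sphere.faces[face][i]), int(sphere.faces[face][(i + 1) % 3]))))
            for i in range(3)
        )
        ring = SurfaceContour(vs, closed=True)
        proj = ProjectedContour(contour=ring, barrier_edges=edges, closed=True)
        region = region_grow(sphere, proj, vs.mean(axis=0), outer_faces=mask)
        assert region.face_ids == frozenset({face})

    def test_seed_on_barrier_rejected(self, icosphere):
        sphere = icosphere(2)
        mask = np.ones(len(sphere.faces), dtype=bool)
        face = 100
        i, j = int(sphere.faces[face][0]), int(sphere.faces[face][1])
        proj = ProjectedContour(
            contour=SurfaceContour(sphere.vertices[sphere.faces[face]], closed=True),
            barrier_edges=frozenset({tuple(sorted((i, j)))}),
            closed=True,
        )
        midpoint = 0.5 * (sphere.vertices[i] + sphere.vertices[j])
        with pytest.raises(SeedInvalidError):
            region_grow(sphere, proj, midpoint, outer_faces=mask)

    def test_seed_choice_inside_region_is_irrelevant(self, icosphere):
        sphere = icosphere(3)
        mask = np.ones(len(sphere.faces), dtype=bool)
        contour = surface_circle_contour(85.0, [0.2, 0.3, 0.93], 25.0)
        proj = project_contour(sphere, contour, outer_faces=mask)
        axis = np.array([0.2, 0.3, 0.93])
        axis = 85.0 * axis / np.linalg.norm(axis)
        base = region_grow(sphere, proj, axis, outer_faces=mask)
        centroids = sphere.face_centroids()
        rng = np.random.default_rng(0)
        for f in rng.choice(sorted(base.face_ids), size=5, replace=False):
            alt = region_grow(sphere, proj, centroids[f], outer_faces=mask)
            assert alt.face_ids == base.face_ids

    def test_inside_outside_partition(self, icosphere):
        sphere = icosphere(3)
        mask = np.ones(len(sphere.faces), dtype=bool)
        contour = surface_circle_contour(85.0, [0, 0, 1], 30.0)
        proj = project_contour(sphere, contour, outer_faces=mask)
        inside = region_grow(sphere, proj, np.array([0, 0, 85.0]), outer_faces=mask)
        outside = region_grow(
            sphere, proj, np.array([0, 0, -85.0]), leak_fraction=1.0, outer_faces=mask
        )
        assert not (inside.face_ids & outside.face_ids)
        barrier_faces = {
            f
            for f in range(len(sphere.faces))
            if any(
                tuple(sorted((int(sphere.faces[f][i]), int(sphere.faces[f][(i + 1) % 3]))))
                in proj.barrier_edges
                for i in range(3)
            )
        }
        covered = inside.face_ids | outside.face_ids | barrier_faces
        assert covered == set(range(len(sphere.faces)))

    def test_area_equals_independent_accumulation(self, icosphere):
        sphere = icosphere(3)
        mask = np.ones(len(sphere.faces), dtype=bool)
        contour = surface_circle_contour(85.0, [1, 0, 0], 20.0)
        proj = project_contour(sphere, contour, outer_faces=mask)
        region = region_grow(sphere, proj, np.array([85.0, 0, 0]), outer_faces=mask)
        tri = sphere.triangles[sorted(region.face_ids)]
        expected = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        ).sum()
        assert region.area_mm2 == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# excision
# ---------------------------------------------------------------------------

class TestExcise:
    @pytest.fixture
    def grown(self, icosphere):
        sphere = icosphere(3)
        mask = np.ones(len(sphere.faces), dtype=bool)
        contour = surface_circle_contour(85.0, [0, 0, 1], 30.0)
        proj = project_contour(sphere, contour, outer_faces=mask)
        region = region_grow(sphere, proj, np.array([0, 0, 85.0]), outer_faces=mask)
        return sphere, proj, region

    def test_face_count_reduced_by_region_size(self, grown):
        sphere, _, region = grown
        cut = excise(sphere, region)
        assert len(cut.faces) == len(sphere.faces) - len(region.face_ids)

    def test_new_boundary_matches_independent_kept_removed_scan(self, grown):
        sphere, proj, region = grown
        cut = excise(sphere, region)
        new_boundary = {tuple(e) for e in cut.boundary_edges()}
        # oracle: edges shared by one kept and one removed face
        pairs, edges = _face_adjacency(sphere)
        expected = {
            tuple(sorted((int(v0), int(v1))))
            for (f0, f1), (v0, v1) in zip(pairs, edges)
            if (f0 in region.face_ids) != (f1 in region.face_ids)
        }
        assert new_boundary == expected
        # every cut edge was claimed by the drawn path
        assert new_boundary <= set(proj.barrier_edges)

    def test_single_boundary_loop(self, grown):
        sphere, _, region = grown
        cut = excise(sphere, region)
        assert len(cut.boundary_loops()) == 1

    def test_empty_region_is_identity(self, icosphere):
        sphere = icosphere(1)
        cut = excise(sphere, CraniotomyRegion(frozenset(), -1, 0.0))
        assert np.array_equal(cut.faces, sphere.faces)
        assert np.array_equal(cut.vertices, sphere.vertices)

    def test_region_out_of_range_rejected(self, icosphere):
        sphere = icosphere(1)
        reg = CraniotomyRegion(frozenset({10**6}), 10**6, 1.0)
        with pytest.raises(ValidationError):
            excise(sphere, reg)


def test_through_cut_removes_inner_table_under_region(default_scene):
    skull = default_scene.skull
    mask = outer_surface_faces(skull)
    proj = project_contour(skull, default_scene.templates[0], outer_faces=mask)
    centroid = proj.contour.points.mean(axis=0)
    seed, _, _ = closest_point_on_mesh(
        skull.vertices, skull.faces[np.flatnonzero(mask)], centroid[None]
    )
    region = region_grow(skull, proj, seed[0], outer_faces=mask)
    outer_only = excise(skull, region)
    through = through_cut(skull, region, outer_faces=mask)
    assert len(through.faces) < len(outer_only.faces)
    # the inner table now has a hole too: at least two boundary loops
    assert len(through.boundary_loops()) >= 2
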