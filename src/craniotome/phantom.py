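"""Deterministic synthetic-anatomy generator.

Stands in for segmented patient models so that every pipeline stage is
testable without data. The scene emulates the anatomy relevant to a
pterional approach to a middle-cerebral-artery target:

* a watertight skull as a thick spherical shell (outer icosphere minus an
  inverted inner icosphere), centred at the origin;
* a brain sphere split by a planar Sylvian-fissure stand-in into a frontal
  and a temporal lobe (open hemispherical shells separated by a small gap);
* a Circle-of-Willis stand-in polyline through the brain interior whose M1
  segment (first MCA segment) has a configurable length — the clinically
  relevant parameter when choosing a strategy for MCA aneurysms;
* point landmarks for the optic nerve and the pterion;
* four closed template contours on the outer skull surface: two drawing
  locations times two line widths, mirroring the tracing protocol used to
  assess drawing precision.

Coordinate frame: ``+x`` left, ``+y`` superior, ``+z`` anterior, patient
supine, all millimetres. All geometry is deterministic for a fixed seed;
optional Gaussian vertex jitter (default off) exercises robustness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from trimesh.intersections import slice_mesh_plane

from .errors import ValidationError
from .geom import closest_point_on_mesh
from .geometry_io import (
    Landmark,
    SurfaceContour,
    TriangleMesh,
    load_contour,
    load_mesh,
    save_contour,
    save_mesh,
)

_SQ2 = float(np.sqrt(0.5))


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("zero vector where a direction is required")
    return v / n


@dataclass
class PhantomConfig:
    """Parameters of the synthetic scene (all lengths in mm).

    Defaults describe an adult-sized head: outer skull radius 85 mm,
    calvarial thickness 6 mm, brain radius 75 mm. The fissure plane passes
    through the brain centre tilted 45° between superior and anterior,
    separating a frontal (antero-superior) from a temporal lobe. Template
    locations sit over the right pterional region and a more frontal site;
    line widths 1 and 2 mm. The M1 length default of 25 mm is mid-range
    for adult anatomy.
    """

    skull_outer_radius: float = 85.0
    skull_thickness: float = 6.0
    brain_radius: float = 75.0
    fissure_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fissure_normal: tuple[float, float, float] = (0.0, _SQ2, _SQ2)
    fissure_gap_mm: float = 2.0
    craniotomy_template_locations: tuple[tuple[float, float, float], ...] = (
        (-0.85, 0.30, 0.43),  # pterional region, right side (+x is left)
        (-0.55, 0.55, 0.63),  # more frontal site
    )
    template_radius_mm: float = 15.0
    template_line_widths: tuple[float, float] = (1.0, 2.0)
    template_points: int = 64
    vessel_waypoints: tuple[tuple[float, float, float], ...] = (
        (-5.0, -40.0, 0.0),   # carotid entering the circle
        (-8.0, -32.0, 8.0),   # carotid bifurcation: M1 origin
        (-30.0, -28.0, 12.0),  # MCA bifurcation (typical target site)
        (-42.0, -22.0, 18.0),  # M2 branch continuing into the fissure
    )
    m1_segment: tuple[int, int] = (1, 2)
    m1_length: float = 25.0
    subdivision_level: int = 4
    jitter_sigma_mm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.skull_thickness < self.skull_outer_radius):
            raise ValidationError("skull thickness must be in (0, outer radius)")
        if not (0 < self.brain_radius < self.skull_outer_radius - self.skull_thickness):
            raise ValidationError("brain radius must fit inside the inner skull surface")
        if len(self.craniotomy_template_locations) != 2:
            raise ValidationError("exactly 2 template locations required")
        if len(self.template_line_widths) != 2:
            raise ValidationError("exactly 2 template line widths required")
        if len(self.vessel_waypoints) < 2:
            raise ValidationError("vessel polyline needs at least 2 waypoints")
        i, j = self.m1_segment
        if not (0 <= i < j < len(self.vessel_waypoints)):
            raise ValidationError("m1_segment indices out of range")
        if self.m1_length <= 0:
            raise ValidationError("m1_length must be positive")
        if self.subdivision_level < 1 or self.subdivision_level > 6:
            raise ValidationError("subdivision_level must be in [1, 6]")


@dataclass
class PhantomScene:
    """Generated anatomy: meshes, vessel, landmarks, drawing templates."""

    skull: TriangleMesh
    brain_frontal: TriangleMesh
    brain_temporal: TriangleMesh
    vessel: SurfaceContour
    landmarks: list[Landmark]
    templates: list[SurfaceContour]
    config: PhantomConfig = field(default_factory=PhantomConfig)

    def landmark(self, name: str) -> Landmark:
        for lm in self.landmarks:
            if lm.name == name:
                return lm
        raise KeyError(f"no landmark named {name!r}")

    @property
    def fissure_plane(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.asarray(self.config.fissure_point, dtype=float),
            _unit(self.config.fissure_normal),
        )


def _shell(config: PhantomConfig, rng: np.random.Generator) -> TriangleMesh:
    outer = trimesh.creation.icosphere(
        subdivisions=config.subdivision_level, radius=config.skull_outer_radius
    )
    inner = trimesh.creation.icosphere(
        subdivisions=max(config.subdivision_level - 1, 1),
        radius=config.skull_outer_radius - config.skull_thickness,
    )
    inner.invert()  # normals point into the shell cavity
    shell = trimesh.util.concatenate([outer, inner])
    v = np.asarray(shell.vertices)
    if config.jitter_sigma_mm > 0:
        # radial jitter keeps the two layers from interpenetrating
        radii = np.linalg.norm(v, axis=1, keepdims=True)
        v = v * (1.0 + rng.normal(0.0, config.jitter_sigma_mm, size=(len(v), 1)) / radii)
    return TriangleMesh(v, np.asarray(shell.faces), name="skull")


def _cap_rim(mesh: TriangleMesh, outward: np.ndarray) -> TriangleMesh:
    """Close the planar rim of a sliced hemisphere by a centroid fan.

    ``outward`` is the direction the cap should face (away from the solid);
    the rim of a plane-sliced convex mesh is a single convex loop, so a
    fan about its centroid is a valid triangulation. The cap centre vertex
    gives the fissure surface particles for the spatula to engage.
    """
    loops = mesh.boundary_loops()
    if len(loops) != 1:
        raise ValidationError(f"expected one rim loop on sliced lobe, got {len(loops)}")
    loop = loops[0]
    centre = mesh.vertices[loop].mean(axis=0)
    vertices = np.vstack([mesh.vertices, centre[None]])
    c = len(vertices) - 1
    fan = np.array([[c, loop[k], loop[(k + 1) % len(loop)]] for k in range(len(loop))])
    v0 = vertices[fan[0]]
    if np.cross(v0[1] - v0[0], v0[2] - v0[0]) @ outward < 0:
        fan = fan[:, [0, 2, 1]]
    return TriangleMesh(vertices, np.vstack([mesh.faces, fan]), name=mesh.name)


def _lobes(config: PhantomConfig, rng: np.random.Generator) -> tuple[TriangleMesh, TriangleMesh]:
    brain = trimesh.creation.icosphere(
        subdivisions=config.subdivision_level, radius=config.brain_radius
    )
    if config.jitter_sigma_mm > 0:
        v = np.asarray(brain.vertices)
        brain.vertices = v + rng.normal(0.0, config.jitter_sigma_mm, size=v.shape)
    point = np.asarray(config.fissure_point, dtype=float)
    n = _unit(config.fissure_normal)
    half = 0.5 * config.fissure_gap_mm
    frontal = slice_mesh_plane(brain, plane_normal=n, plane_origin=point + half * n)
    temporal = slice_mesh_plane(brain, plane_normal=-n, plane_origin=point - half * n)
    if len(frontal.faces) == 0 or len(temporal.faces) == 0:
        raise ValidationError("fissure plane does not intersect the brain")
    # weld the duplicated rim vertices the slicer introduces
    for m in (frontal, temporal):
        m.merge_vertices(digits_vertex=6)
    return (
        _cap_rim(TriangleMesh.from_trimesh(frontal, name="brain_frontal"), -n),
        _cap_rim(TriangleMesh.from_trimesh(temporal, name="brain_temporal"), n),
    )


def _vessel(config: PhantomConfig) -> SurfaceContour:
    pts = np.asarray(config.vessel_waypoints, dtype=float).copy()
    i, j = config.m1_segment
    # rescale the M1 waypoint chain so the designated segment has m1_length
    direction = pts[j] - pts[i]
    cur = np.linalg.norm(direction)
    if cur == 0:
        raise ValidationError("degenerate M1 segment in vessel waypoints")
    shift = (config.m1_length / cur - 1.0) * direction
    pts[j:] += shift
    limit = config.brain_radius - 1.0
    radii = np.linalg.norm(pts, axis=1)
    if np.any(radii >= limit):
        raise ValidationError(
            "vessel polyline leaves the brain volume; shorten m1_length or move waypoints"
        )
    return SurfaceContour(pts, closed=False, name="vessel")


def _project_to_mesh(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    proj, _, _ = closest_point_on_mesh(mesh.vertices, mesh.faces, points)
    return proj


def _surface_circle(
    mesh: TriangleMesh,
    direction: np.ndarray,
    sphere_radius: float,
    geodesic_radius: float,
    n_points: int,
) -> np.ndarray:
    """Points of a circle of given geodesic radius around ``direction`` on a
    sphere of ``sphere_radius``, snapped onto the mesh surface."""
    c = _unit(direction)
    # orthonormal frame around c
    ref = np.array([0.0, 0.0, 1.0]) if abs(c[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = _unit(np.cross(c, ref))
    v = np.cross(c, u)
    alpha = geodesic_radius / sphere_radius
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    ring = sphere_radius * (
        np.cos(alpha) * c[None, :]
        + np.sin(alpha) * (np.cos(t)[:, None] * u[None, :] + np.sin(t)[:, None] * v[None, :])
    )
    return _project_to_mesh(ring, mesh)


def generate_phantom(config: PhantomConfig | None = None) -> PhantomScene:
    """Build the full synthetic scene; deterministic for a fixed seed."""
    config = config or PhantomConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    skull = _shell(config, rng)
    frontal, temporal = _lobes(config, rng)
    vessel = _vessel(config)

    r_out = config.skull_outer_radius
    landmarks = [
        # short optic-nerve stump protruding near the skull base, midline-anterior
        Landmark("optic_nerve", (-4.0, -30.0, 24.0)),
        # pterion on the outer table over the first template location
        Landmark(
            "pterion",
            _project_to_mesh(
                np.asarray(config.craniotomy_template_locations[0], dtype=float)[None]
                * r_out,
                skull,
            )[0],
        ),
    ]

    templates = []
    for loc_idx, loc in enumerate(config.craniotomy_template_locations):
        for width in config.template_line_widths:
            pts = _surface_circle(
                skull,
                np.asarray(loc, dtype=float),
                r_out,
                config.template_radius_mm,
                config.template_points,
            )
            templates.append(
                SurfaceContour(
                    pts,
                    closed=True,
                    name=f"L{loc_idx + 1}_w{width:g}",
                    host_mesh=skull,
                )
            )

    return PhantomScene(
        skull=skull,
        brain_frontal=frontal,
        brain_temporal=temporal,
        vessel=vessel,
        landmarks=landmarks,
        templates=templates,
        config=replace(config),
    )


def place_target(scene: PhantomScene, arclength_fraction: float) -> Landmark:
    """Place the target sphere centre on the vessel polyline.

    ``arclength_fraction`` is the normalised arc length along the vessel in
    ``[0, 1]``; the landmark is appended to ``scene.landmarks`` and returned.
    """
    if not np.isfinite(arclength_fraction) or not (0.0 <= arclength_fraction <= 1.0):
        raise ValidationError("arclength_fraction must be in [0, 1]")
    pts = scene.vessel.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = arclength_fraction * cum[-1]
    k = int(np.searchsorted(cum, s, side="right") - 1)
    k = min(k, len(seg) - 1)
    t = (s - cum[k]) / seg[k] if seg[k] > 0 else 0.0
    pos = pts[k] + t * (pts[k + 1] - pts[k])
    target = Landmark("target", pos)
    scene.landmarks = [lm for lm in scene.landmarks if lm.name != "target"]
    scene.landmarks.append(target)
    return target


# ---------------------------------------------------------------------------
# scene persistence (CLI format: STL meshes + contour CSV/JSON + landmarks JSON)
# ---------------------------------------------------------------------------

def save_scene(scene: PhantomScene, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_mesh(scene.skull, directory / "skull.stl")
    save_mesh(scene.brain_frontal, directory / "brain_frontal.stl")
    save_mesh(scene.brain_temporal, directory / "brain_temporal.stl")
    save_contour(scene.vessel, directory / "vessel.csv")
    (directory / "landmarks.json").write_text(
        json.dumps(
            [{"name": lm.name, "position": lm.position.tolist()} for lm in scene.landmarks],
            indent=2,
        )
    )
    tdir = directory / "templates"
    tdir.mkdir(exist_ok=True)
    for i, c in enumerate(scene.templates):
        save_contour(c, tdir / f"template_{i}.csv")
    (directory / "phantom_config.json").write_text(json.dumps(_config_dict(scene.config), indent=2))


def load_scene(directory: str | Path) -> PhantomScene:
    directory = Path(directory)
    if not directory.exists():
        raise ValidationError(f"scene directory not found: {directory}")
    cfg_path = directory / "phantom_config.json"
    config = (
        PhantomConfig(**_config_from_dict(json.loads(cfg_path.read_text())))
        if cfg_path.exists()
        else PhantomConfig()
    )
    landmarks = [
        Landmark(d["name"], d["position"])
        for d in json.loads((directory / "landmarks.json").read_text())
    ]
    tdir = directory / "templates"
    templates = [
        load_contour(p) for p in sorted(tdir.glob("template_*.csv"))
    ] if tdir.exists() else []
    return PhantomScene(
        skull=load_mesh(directory / "skull.stl"),
        brain_frontal=load_mesh(directory / "brain_frontal.stl"),
        brain_temporal=load_mesh(directory / "brain_temporal.stl"),
        vessel=load_contour(directory / "vessel.csv"),
        landmarks=landmarks,
        templates=templates,
        config=config,
    )


def _config_dict(config: PhantomConfig) -> dict:
    return {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
    }


def _config_from_dict(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        out[k] = v
    return out
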