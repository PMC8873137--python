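"""Quantitative exposure evaluation for a craniotomy.

In the simulator the surgeon judges the hole in a microscopic view; this
module replaces that self-assessment with a measurable proxy: the fraction
of sight lines from a small sphere around the intracranial target to the
microscope eye that pass through the hole unoccluded, plus the clearance
of the eye–target trajectory from the hole rim and the hole area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .craniotomy import CraniotomyRegion
from .errors import ValidationError
from .geom import rays_occluded, segment_to_segment_distance
from .geometry_io import Landmark, TriangleMesh

DEFAULT_TARGET_RADIUS_MM = 2.0


@dataclass
class MicroscopeView:
    """Eye position and viewing target of the virtual microscope (mm)."""

    eye: np.ndarray
    look_at: np.ndarray
    fov_deg: float = 30.0

    def __post_init__(self) -> None:
        self.eye = np.asarray(self.eye, dtype=float).reshape(3)
        self.look_at = np.asarray(self.look_at, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.eye)) or not np.all(np.isfinite(self.look_at)):
            raise ValidationError("view positions must be finite")
        if np.linalg.norm(self.eye - self.look_at) < 1e-9:
            raise ValidationError("eye and look_at coincide")
        if not (0.0 < self.fov_deg < 180.0):
            raise ValidationError("fov_deg must be in (0, 180)")


@dataclass
class ExposureReport:
    """Result of ray-sampled visibility toward the target."""

    visible_fraction: float
    min_clearance_mm: float
    hole_area_mm2: float
    n_rays: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.visible_fraction <= 1.0):
            raise ValidationError("visible_fraction must be in [0, 1]")


def _sphere_samples(n: int, radius: float, seed: int) -> np.ndarray:
    """Stratified-random directions: golden-spiral lattice with seeded jitter."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    rng = np.random.default_rng(seed)
    # jitter within roughly one lattice cell, then renormalise
    base = np.column_stack(
        [np.cos(phi) * np.sqrt(1.0 - z**2), np.sin(phi) * np.sqrt(1.0 - z**2), z]
    )
    jitter = rng.normal(0.0, 1.0 / max(np.sqrt(n), 1.0), size=(n, 3))
    d = base + jitter
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return radius * d


def _loop_area(mesh: TriangleMesh, loop: np.ndarray) -> float:
    """Area of the (generally non-planar) polygon by centroid fan."""
    pts = mesh.vertices[loop]
    c = pts.mean(axis=0)
    a = pts - c
    b = np.roll(pts, -1, axis=0) - c
    return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())


def evaluate_exposure(
    cut_skull: TriangleMesh,
    target: Landmark | np.ndarray,
    view: MicroscopeView,
    n_rays: int = 500,
    seed: int = 0,
    target_radius_mm: float = DEFAULT_TARGET_RADIUS_MM,
    region: CraniotomyRegion | None = None,
    extra_occluders: tuple[TriangleMesh, ...] = (),
) -> ExposureReport:
    """Ray-sampled visibility of the target through the craniotomy hole.

    Rays start at stratified-random points on a small sphere (default
    radius 2 mm, the target-sphere stand-in) around the target and run to
    the eye; a ray occluded by the cut skull (or any extra occluder, e.g.
    an unretracted brain lobe) counts as blocked. Deterministic for a
    fixed seed. ``min_clearance_mm`` is the smallest distance from the
    eye–target segment to the hole rim (``inf`` when the mesh has no
    boundary); ``hole_area_mm2`` comes from the region if given, else from
    the largest boundary loop.
    """
    if n_rays < 1:
        raise ValidationError("n_rays must be >= 1")
    if target_radius_mm <= 0:
        raise ValidationError("target_radius_mm must be positive")
    pos = target.position if isinstance(target, Landmark) else np.asarray(target, dtype=float)

    origins = pos + _sphere_samples(n_rays, target_radius_mm, seed)
    occluded = rays_occluded(
        cut_skull.vertices, cut_skull.faces, origins, np.broadcast_to(view.eye, origins.shape)
    )
    for occ in extra_occluders:
        occluded |= rays_occluded(
            occ.vertices, occ.faces, origins, np.broadcast_to(view.eye, origins.shape)
        )
    visible_fraction = float(1.0 - occluded.mean())

    loops = cut_skull.boundary_loops()
    if loops:
        clearance = np.inf
        for loop in loops:
            pts = cut_skull.vertices[loop]
            nxt = np.roll(pts, -1, axis=0)
            for p, q in zip(pts, nxt):
                clearance = min(
                    clearance, segment_to_segment_distance(view.eye, pos, p, q)
                )
        hole_area = region.area_mm2 if region is not None else max(
            _loop_area(cut_skull, lp) for lp in loops
        )
    else:
        clearance = np.inf
        hole_area = region.area_mm2 if region is not None else 0.0

    return ExposureReport(
        visible_fraction=visible_fraction,
        min_clearance_mm=float(clearance),
        hole_area_mm2=float(hole_area),
        n_rays=n_rays,
        seed=seed,
    )
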