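"""Head positioning: clamped two-axis inclination as a rigid transform.

The head can be inclined longitudinally (nodding, about the left–right
``x`` axis) up to ±90° and transversally (ear-to-shoulder, about the
anterior–posterior ``z`` axis) up to ±30°. The stated limits are
magnitudes; a symmetric per-direction range is the anatomically neutral
reading and is adopted here.

Composition convention (documented because any slider UI leaves it
implicit): the longitudinal rotation is applied first, the transversal
rotation acts about the head-fixed (intrinsic) anterior axis, i.e.
``R = Rx(longitudinal) @ Rz(transversal)`` applied about the pivot. The
pivot stands in for the head clamp and defaults to the skull centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .geom import rotation_about_axis
from .geometry_io import Landmark, SurfaceContour, TriangleMesh
from .phantom import PhantomScene

LONGITUDINAL_LIMIT_DEG = 90.0
TRANSVERSAL_LIMIT_DEG = 30.0

_X = np.array([1.0, 0.0, 0.0])  # left–right axis
_Z = np.array([0.0, 0.0, 1.0])  # anterior–posterior axis


@dataclass(frozen=True)
class HeadPose:
    """Clamped inclination angles plus the fixation pivot (mm).

    Construction never yields out-of-range angles: values are clamped to
    ±90° longitudinal, ±30° transversal.
    """

    longitudinal_deg: float = 0.0
    transversal_deg: float = 0.0
    pivot: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.longitudinal_deg) and np.isfinite(self.transversal_deg)):
            raise ValidationError("pose angles must be finite")
        object.__setattr__(
            self,
            "longitudinal_deg",
            float(np.clip(self.longitudinal_deg, -LONGITUDINAL_LIMIT_DEG, LONGITUDINAL_LIMIT_DEG)),
        )
        object.__setattr__(
            self,
            "transversal_deg",
            float(np.clip(self.transversal_deg, -TRANSVERSAL_LIMIT_DEG, TRANSVERSAL_LIMIT_DEG)),
        )
        object.__setattr__(self, "pivot", tuple(float(c) for c in self.pivot))

    def rotation(self) -> np.ndarray:
        """3×3 rotation matrix: longitudinal first, intrinsic transversal."""
        return rotation_about_axis(_X, self.longitudinal_deg) @ rotation_about_axis(
            _Z, self.transversal_deg
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "longitudinal_deg": self.longitudinal_deg,
                    "transversal_deg": self.transversal_deg,
                    "pivot": list(self.pivot),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HeadPose":
        d = json.loads(Path(path).read_text())
        return cls(d["longitudinal_deg"], d["transversal_deg"], tuple(d.get("pivot", (0, 0, 0))))


def clamp_pose(
    longitudinal_deg: float,
    transversal_deg: float,
    pivot: tuple[float, float, float] | np.ndarray = (0.0, 0.0, 0.0),
) -> HeadPose:
    """Clamp requested angles to the allowed inclination range."""
    return HeadPose(longitudinal_deg, transversal_deg, tuple(np.asarray(pivot, dtype=float)))


def incremental_rotate(pose: HeadPose, d_long: float, d_trans: float) -> HeadPose:
    """Hand-rotation increment; saturates at the limits."""
    if not (np.isfinite(d_long) and np.isfinite(d_trans)):
        raise ValidationError("rotation deltas must be finite")
    return HeadPose(pose.longitudinal_deg + d_long, pose.transversal_deg + d_trans, pose.pivot)


def transform_points(points: np.ndarray, pose: HeadPose) -> np.ndarray:
    pivot = np.asarray(pose.pivot, dtype=float)
    return (np.asarray(points, dtype=float) - pivot) @ pose.rotation().T + pivot


def _transform_mesh(mesh: TriangleMesh, pose: HeadPose) -> TriangleMesh:
    return TriangleMesh(transform_points(mesh.vertices, pose), mesh.faces.copy(), mesh.name)


def _transform_contour(contour: SurfaceContour, pose: HeadPose) -> SurfaceContour:
    return SurfaceContour(
        transform_points(contour.points, pose), contour.closed, contour.name
    )


def apply_pose(scene: PhantomScene, pose: HeadPose) -> PhantomScene:
    """Rigidly rotate every mesh, contour and landmark of the scene.

    If the pose pivot is the origin default, the skull centroid is used
    (the head-clamp stand-in). Pairwise distances are preserved exactly up
    to floating point.
    """
    if pose.pivot == (0.0, 0.0, 0.0):
        pose = replace(pose, pivot=tuple(scene.skull.vertices.mean(axis=0)))
    # keep the fissure plane consistent with the rotated anatomy
    cfg = replace(
        scene.config,
        fissure_point=tuple(
            transform_points(np.asarray(scene.config.fissure_point)[None], pose)[0]
        ),
        fissure_normal=tuple(
            np.asarray(scene.config.fissure_normal, dtype=float) @ pose.rotation().T
        ),
    )
    return PhantomScene(
        skull=_transform_mesh(scene.skull, pose),
        brain_frontal=_transform_mesh(scene.brain_frontal, pose),
        brain_temporal=_transform_mesh(scene.brain_temporal, pose),
        vessel=_transform_contour(scene.vessel, pose),
        landmarks=[
            Landmark(lm.name, transform_points(lm.position[None], pose)[0])
            for lm in scene.landmarks
        ],
        templates=[_transform_contour(c, pose) for c in scene.templates],
        config=cfg,
    )
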