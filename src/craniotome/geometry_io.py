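"""Mesh and contour data model plus readers/writers.

Conventions shared by every module:

* units are millimetres;
* coordinate frame is right-handed, patient supine: ``+x`` left, ``+y``
  superior, ``+z`` anterior;
* meshes are cleaned on load — duplicate vertices merged within 1e-6 mm,
  degenerate (zero-area) faces dropped.

Mesh IO (STL / PLY / OBJ, geometry only) goes through :mod:`trimesh`;
contours are stored either as a CSV with header ``x,y,z`` plus a JSON
sidecar (``{"closed": ..., "name": ...}``) or as a single self-contained
JSON file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshIOError, ValidationError

log = logging.getLogger(__name__)

MERGE_TOL_MM = 1e-6
_FORMATS = ("stl", "ply", "obj")


@dataclass
class TriangleMesh:
    """Indexed triangle surface in millimetres.

    Attributes
    ----------
    vertices : (V, 3) float array
    faces : (F, 3) int array of vertex indices
    name : text label carried through IO
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValidationError(f"face indices out of range in mesh {self.name!r}")

    # -- derived geometry ------------------------------------------------
    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges as sorted (i, j) pairs, shape (E, 2)."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def boundary_edges(self) -> np.ndarray:
        """Edges referenced by exactly one face (sorted pairs)."""
        e = np.sort(
            np.vstack(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def is_watertight(self) -> bool:
        return len(self.faces) > 0 and len(self.boundary_edges()) == 0

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex loops of the boundary (empty when watertight)."""
        edges = self.boundary_edges()
        if len(edges) == 0:
            return []
        nbr: dict[int, list[int]] = {}
        for i, j in edges:
            nbr.setdefault(int(i), []).append(int(j))
            nbr.setdefault(int(j), []).append(int(i))
        loops: list[np.ndarray] = []
        unused = {tuple(e) for e in edges}
        while unused:
            i, j = next(iter(unused))
            loop = [i, j]
            unused.discard((i, j))
            while True:
                nxt = [k for k in nbr[loop[-1]] if tuple(sorted((loop[-1], k))) in unused]
                if not nxt:
                    break
                k = nxt[0]
                unused.discard(tuple(sorted((loop[-1], k))))
                if k == loop[0]:
                    break
                loop.append(k)
            loops.append(np.asarray(loop, dtype=np.int64))
        return loops

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, name: str = "") -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), name=name)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)


@dataclass
class SurfaceContour:
    """Ordered 3D polyline, optionally closed, in millimetres.

    Consecutive duplicate points are removed on construction; a closed
    contour treats last→first as an implicit segment (the first point is
    not repeated at the end).
    """

    points: np.ndarray
    closed: bool = False
    name: str = ""
    host_mesh: TriangleMesh | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(pts):
            keep = np.ones(len(pts), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > MERGE_TOL_MM
            pts = pts[keep]
            if self.closed and len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) <= MERGE_TOL_MM:
                pts = pts[:-1]
        if len(pts) < 2:
            raise ValidationError("contour needs at least 2 distinct points")
        self.points = pts

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment endpoint arrays (a, b); includes the wrap segment if closed."""
        a, b = self.points[:-1], self.points[1:]
        if self.closed:
            a = np.vstack([a, self.points[-1:]])
            b = np.vstack([b, self.points[:1]])
        return a, b

    def length(self) -> float:
        a, b = self.segments()
        return float(np.linalg.norm(b - a, axis=1).sum())

    def copy(self) -> "SurfaceContour":
        return SurfaceContour(self.points.copy(), self.closed, self.name, self.host_mesh)


@dataclass
class Landmark:
    """Named anatomical point (e.g. ``optic_nerve``, ``pterion``, ``target``)."""

    name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("landmark name must be non-empty")
        self.position = np.asarray(self.position, dtype=float).reshape(3)


# ---------------------------------------------------------------------------
# mesh IO
# ---------------------------------------------------------------------------

def _clean(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Merge duplicate vertices within MERGE_TOL_MM, drop degenerate faces."""
    mesh = mesh.copy()
    mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    areas = trimesh.triangles.area(mesh.triangles)
    mesh.update_faces(areas > 1e-12)
    mesh.remove_unreferenced_vertices()
    return mesh


def load_mesh(path: str | Path, format: str | None = None) -> TriangleMesh:
    """Load and clean an STL/PLY/OBJ mesh.

    The format is inferred from the extension unless given explicitly.
    Raises :class:`MeshIOError` on unreadable files and
    :class:`ValidationError` if nothing remains after cleaning.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValidationError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    try:
        raw = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - wrap all loader failures
        raise MeshIOError(f"cannot read mesh {path}: {exc}") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        raise ValidationError(f"mesh {path} is empty or not a triangle surface")
    cleaned = _clean(raw)
    if len(cleaned.faces) == 0 or len(cleaned.vertices) == 0:
        raise ValidationError(f"mesh {path} empty after cleaning")
    log.info(
        "loaded %s: %d vertices, %d faces (raw %d/%d)",
        path, len(cleaned.vertices), len(cleaned.faces), len(raw.vertices), len(raw.faces),
    )
    return TriangleMesh.from_trimesh(cleaned, name=path.stem)


def save_mesh(mesh: TriangleMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh as STL (binary), PLY (ASCII) or OBJ."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValidationError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    if len(mesh.faces) == 0 or len(mesh.vertices) == 0:
        raise ValidationError("refusing to write an empty mesh")
    try:
        tm = mesh.to_trimesh()
        if fmt == "ply":
            path.write_bytes(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))
        else:
            tm.export(str(path), file_type=fmt)
    except (OSError, ValueError) as exc:
        raise MeshIOError(f"cannot write mesh {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# contour IO
# ---------------------------------------------------------------------------

def save_contour(contour: SurfaceContour, path: str | Path) -> None:
    """Write a contour.

    ``.json`` → a single JSON document; anything else → CSV with header
    ``x,y,z`` plus a sidecar ``<stem>.json`` carrying ``closed``/``name``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "points": contour.points.tolist(),
            "closed": bool(contour.closed),
            "name": contour.name,
        }
        path.write_text(json.dumps(payload, indent=2))
        return
    lines = ["x,y,z"] + [f"{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}" for p in contour.points]
    try:
        path.write_text("\n".join(lines) + "\n")
        path.with_suffix(".json").write_text(
            json.dumps({"closed": bool(contour.closed), "name": contour.name})
        )
    except OSError as exc:
        raise MeshIOError(f"cannot write contour {path}: {exc}") from exc


def load_contour(path: str | Path) -> SurfaceContour:
    """Read a contour written by :func:`save_contour`.

    A bare CSV without sidecar loads as an open, unnamed polyline.
    """
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"contour file not found: {path}")
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return SurfaceContour(
            np.asarray(data["points"], dtype=float),
            closed=bool(data.get("closed", False)),
            name=str(data.get("name", "")),
        )
    try:
        pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise MeshIOError(f"cannot parse contour CSV {path}: {exc}") from exc
    closed, name = False, path.stem
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        closed = bool(meta.get("closed", False))
        name = str(meta.get("name", name))
    return SurfaceContour(pts, closed=closed, name=name)
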