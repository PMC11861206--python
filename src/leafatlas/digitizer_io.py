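"""Digitizer point-grid parsing and the raw leaf mesh.

A 3D digitizer records a maize leaf as ``n`` transects of 5 points each
(crossing the blade perpendicular to the midvein, ordered left to right,
base to tip) plus one final tip point, so a valid file always holds
``5*n + 1`` coordinate rows.  This module reads/writes those grids,
triangulates them into the raw 3D leaf mesh, and round-trips meshes
through OBJ/PLY with a JSON sidecar for vertex roles and units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import meshutil
from .errors import (
    DegenerateGeometryError,
    MalformedGridError,
    TooFewTransectsError,
    TopologyError,
    UnsupportedFormatError,
)

__all__ = [
    "ROLES",
    "DigitizedLeaf",
    "LeafMesh",
    "read_digitized_leaf",
    "write_digitized_leaf",
    "triangulate_grid",
    "write_mesh",
    "read_mesh",
]

#: Vertex role vocabulary.  Original grid vertices carry structural tags;
#: vertices added by subdivision are tagged ``inserted``.
ROLES = ("midvein", "left_edge", "right_edge", "tip", "interior", "inserted")

POINTS_PER_TRANSECT = 5
MIDVEIN_COLUMN = 2  # middle of the 5 evenly spaced probe points


@dataclass
class DigitizedLeaf:
    """Ordered raw point grid of one digitized leaf.

    Parameters
    ----------
    line_id, sample_id
        Inbred-line and replicate labels.
    transects
        ``(n, 5, 3)`` array, transects ordered base to tip, points within a
        transect ordered left to right.  Units: cm.
    tip
        The single leaf-tip point, shape ``(3,)``.
    """

    line_id: str
    sample_id: str
    transects: np.ndarray
    tip: np.ndarray

    def __post_init__(self):
        self.transects = np.asarray(self.transects, dtype=float)
        self.tip = np.asarray(self.tip, dtype=float).reshape(3)
        if self.transects.ndim != 3 or self.transects.shape[1:] != (5, 3):
            raise MalformedGridError(
                f"transects must have shape (n, 5, 3), got {self.transects.shape}")
        if self.n_transects < 2:
            raise TooFewTransectsError(
                f"need at least 2 transects, got {self.n_transects}")
        pts = self.points
        if not np.all(np.isfinite(pts)):
            raise MalformedGridError("non-finite coordinates in grid")
        # exact duplicates indicate a probe misfire
        uniq = np.unique(pts, axis=0)
        if len(uniq) != len(pts):
            raise MalformedGridError("grid contains exactly coincident points")

    @property
    def n_transects(self) -> int:
        return self.transects.shape[0]

    @property
    def n_points(self) -> int:
        """Total point count; always ``5*n + 1``."""
        return self.transects.shape[0] * POINTS_PER_TRANSECT + 1

    @property
    def points(self) -> np.ndarray:
        """All points in acquisition order, shape ``(5n+1, 3)``."""
        return np.vstack([self.transects.reshape(-1, 3), self.tip[None, :]])


@dataclass
class LeafMesh:
    """Indexed triangle mesh of one leaf, 3D (cm-scaled) or 2D (flattened).

    ``scale_to_cm`` restores physical units after the [-1, 1] normalization:
    multiplying vertex coordinates by it yields centimetres.
    """

    vertices: np.ndarray
    faces: np.ndarray
    roles: np.ndarray
    scale_to_cm: float = 1.0
    line_id: str = ""
    sample_id: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.roles = np.asarray(self.roles, dtype=object)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise UnsupportedFormatError("faces must be an (F, 3) index array")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise TopologyError("face references an out-of-range vertex index")
        if np.any(self.faces[:, 0] == self.faces[:, 1]) or \
           np.any(self.faces[:, 1] == self.faces[:, 2]) or \
           np.any(self.faces[:, 0] == self.faces[:, 2]):
            raise TopologyError("face with repeated vertex index")
        if len(self.roles) != len(self.vertices):
            raise ValueError("roles must have one tag per vertex")
        if self.scale_to_cm <= 0:
            raise ValueError("scale_to_cm must be positive")

    # -- basic queries ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_2d(self) -> bool:
        return self.vertices.shape[1] == 2

    def vertices_cm(self) -> np.ndarray:
        return self.vertices * self.scale_to_cm

    def role_indices(self, role: str) -> np.ndarray:
        """Indices of vertices tagged ``role``, in ascending (base-to-tip) order."""
        return np.flatnonzero(self.roles == role)

    def tip_index(self) -> int:
        idx = self.role_indices("tip")
        if len(idx) != 1:
            raise TopologyError(f"expected exactly one tip vertex, found {len(idx)}")
        return int(idx[0])

    def triangle_areas(self) -> np.ndarray:
        return meshutil.triangle_areas(self.vertices, self.faces)

    def total_area_cm2(self) -> float:
        return float(self.triangle_areas().sum()) * self.scale_to_cm ** 2

    def boundary_loop(self) -> np.ndarray:
        return meshutil.boundary_loop(self.faces)

    def copy(self) -> "LeafMesh":
        return LeafMesh(self.vertices.copy(), self.faces.copy(), self.roles.copy(),
                        self.scale_to_cm, self.line_id, self.sample_id)


# ---------------------------------------------------------------------------
# Grid file I/O
# ---------------------------------------------------------------------------

def read_digitized_leaf(path, line_id: str = "", sample_id: str = "") -> DigitizedLeaf:
    """Read a plain-text digitizer grid.

    One point per line (``x y z`` in cm, whitespace or comma separated) in
    acquisition order; lines starting with ``#`` are comments.  The row count
    must equal ``5*n + 1`` with ``n >= 2``.
    """
    path = Path(path)
    rows = []
    for raw in path.read_text().splitlines():
        s = raw.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.replace(",", " ").split()
        if len(parts) != 3:
            raise MalformedGridError(f"{path}: expected 3 coordinates, got {len(parts)!r}")
        rows.append([float(p) for p in parts])
    pts = np.asarray(rows, dtype=float)
    if len(pts) % POINTS_PER_TRANSECT != 1:
        raise MalformedGridError(
            f"{path}: {len(pts)} points is not of the form 5n+1")
    n = len(pts) // POINTS_PER_TRANSECT
    if n < 2:
        raise TooFewTransectsError(f"{path}: only {n} transect(s), need >= 2")
    if not line_id:
        line_id = path.stem.split("_")[0]
    if not sample_id:
        sample_id = path.stem
    return DigitizedLeaf(line_id, sample_id,
                         pts[:-1].reshape(n, POINTS_PER_TRANSECT, 3), pts[-1])


def write_digitized_leaf(leaf: DigitizedLeaf, path) -> None:
    """Write a grid file readable by :func:`read_digitized_leaf`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# line={leaf.line_id} sample={leaf.sample_id}\n")
        fh.write(f"# {leaf.n_transects} transects, 5 points each, tip last\n")
        for p in leaf.points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


# ---------------------------------------------------------------------------
# Grid triangulation
# ---------------------------------------------------------------------------

def triangulate_grid(leaf: DigitizedLeaf) -> LeafMesh:
    """Triangulate the structured digitizer grid into the raw 3D leaf mesh.

    Each quad between consecutive transects is split along the diagonal from
    its lower-left to upper-right corner; the tip is joined by a 4-triangle
    fan to the last transect.  Face count is therefore ``8*(n-1) + 4``.
    """
    n = leaf.n_transects
    vertices = leaf.points
    tip = 5 * n  # index of the tip vertex

    faces = []
    for t in range(n - 1):
        for c in range(4):
            ll = 5 * t + c          # lower-left
            lr = 5 * t + c + 1      # lower-right
            ul = 5 * (t + 1) + c    # upper-left
            ur = 5 * (t + 1) + c + 1
            faces.append((ll, lr, ur))
            faces.append((ll, ur, ul))
    for c in range(4):
        faces.append((5 * (n - 1) + c, 5 * (n - 1) + c + 1, tip))
    faces = np.asarray(faces, dtype=np.int64)

    areas = meshutil.triangle_areas(vertices, faces)
    if np.any(areas <= 1e-12):
        bad = int(np.argmin(areas))
        transect = int(faces[bad].min()) // 5
        raise DegenerateGeometryError(
            f"degenerate (zero-area) triangle near transect {transect}")

    roles = np.full(len(vertices), "interior", dtype=object)
    cols = np.arange(5 * n) % 5
    roles[np.flatnonzero(cols == 0)] = "left_edge"
    roles[np.flatnonzero(cols == MIDVEIN_COLUMN)] = "midvein"
    roles[np.flatnonzero(cols == 4)] = "right_edge"
    roles[tip] = "tip"

    return LeafMesh(vertices, faces, roles, 1.0, leaf.line_id, leaf.sample_id)


# ---------------------------------------------------------------------------
# Mesh file I/O (OBJ / PLY via trimesh, roles in a JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".roles.json")


def write_mesh(mesh: LeafMesh, path, fmt: str | None = None) -> None:
    """Write a mesh as OBJ or PLY; 2D meshes are stored with z = 0.

    Role tags, ``scale_to_cm``, identity, and the 2D flag go to a
    ``<path>.roles.json`` sidecar so round-trips are lossless.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply"):
        raise UnsupportedFormatError(f"unsupported mesh format: {fmt!r}")
    v = mesh.vertices
    if mesh.is_2d:
        v = np.column_stack([v, np.zeros(len(v))])
    tm = trimesh.Trimesh(vertices=v, faces=mesh.faces, process=False)
    tm.export(str(path), file_type=fmt)
    sidecar = {
        "roles": list(map(str, mesh.roles)),
        "scale_to_cm": mesh.scale_to_cm,
        "line_id": mesh.line_id,
        "sample_id": mesh.sample_id,
        "is_2d": mesh.is_2d,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_mesh(path, fmt: str | None = None) -> LeafMesh:
    """Read an OBJ/PLY written by :func:`write_mesh` (sidecar optional)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply"):
        raise UnsupportedFormatError(f"unsupported mesh format: {fmt!r}")
    if fmt == "obj":
        # trimesh silently triangulates polygons; reject them up front
        for raw in path.read_text().splitlines():
            if raw.startswith("f ") and len(raw.split()) > 4:
                raise UnsupportedFormatError(f"{path}: mesh contains non-triangle faces")
    tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise UnsupportedFormatError(f"{path}: mesh contains non-triangle faces")
    vertices = np.asarray(tm.vertices, dtype=float)

    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        meta = json.loads(sidecar_file.read_text())
        roles = np.asarray(meta["roles"], dtype=object)
        if meta.get("is_2d", False):
            vertices = vertices[:, :2]
        return LeafMesh(vertices, faces, roles, float(meta.get("scale_to_cm", 1.0)),
                        meta.get("line_id", ""), meta.get("sample_id", ""))
    roles = np.full(len(vertices), "interior", dtype=object)
    return LeafMesh(vertices, faces, roles)
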