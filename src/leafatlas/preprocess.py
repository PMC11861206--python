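"""Replicate screening, mesh normalization and sqrt(3) subdivision.

Preprocessing turns the raw digitizer meshes into clean, canonically
oriented, refined 3D meshes ready for planar flattening:

1. *Replicate screening* drops the odd sample out of a 3-replicate group
   when its 4-feature Euclidean distance to both siblings exceeds the
   sibling pair's own distance by more than a fixed margin (default 0.1 on
   min-max scaled features).
2. *Normalization* rotates each mesh onto its principal axes (tip toward
   +x, left margin at y > 0), centres the centroid at the origin, and
   scales coordinates into [-1, 1]; the inverse scale is kept so features
   can be reported in centimetres.
3. *sqrt(3) subdivision* refines the triangulation: one vertex inserted per
   face centroid, interior original edges flipped, interior original
   vertices relaxed; face count triples per iteration (9x after the
   standard two iterations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import meshutil
from .digitizer_io import LeafMesh
from .errors import DegenerateGeometryError, LeafAtlasError, MissingRolesError, TopologyError

__all__ = [
    "ScreeningRecord",
    "raw_screen_features",
    "screen_replicates",
    "normalize_mesh",
    "sqrt3_subdivide",
]

SCREEN_FEATURE_NAMES = ("leaf_length", "leaf_width", "aspect_ratio", "mesh_average_angle")


@dataclass
class ScreeningRecord:
    """Per-sample screening outcome within an inbred line."""

    line_id: str
    sample_id: str
    screen_features: np.ndarray  # (length, width, aspect ratio, mean normal angle)
    excluded: bool = False
    reason: str = ""

    def __post_init__(self):
        self.screen_features = np.asarray(self.screen_features, dtype=float).reshape(4)
        if not np.all(np.isfinite(self.screen_features)):
            raise LeafAtlasError(f"{self.sample_id}: non-finite screening features")
        if self.screen_features[0] <= 0 or self.screen_features[1] <= 0:
            raise LeafAtlasError(f"{self.sample_id}: non-positive leaf length/width")


def _mean_adjacent_normal_angle(mesh: LeafMesh) -> float:
    """Mean over faces of the mean angle to edge-neighbour normals.

    Same statistic as the folding feature FA; angles use the absolute dot
    product so face orientation does not matter.  A planar mesh gives 0.
    """
    if mesh.is_2d:
        return 0.0
    normals = meshutil.face_normals(mesh.vertices, mesh.faces)
    adjacency = meshutil.face_adjacency(mesh.faces)
    per_face = []
    for i, nbrs in enumerate(adjacency):
        if not nbrs:
            continue
        dots = np.abs(normals[nbrs] @ normals[i])
        per_face.append(float(np.mean(np.arccos(np.clip(dots, -1.0, 1.0)))))
    return float(np.mean(per_face)) if per_face else 0.0


def raw_screen_features(mesh: LeafMesh) -> np.ndarray:
    """The 4 screening features: length, max width, aspect ratio, mean angle.

    Length is the midvein polyline arclength (base to tip), width the
    maximum transect width (left-to-right margin distance), aspect ratio
    their quotient, and the angle term the mean adjacent-face normal angle.
    All lengths in cm.
    """
    mid = mesh.role_indices("midvein")
    left = mesh.role_indices("left_edge")
    right = mesh.role_indices("right_edge")
    if len(mid) == 0 or len(left) == 0 or len(right) == 0:
        raise MissingRolesError("mesh lacks midvein/left_edge/right_edge role tags")
    v = mesh.vertices_cm()
    chain = np.vstack([v[mid], v[mesh.tip_index()][None, :]])
    length = float(np.linalg.norm(np.diff(chain, axis=0), axis=1).sum())
    if len(left) != len(right):
        raise MissingRolesError("left/right edge chains have different lengths")
    width = float(np.linalg.norm(v[left] - v[right], axis=1).max())
    angle = _mean_adjacent_normal_angle(mesh)
    return np.array([length, width, length / width, angle])


def screen_replicates(records: list[ScreeningRecord],
                      threshold: float = 0.1) -> list[ScreeningRecord]:
    """Flag the outlier replicate in 3-sample groups.

    Features are min-max scaled to [0, 1] per feature over *all* records so
    the threshold is dimensionless.  Within each 3-sample line, if one
    sample's scaled Euclidean distances to both others exceed the remaining
    pair's mutual distance by more than ``threshold``, that sample is marked
    ``excluded``.  Groups of one or two samples are never screened.
    """
    if not records:
        raise LeafAtlasError("empty record list")
    X = np.stack([r.screen_features for r in records])
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    S = (X - lo) / span

    by_line: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_line.setdefault(r.line_id, []).append(i)

    out = [ScreeningRecord(r.line_id, r.sample_id, r.screen_features.copy())
           for r in records]
    for line_id, idx in by_line.items():
        if len(idx) == 0:
            raise LeafAtlasError(f"empty group for line {line_id}")
        if len(idx) != 3:
            continue
        i, j, k = idx
        d = {(a, b): float(np.linalg.norm(S[a] - S[b]))
             for a, b in ((i, j), (i, k), (j, k))}
        trios = [(i, d[(i, j)], d[(i, k)], d[(j, k)]),
                 (j, d[(i, j)], d[(j, k)], d[(i, k)]),
                 (k, d[(i, k)], d[(j, k)], d[(i, j)])]
        for cand, d1, d2, rest in trios:
            if d1 > rest + threshold and d2 > rest + threshold:
                out[cand].excluded = True
                out[cand].reason = (
                    f"distances {d1:.3f}/{d2:.3f} exceed sibling pair "
                    f"distance {rest:.3f} by more than {threshold}")
                break
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_mesh(mesh: LeafMesh) -> LeafMesh:
    """Canonically orient, centre and scale a 3D leaf mesh.

    Principal axes (by descending variance) map to x, y, z; signs are fixed
    so the tip has the largest x and the base left-margin vertex has y > 0;
    the z axis completes a right-handed frame.  The centroid moves to the
    origin and coordinates are scaled so max |coordinate| = 1 exactly;
    ``scale_to_cm`` accumulates the inverse scale.
    """
    v = mesh.vertices
    if v.shape[1] != 3:
        raise DegenerateGeometryError("normalize_mesh expects a 3D mesh")
    centroid = v.mean(axis=0)
    centered = v - centroid
    # principal axes from the vertex covariance
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-12 * max(svals[0], 1.0):
        raise DegenerateGeometryError("vertex cloud is (near) collinear")
    axes = vt  # rows = principal directions, descending variance

    tip = mesh.tip_index()
    if centered[tip] @ axes[0] < 0:
        axes[0] = -axes[0]
    left = mesh.role_indices("left_edge")
    if len(left) == 0:
        raise MissingRolesError("mesh lacks left_edge role tags")
    base_left = int(left[0])
    if centered[base_left] @ axes[1] < 0:
        axes[1] = -axes[1]
    axes[2] = np.cross(axes[0], axes[1])  # right-handed frame

    rotated = centered @ axes.T
    extent = float(np.abs(rotated).max())
    if extent <= 0:
        raise DegenerateGeometryError("zero-extent vertex cloud")
    out = mesh.copy()
    out.vertices = rotated / extent
    out.scale_to_cm = mesh.scale_to_cm * extent
    return out


# ---------------------------------------------------------------------------
# sqrt(3) subdivision
# ---------------------------------------------------------------------------

def _sqrt3_alpha(n: int) -> float:
    # relaxation coefficient of the sqrt(3) scheme for valence n
    return (4.0 - 2.0 * np.cos(2.0 * np.pi / n)) / 9.0


def _sqrt3_once(mesh: LeafMesh) -> LeafMesh:
    V, F = mesh.vertices, mesh.faces
    nV, nF = len(V), len(F)

    edges, counts, edge_to_faces = meshutil.undirected_edges(F)
    if np.any(counts > 2):
        raise TopologyError("non-manifold edge: more than two incident faces")

    centroids = V[F].mean(axis=1)
    cidx = nV + np.arange(nF)

    # relax interior original vertices using original neighbour positions
    boundary_vertices = set(np.unique(edges[counts == 1]).tolist())
    adjacency = meshutil.vertex_adjacency(F, nV)
    newV = np.vstack([V, centroids])
    for p in range(nV):
        nbrs = adjacency[p]
        if p in boundary_vertices or not nbrs:
            continue
        n = len(nbrs)
        a = _sqrt3_alpha(n)
        newV[p] = (1.0 - a) * V[p] + (a / n) * V[list(nbrs)].sum(axis=0)

    faces_new = []
    for incidences in edge_to_faces.values():
        if len(incidences) == 1:
            f, a, b = incidences[0]
            faces_new.append((a, b, cidx[f]))
        else:
            (f1, a, b), (f2, _, _) = incidences
            c1, c2 = cidx[f1], cidx[f2]
            # flip the original edge a-b to the centroid-centroid diagonal
            faces_new.append((a, c2, c1))
            faces_new.append((b, c1, c2))

    roles = np.concatenate([mesh.roles, np.full(nF, "inserted", dtype=object)])
    return LeafMesh(newV, np.asarray(faces_new, dtype=np.int64), roles,
                    mesh.scale_to_cm, mesh.line_id, mesh.sample_id)


def sqrt3_subdivide(mesh: LeafMesh, iterations: int = 2) -> LeafMesh:
    """Refine a manifold triangle disk mesh by sqrt(3) subdivision.

    Per iteration: a vertex is inserted at every face centroid and joined to
    the face corners, every *interior* original edge is flipped, and interior
    original vertices are relaxed toward their neighbours with the
    valence-dependent coefficient ``(4 - 2 cos(2 pi / n)) / 9``.  Boundary
    vertices stay fixed, preserving the digitized leaf margin.  The face
    count triples per iteration and original vertices keep their indices and
    role tags.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = mesh.copy()
    for _ in range(iterations):
        out = _sqrt3_once(out)
    return out
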