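"""Leaf contour extraction, radial sampling, averaging and segmentation.

The flattened 2D leaf mesh is an open disk whose boundary edges form the
leaf silhouette.  A ray is swept from the leaf centre (the origin, where
the mesh centroid is pinned) over ``R`` evenly spaced angles (default 600)
and intersected with the boundary polyline; the farthest intersection per
ray yields an ordered, angle-indexed contour that can be averaged
point-wise across replicates and inbred lines and partitioned into six
angular sectors (tip, base, upper/lower left/right) for contour features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import meshutil
from .digitizer_io import LeafMesh
from .errors import ConfigError, LeafAtlasError, TopologyError

__all__ = [
    "DEFAULT_RESOLUTION",
    "SampledContour",
    "extract_boundary",
    "sample_contour",
    "average_contours",
    "segment_contour",
    "contour_from_mesh",
]

DEFAULT_RESOLUTION = 600
SECTOR_NAMES = ("tip", "upper_left", "lower_left", "base", "lower_right", "upper_right")


@dataclass
class SampledContour:
    """Angle-indexed leaf contour: point ``k`` lies on the ray at angle
    ``2*pi*k/R`` from the origin.  Coordinates in cm."""

    points: np.ndarray
    line_id: str = ""
    sample_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise LeafAtlasError("contour points must be an (R, 2) array")

    @property
    def resolution(self) -> int:
        return len(self.points)

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.resolution) / self.resolution

    @property
    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.points, axis=1)

    def polygon_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def extract_boundary(mesh2d: LeafMesh) -> np.ndarray:
    """Boundary of a 2D disk mesh as a closed CCW polyline, in cm.

    Returns an ``(B+1, 2)`` array whose last point repeats the first.
    """
    if not mesh2d.is_2d:
        raise TopologyError("extract_boundary expects a 2D mesh")
    loop = meshutil.boundary_loop(mesh2d.faces)
    pts = mesh2d.vertices_cm()[loop]
    x, y = pts[:, 0], pts[:, 1]
    signed = 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if signed < 0:
        pts = pts[::-1]
    return np.vstack([pts, pts[:1]])


def sample_contour(boundary: np.ndarray, resolution: int = DEFAULT_RESOLUTION,
                   line_id: str = "", sample_id: str = "",
                   tol: float = 1e-12) -> SampledContour:
    """Radially sample a closed boundary polyline from the origin.

    For each of ``resolution`` ray angles the ray is intersected with every
    boundary segment and the farthest intersection kept, yielding the outer
    silhouette even at zigzag margins.  The origin must lie inside the
    polygon (every ray must hit).
    """
    boundary = np.asarray(boundary, dtype=float)
    if not np.allclose(boundary[0], boundary[-1]):
        boundary = np.vstack([boundary, boundary[:1]])
    p = boundary[:-1]          # (Nseg, 2) segment starts
    q = boundary[1:]           # segment ends
    seg = q - p

    angles = 2.0 * np.pi * np.arange(resolution) / resolution
    d = np.column_stack([np.cos(angles), np.sin(angles)])  # (R, 2)

    # ray: r * d, segment: p + s * seg; solve [d, -seg] [r, s]^T = p
    # cross-product form: s = cross(d, p) / cross(d, seg); r = cross(p, seg) / cross(seg, d)
    cross_d_seg = d[:, 0][:, None] * seg[:, 1][None, :] - d[:, 1][:, None] * seg[:, 0][None, :]
    cross_d_p = d[:, 0][:, None] * p[:, 1][None, :] - d[:, 1][:, None] * p[:, 0][None, :]
    cross_p_seg = (p[:, 0] * seg[:, 1] - p[:, 1] * seg[:, 0])[None, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        s = -cross_d_p / cross_d_seg
        r = cross_p_seg / cross_d_seg
    valid = (np.abs(cross_d_seg) > tol) & (s >= -tol) & (s <= 1.0 + tol) & (r > tol)
    r = np.where(valid, r, -np.inf)
    rmax = r.max(axis=1)
    if np.any(~np.isfinite(rmax)):
        k = int(np.flatnonzero(~np.isfinite(rmax))[0])
        raise LeafAtlasError(
            f"ray at angle {angles[k]:.4f} rad has no boundary intersection; "
            "is the origin inside the contour?")
    pts = rmax[:, None] * d
    return SampledContour(pts, line_id=line_id, sample_id=sample_id)


def average_contours(samples: list[SampledContour], line_id: str = "ALL") -> SampledContour:
    """Point-wise arithmetic mean of equally-resolved contours."""
    if not samples:
        raise LeafAtlasError("no contours to average")
    res = {s.resolution for s in samples}
    if len(res) != 1:
        raise LeafAtlasError(f"mixed contour resolutions: {sorted(res)}")
    pts = np.mean([s.points for s in samples], axis=0)
    return SampledContour(pts, line_id=line_id, sample_id="mean")


def segment_contour(contour: SampledContour, theta_tip: float = np.deg2rad(15.0),
                    theta_base: float = np.deg2rad(15.0)) -> dict[str, np.ndarray]:
    """Partition contour point indices into the six leaf sectors.

    With the tip at +x and the left margin at y > 0, sectors are defined by
    the ray angle ``a`` wrapped to (-pi, pi]: tip ``|a| <= theta_tip``, base
    ``|a| >= pi - theta_base``, the left half (a > 0) split at pi/2 into
    upper-left (toward the tip) and lower-left, mirrored on the right.
    Every point falls in exactly one sector.
    """
    if not (0 < theta_tip < np.pi / 2) or not (0 < theta_base < np.pi / 2):
        raise ConfigError("sector half-angles must lie in (0, pi/2)")
    a = np.mod(contour.angles + np.pi, 2.0 * np.pi) - np.pi  # wrap to (-pi, pi]
    sectors = {
        "tip": np.abs(a) <= theta_tip,
        "base": np.abs(a) >= np.pi - theta_base,
        "upper_left": (a > theta_tip) & (a <= np.pi / 2),
        "lower_left": (a > np.pi / 2) & (a < np.pi - theta_base),
        "upper_right": (a < -theta_tip) & (a >= -np.pi / 2),
        "lower_right": (a < -np.pi / 2) & (a > -(np.pi - theta_base)),
    }
    counts = np.sum([m.sum() for m in sectors.values()])
    if counts != contour.resolution:
        raise ConfigError("sector definition does not partition the contour")
    return {name: np.flatnonzero(mask) for name, mask in sectors.items()}


def contour_from_mesh(mesh2d: LeafMesh, resolution: int = DEFAULT_RESOLUTION) -> SampledContour:
    """Convenience: extract the boundary of a 2D mesh and radially sample it."""
    boundary = extract_boundary(mesh2d)
    return sample_contour(boundary, resolution,
                          line_id=mesh2d.line_id, sample_id=mesh2d.sample_id)
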