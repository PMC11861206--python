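"""The 29 morphometric leaf-shape features.

Seventeen mesh features are measured on the flattened 2D leaf (lengths of
the left margin, right margin and midvein; widths at the digitizer
transects; areas; tip, offset and tortuosity angles) plus the two folding
statistics FA/FV measured on the 3D surface; twelve contour features are
mean centre distances of the six contour sectors and their combinations.

Identifiers follow the field convention:

========  =========================================================  =====
LL/RL/ML  left / right margin and midvein arclengths                 cm
WA/WM/WV  mean / max / variance of transect widths                   cm,cm2
WP        relative midvein position of the widest transect           --
LWR       ML / WA                                                    --
LTA       interior angle at the tip vertex                           rad
LOA/ROA/  summed absolute turning angles of the left/right margin    rad
MOA       and midvein polylines
MTA/MTV   mean / variance of midvein-segment angle to base-tip chord rad
A         triangle-sum leaf area                                     cm2
FA/FV     mean / variance of per-face mean dihedral normal angles    rad
TP..BP    per-sector mean contour radius (tip, upper/lower x2, base) cm
UP/LP     mean radius of both upper / both lower sectors             cm
L, W      TP + BP and (LUP + LLP + RUP + RLP) / 2                    cm
UL, LW    UP - LP and L / W                                          cm, --
========  =========================================================  =====

Variances use the population convention (divide by N): the features are
shape descriptors, not estimators of a sampling distribution.
"""

from __future__ import annotations

import numpy as np

from .arap import fold_field
from .contour import SampledContour, segment_contour
from .digitizer_io import LeafMesh
from .errors import FeatureError, MissingRolesError
from .meshutil import boundary_loop

__all__ = [
    "FEATURE_NAMES",
    "MESH_FEATURES",
    "CONTOUR_FEATURES",
    "edge_and_midvein_features",
    "width_features",
    "area_feature",
    "folding_features",
    "contour_features",
    "extract_all",
]

MESH_FEATURES = ("LL", "RL", "ML", "WA", "WM", "WV", "WP", "LWR", "LTA",
                 "LOA", "ROA", "MOA", "MTA", "MTV", "A", "FA", "FV")
CONTOUR_FEATURES = ("TP", "RUP", "LUP", "RLP", "LLP", "BP", "UP", "LP",
                    "L", "W", "UL", "LW")
FEATURE_NAMES = MESH_FEATURES + CONTOUR_FEATURES


def _chain(mesh: LeafMesh, role: str) -> np.ndarray:
    """Base-to-tip polyline of an original role chain, ending at the tip, cm."""
    idx = mesh.role_indices(role)
    if len(idx) < 2:
        raise MissingRolesError(f"mesh lacks a {role} chain")
    v = mesh.vertices_cm()
    return np.vstack([v[idx], v[mesh.tip_index()][None, :]])


def _arclength(chain: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(chain, axis=0), axis=1).sum())


def _turning_angle_sum(chain: np.ndarray) -> float:
    """Sum of absolute exterior (turning) angles along a polyline."""
    seg = np.diff(chain, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    keep = norms > 1e-14
    seg = seg[keep] / norms[keep][:, None]
    if len(seg) < 2:
        return 0.0
    dots = np.clip(np.einsum("ij,ij->i", seg[:-1], seg[1:]), -1.0, 1.0)
    return float(np.arccos(dots).sum())


def edge_and_midvein_features(mesh2d: LeafMesh) -> dict[str, float]:
    """Arclengths, offset angles, tortuosity and tip angle of a 2D mesh."""
    left = _chain(mesh2d, "left_edge")
    right = _chain(mesh2d, "right_edge")
    mid = _chain(mesh2d, "midvein")

    out = {
        "LL": _arclength(left),
        "RL": _arclength(right),
        "ML": _arclength(mid),
        "LOA": _turning_angle_sum(left),
        "ROA": _turning_angle_sum(right),
        "MOA": _turning_angle_sum(mid),
    }

    # midvein tortuosity: unsigned angle of each midvein segment to the
    # base-to-tip chord
    chord = mid[-1] - mid[0]
    cn = np.linalg.norm(chord)
    if cn <= 1e-14:
        raise FeatureError("midvein base and tip coincide")
    chord = chord / cn
    seg = np.diff(mid, axis=0)
    seg = seg / np.linalg.norm(seg, axis=1)[:, None]
    ang = np.arccos(np.clip(seg @ chord, -1.0, 1.0))
    out["MTA"] = float(ang.mean())
    out["MTV"] = float(ang.var())

    # leaf tip angle: interior angle at the tip vertex between its two
    # neighbouring boundary vertices
    tip = mesh2d.tip_index()
    loop = boundary_loop(mesh2d.faces)
    where = np.flatnonzero(loop == tip)
    if len(where) != 1:
        raise FeatureError("tip vertex is not on the mesh boundary")
    k = int(where[0])
    v = mesh2d.vertices_cm()
    a = v[loop[(k - 1) % len(loop)]] - v[tip]
    b = v[loop[(k + 1) % len(loop)]] - v[tip]
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    out["LTA"] = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return out


def width_features(mesh2d: LeafMesh) -> dict[str, float]:
    """Transect widths: mean, max, variance, widest position, aspect ratio.

    Widths are left-to-right margin distances at the original digitizer
    transects (tracked through subdivision via role tags); WP is the midvein
    arclength from the base to the widest transect divided by ML, ties going
    to the station nearest the base.
    """
    left = mesh2d.role_indices("left_edge")
    right = mesh2d.role_indices("right_edge")
    mid = mesh2d.role_indices("midvein")
    if len(left) != len(right) or len(left) != len(mid):
        raise MissingRolesError("left/right/midvein chains must align per transect")
    if len(left) < 2:
        raise FeatureError("need at least 2 transect stations")
    v = mesh2d.vertices_cm()
    widths = np.linalg.norm(v[left] - v[right], axis=1)

    mid_chain = np.vstack([v[mid], v[mesh2d.tip_index()][None, :]])
    seg_len = np.linalg.norm(np.diff(mid_chain, axis=0), axis=1)
    ml = float(seg_len.sum())
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])[:len(mid)]

    widest = int(np.argmax(widths))  # argmax takes the first = nearest base on ties
    wa = float(widths.mean())
    return {
        "WA": wa,
        "WM": float(widths.max()),
        "WV": float(widths.var()),
        "WP": float(cum[widest] / ml),
        "LWR": ml / wa,
    }


def area_feature(mesh2d: LeafMesh) -> float:
    """Leaf area as the sum of all triangle areas, in cm^2."""
    return mesh2d.total_area_cm2()


def traditional_area(ml: float, wm: float, coefficient: float = 0.75) -> float:
    """The classical length x max-width x coefficient approximation, for
    comparison against the triangle-sum area."""
    return ml * wm * coefficient


def folding_features(mesh3d: LeafMesh) -> dict[str, float]:
    """Folding degree FA/FV of the 3D surface.

    For each face the mean angle between its normal and each edge-adjacent
    face's normal is taken with ``alpha(x, y) = arccos(|x.y| / (|x||y|))``
    (orientation independent, range [0, pi/2]); FA is the mean and FV the
    population variance of the per-face means.  A flat mesh gives FA=FV=0.
    """
    if mesh3d.is_2d:
        return {"FA": 0.0, "FV": 0.0}
    field = fold_field(mesh3d)
    return {"FA": float(field.mean()), "FV": float(field.var())}


def contour_features(contour: SampledContour,
                     parts: dict[str, np.ndarray] | None = None) -> dict[str, float]:
    """Sector mean-radius features of a sampled contour (all in cm)."""
    if parts is None:
        parts = segment_contour(contour)
    radii = contour.radii
    means = {}
    for name, idx in parts.items():
        if len(idx) == 0:
            raise FeatureError(f"contour sector {name!r} is empty")
        means[name] = float(radii[idx].mean())
    up = 0.5 * (means["upper_left"] + means["upper_right"])
    lp = 0.5 * (means["lower_left"] + means["lower_right"])
    L = means["tip"] + means["base"]
    W = 0.5 * (means["upper_left"] + means["lower_left"]
               + means["upper_right"] + means["lower_right"])
    return {
        "TP": means["tip"],
        "RUP": means["upper_right"],
        "LUP": means["upper_left"],
        "RLP": means["lower_right"],
        "LLP": means["lower_left"],
        "BP": means["base"],
        "UP": up,
        "LP": lp,
        "L": L,
        "W": W,
        "UL": up - lp,
        "LW": L / W,
    }


def extract_all(mesh2d: LeafMesh, mesh3d: LeafMesh,
                contour: SampledContour) -> dict[str, float]:
    """All 29 features of one leaf, as an identifier -> value mapping.

    The definitional identities ``LWR = ML/WA``, ``LW = L/W`` and
    ``UL = UP - LP`` hold exactly by construction.
    """
    out: dict[str, float] = {}
    out.update(edge_and_midvein_features(mesh2d))
    out.update(width_features(mesh2d))
    out["A"] = area_feature(mesh2d)
    out.update(folding_features(mesh3d))
    out.update(contour_features(contour))
    return {name: out[name] for name in FEATURE_NAMES}
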