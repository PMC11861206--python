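"""Parametric synthetic maize-leaf generator with known ground truth.

Real digitizer campaigns are not redistributable, so populations of
digitizer-format leaves are simulated instead.  A leaf is built around an
arc-length parameterized midvein curve that bends in the vertical plane
(maize ear leaves arch from the sheath toward the tip); at ``n`` evenly
spaced stations, five points are placed across the local width following a
smooth lanceolate width profile, with optional cumulative twist about the
midvein, sinusoidal margin waves on the two edge columns, and a transverse
fold field concentrated in the lower-middle region of the blade, where
fold amplitude is largest on real ear leaves.  With all deformations at
zero the generated grid is exactly planar.

Populations draw line-level parameters from uniform ranges covering
realistic ear-leaf morphology (length 60-105 cm, width 6-12 cm at silking)
and add small within-line replicate jitter, so between-line variation
dominates within-line variation as in a real inbred panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digitizer_io import DigitizedLeaf
from .errors import LeafAtlasError

__all__ = ["LeafParams", "PopulationSpec", "generate_leaf", "generate_population"]


@dataclass
class LeafParams:
    """Ground-truth parameters of one synthetic leaf.

    ``bend_curvature`` is the (constant) midvein curvature in rad/cm;
    ``twist_total`` the cumulative blade twist base-to-tip in rad;
    ``wave_amp``/``wave_freq`` the margin waviness amplitude (cm) and number
    of periods along the blade; ``fold_amp`` (cm) and ``fold_freq`` the
    transverse surface fold field.  ``widest_frac`` is the relative midvein
    position of maximum width.
    """

    length_cm: float = 80.0
    max_width_cm: float = 9.0
    widest_frac: float = 0.4
    bend_curvature: float = 0.02
    twist_total: float = 0.0
    wave_amp: float = 0.0
    wave_freq: float = 3.0
    wave_phase: float | None = None  # None: drawn from ``seed``
    fold_amp: float = 0.0
    fold_freq: float = 2.0
    n_transects: int = 13
    seed: int = 0

    def __post_init__(self):
        if self.length_cm <= 0 or self.max_width_cm <= 0:
            raise LeafAtlasError("length and width must be positive")
        if not 0 < self.widest_frac < 1:
            raise LeafAtlasError("widest_frac must lie in (0, 1)")
        if self.n_transects < 2:
            raise LeafAtlasError("need at least 2 transects")
        if self.fold_amp > 0.25 * self.max_width_cm:
            raise LeafAtlasError(
                "fold_amp too large: surface would self-intersect")


def _width_profile(t: np.ndarray, widest_frac: float, taper: float = 1.2) -> np.ndarray:
    """Smooth lanceolate width profile on [0, 1], max 1 at ``widest_frac``,
    vanishing at the tip (t=1) and positive at the base (t=0)."""
    t0 = 0.15
    a = taper * (t0 + widest_frac) / (1.0 - widest_frac)
    w = (t0 + t) ** a * (1.0 - t) ** taper
    wmax = (t0 + widest_frac) ** a * (1.0 - widest_frac) ** taper
    return w / wmax


def _midvein(params: LeafParams, s: np.ndarray):
    """Arc-length parameterized midvein curve and its local frame.

    The midvein lies in the x-z plane, bending downward with constant
    curvature; returns positions, unit tangents, and the horizontal
    transverse direction (y) before twist.
    """
    k = params.bend_curvature
    if abs(k) < 1e-12:
        pos = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
        tan = np.tile([1.0, 0.0, 0.0], (len(s), 1))
    else:
        # tangent angle phi(s) = k*s below the horizontal
        phi = k * s
        pos = np.column_stack([np.sin(phi) / k, np.zeros_like(s),
                               (np.cos(phi) - 1.0) / k])
        tan = np.column_stack([np.cos(phi), np.zeros_like(s), -np.sin(phi)])
    trans = np.tile([0.0, 1.0, 0.0], (len(s), 1))
    return pos, tan, trans


def generate_leaf(params: LeafParams) -> DigitizedLeaf:
    """Generate one digitizer-format leaf (``5*n + 1`` points).

    Transects sit at arc-length fractions ``t/n`` (t = 0..n-1) so the last
    transect keeps positive width; the tip point terminates the midvein at
    full length.  Deterministic for a given parameter set.
    """
    n = params.n_transects
    L = params.length_cm
    u = np.arange(n) / n                      # station fractions along [0, 1)
    s = u * L
    pos, tan, trans = _midvein(params, s)
    normal = np.cross(tan, trans)             # local blade normal

    halfw = 0.5 * params.max_width_cm * _width_profile(u, params.widest_frac)
    offsets = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])   # columns left -> right

    rng = np.random.default_rng(params.seed)
    phase = rng.uniform(0.0, 2.0 * np.pi) if params.wave_phase is None else params.wave_phase
    twist = params.twist_total * u
    transects = np.empty((n, 5, 3))
    for t in range(n):
        ct, st = np.cos(twist[t]), np.sin(twist[t])
        y_dir = ct * trans[t] + st * normal[t]
        z_dir = -st * trans[t] + ct * normal[t]
        for c, off in enumerate(offsets):
            d = off * halfw[t]
            pt = pos[t] + d * y_dir
            # margin waves on the edge columns, along the local normal
            if params.wave_amp > 0 and c in (0, 4):
                pt = pt + params.wave_amp * np.sin(
                    2.0 * np.pi * params.wave_freq * u[t] + phase
                    + (np.pi if c == 4 else 0.0)) * z_dir
            # transverse fold field, concentrated in the lower-middle blade
            if params.fold_amp > 0:
                envelope = np.exp(-((u[t] - 0.3) / 0.25) ** 2)
                fold = params.fold_amp * envelope * np.cos(
                    np.pi * params.fold_freq * off)
                pt = pt + fold * z_dir
            transects[t, c] = pt

    tip_pos, _, _ = _midvein(params, np.array([L]))
    return DigitizedLeaf("", "", transects, tip_pos[0])


@dataclass
class PopulationSpec:
    """Specification of a synthetic inbred-line population.

    Line-level parameters are drawn uniformly from ``param_ranges``;
    replicates within a line jitter each parameter by a Gaussian with
    standard deviation ``noise_ratio`` times the line-level range width,
    so within-line spread stays well below between-line spread at the
    default ratio of 0.15.
    """

    n_lines: int = 100
    replicates: int = 3
    noise_ratio: float = 0.15
    master_seed: int = 7
    param_ranges: dict = field(default_factory=lambda: {
        "length_cm": (60.0, 105.0),
        "max_width_cm": (6.0, 12.0),
        "widest_frac": (0.30, 0.50),
        "bend_curvature": (0.005, 0.045),
        "twist_total": (-0.3, 0.3),
        "wave_amp": (0.0, 0.4),
        "wave_freq": (2.0, 5.0),
        "wave_phase": (0.0, 2.0 * np.pi),
        "fold_amp_frac": (0.0, 0.02),   # fraction of max width
        "fold_freq": (1.0, 3.0),
    })

    def __post_init__(self):
        if self.n_lines < 1 or not 1 <= self.replicates <= 3:
            raise LeafAtlasError("need n_lines >= 1 and 1-3 replicates")
        if not 0 <= self.noise_ratio < 1:
            raise LeafAtlasError("noise_ratio must lie in [0, 1)")


def _leaf_seed(master_seed: int, line: int, rep: int) -> int:
    return int(np.random.SeedSequence([master_seed, line, rep]).generate_state(1)[0] % (2**31))


def generate_population(spec: PopulationSpec):
    """Generate ``n_lines x replicates`` leaves plus a ground-truth table.

    Returns ``(leaves, truth)`` where ``leaves`` is a list of
    :class:`DigitizedLeaf` tagged ``L###``/``L###_r#`` and ``truth`` a
    DataFrame of one row per line with the true line-level parameters.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.master_seed, 0]))
    leaves: list[DigitizedLeaf] = []
    truth_rows = []
    ranges = spec.param_ranges
    for li in range(spec.n_lines):
        line_params = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
        line_id = f"L{li:03d}"
        truth_rows.append({"line_id": line_id, **line_params})
        for rep in range(spec.replicates):
            rrng = np.random.default_rng(
                np.random.SeedSequence([spec.master_seed, 1 + li, rep]))
            p = {}
            for k, (lo, hi) in ranges.items():
                jitter = rrng.normal(0.0, spec.noise_ratio * (hi - lo))
                p[k] = float(np.clip(line_params[k] + jitter, lo, hi))
            fold_amp = p.pop("fold_amp_frac") * p["max_width_cm"]
            # transect count follows leaf length at ~5 cm probe spacing,
            # clamped to the observed 13..18 range (66..91 points)
            n_transects = int(np.clip(round(p["length_cm"] / 5.0), 13, 18))
            params = LeafParams(fold_amp=fold_amp, n_transects=n_transects,
                                seed=_leaf_seed(spec.master_seed, li, rep), **p)
            leaf = generate_leaf(params)
            leaf.line_id = line_id
            leaf.sample_id = f"{line_id}_r{rep}"
            leaves.append(leaf)
    truth = pd.DataFrame(truth_rows).set_index("line_id")
    return leaves, truth
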