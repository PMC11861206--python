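"""End-to-end orchestration: digitizer grids (or synthetic spec) to atlas.

Stages: replicate screening -> normalization -> sqrt(3) subdivision ->
ARAP flattening -> contour sampling -> 29-feature extraction -> semantic
feature selection -> greedy weight search -> atlas construction ->
leave-one-replicate-out identification.  Every stage writes its artifact
under the output directory and the run report records counts, the mean and
minimum 2D/3D area ratio, and the Top-X accuracy curve.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import contour as contour_mod
from . import features as features_mod
from . import preprocess, synthetic
from .arap import arap_flatten
from .digitizer_io import DigitizedLeaf, read_digitized_leaf, triangulate_grid, write_mesh
from .errors import LeafAtlasError

log = logging.getLogger("leafatlas")

__all__ = ["PipelineConfig", "process_leaf", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Stage parameters; defaults are the pipeline's standard constants
    (screening margin 0.1, two subdivision iterations, 600 contour rays,
    clustering cut 0.25, weight grid 0..3 step 0.5, match threshold 0.9)."""

    input_dir: str | None = None      # directory of grid files; None -> synthesize
    out_dir: str = "leafatlas_out"
    n_lines: int = 100
    replicates: int = 3
    seed: int = 7
    screen_threshold: float = 0.1
    subdiv_iters: int = 2
    arap_tol: float = 1e-6
    arap_max_iters: int = 200
    resolution: int = contour_mod.DEFAULT_RESOLUTION
    cluster_threshold: float = atlas_mod.DEFAULT_CLUSTER_THRESHOLD
    weight_grid: tuple = atlas_mod.DEFAULT_WEIGHT_GRID
    match_threshold: float = 0.9
    write_meshes: bool = False

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        d.pop("weight_grid_note", None)
        if "weight_grid" in d:
            d["weight_grid"] = tuple(d["weight_grid"])
        return cls(**d)


def process_leaf(leaf: DigitizedLeaf, subdiv_iters: int = 2, tol: float = 1e-6,
                 max_iters: int = 200, resolution: int = 600):
    """Run one leaf through normalize -> subdivide -> flatten -> contour ->
    features.

    Returns ``(mesh3d, mesh2d, contour, feature_dict, distortion_report)``
    where ``mesh3d`` is the normalized subdivided 3D mesh.
    """
    raw = triangulate_grid(leaf)
    normalized = preprocess.normalize_mesh(raw)
    mesh3d = preprocess.sqrt3_subdivide(normalized, subdiv_iters)
    mesh2d, report, _ = arap_flatten(mesh3d, tol=tol, max_iters=max_iters)
    cont = contour_mod.contour_from_mesh(mesh2d, resolution)
    feats = features_mod.extract_all(mesh2d, mesh3d, cont)
    return mesh3d, mesh2d, cont, feats, report


def _load_or_generate(config: PipelineConfig):
    if config.input_dir is not None:
        paths = sorted(Path(config.input_dir).glob("*.txt")) + \
                sorted(Path(config.input_dir).glob("*.csv"))
        if not paths:
            raise LeafAtlasError(f"no grid files under {config.input_dir}")
        leaves = [read_digitized_leaf(p) for p in paths]
        truth = None
    else:
        spec = synthetic.PopulationSpec(n_lines=config.n_lines,
                                        replicates=config.replicates,
                                        master_seed=config.seed)
        leaves, truth = synthetic.generate_population(spec)
    return leaves, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(config).items()}}

    leaves, truth = _load_or_generate(config)
    report["n_input_leaves"] = len(leaves)
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv")

    # ---- screening on raw meshes -------------------------------------
    records = []
    raw_meshes = {}
    for leaf in leaves:
        mesh = triangulate_grid(leaf)
        raw_meshes[leaf.sample_id] = mesh
        records.append(preprocess.ScreeningRecord(
            leaf.line_id, leaf.sample_id, preprocess.raw_screen_features(mesh)))
    screened = preprocess.screen_replicates(records, config.screen_threshold)
    pd.DataFrame([{
        "line_id": r.line_id, "sample_id": r.sample_id,
        "leaf_length": r.screen_features[0], "leaf_width": r.screen_features[1],
        "aspect_ratio": r.screen_features[2], "mesh_average_angle": r.screen_features[3],
        "excluded": r.excluded, "reason": r.reason,
    } for r in screened]).to_csv(out / "screening.csv", index=False)
    keep = {r.sample_id for r in screened if not r.excluded}
    report["n_excluded"] = len(leaves) - len(keep)
    report["n_retained"] = len(keep)
    leaves = [lf for lf in leaves if lf.sample_id in keep]

    # ---- per-leaf geometry + features --------------------------------
    rows = []
    contours = []
    area_ratios = []
    mesh_dir = out / "meshes"
    if config.write_meshes:
        mesh_dir.mkdir(exist_ok=True)
    for leaf in leaves:
        mesh3d, mesh2d, cont, feats, rep = process_leaf(
            leaf, config.subdiv_iters, config.arap_tol,
            config.arap_max_iters, config.resolution)
        area_ratios.append(rep.area_ratio)
        contours.append(cont)
        rows.append({"line_id": leaf.line_id, "sample_id": leaf.sample_id, **feats})
        if config.write_meshes:
            write_mesh(mesh2d, mesh_dir / f"{leaf.sample_id}_2d.obj")
    table = pd.DataFrame(rows)
    table.to_csv(out / "features.csv", index=False)
    with (out / "feature_units.json").open("w") as fh:
        json.dump(_FEATURE_UNITS, fh, indent=1)
    report["area_ratio_mean"] = float(np.mean(area_ratios))
    report["area_ratio_min"] = float(np.min(area_ratios))
    report["area_ratio_max"] = float(np.max(area_ratios))

    # ---- per-line averaged contour models ----------------------------
    by_line: dict[str, list] = {}
    for cont in contours:
        by_line.setdefault(cont.line_id, []).append(cont)
    line_contours = {lid: contour_mod.average_contours(cs, line_id=lid)
                     for lid, cs in by_line.items()}
    report["n_line_models"] = len(line_contours)
    cont_dir = out / "line_contours"
    cont_dir.mkdir(exist_ok=True)
    for lid, cont in line_contours.items():
        pd.DataFrame({
            "ray_index": np.arange(cont.resolution),
            "angle_rad": cont.angles,
            "x_cm": cont.points[:, 0],
            "y_cm": cont.points[:, 1],
        }).to_csv(cont_dir / f"{lid}.csv", index=False)

    # ---- semantic selection + weights --------------------------------
    dist = atlas_mod.feature_distance_matrix(table)
    selected = atlas_mod.cluster_and_select(dist, config.cluster_threshold)
    report["selected_features"] = list(selected)
    model = atlas_mod.greedy_weight_search(table, selected, config.weight_grid,
                                           config.cluster_threshold)
    report["weights"] = dict(zip(model.selected, model.weights.round(6).tolist()))

    # ---- atlas --------------------------------------------------------
    S = model.standardize(table)
    line_ids = table["line_id"].to_numpy()
    line_semantics = {lid: S[line_ids == lid].mean(axis=0) for lid in line_contours}
    atl = atlas_mod.build_atlas(line_contours, line_semantics, model)
    atl.to_json(out / "atlas.json")

    # ---- evaluation ---------------------------------------------------
    top_x = tuple(range(1, 11))
    accs, n_queries = atlas_mod.loo_identification(S, line_ids, model.weights, top_x)
    unweighted = np.ones(len(model.selected)) / len(model.selected)
    accs_unw, _ = atlas_mod.loo_identification(S, line_ids, unweighted, top_x)
    report["top_x"] = {f"top{x}": float(a) for x, a in zip(top_x, accs)}
    report["top_x_unweighted"] = {f"top{x}": float(a) for x, a in zip(top_x, accs_unw)}
    report["n_queries"] = n_queries
    report["runtime_s"] = round(time.time() - t0, 2)

    (out / "report.json").write_text(json.dumps(report, indent=1))
    log.info("pipeline finished: %d leaves, %d line models, %.1f s",
             report["n_retained"], report["n_line_models"], report["runtime_s"])
    return report


_FEATURE_UNITS = {
    "LL": "cm", "RL": "cm", "ML": "cm", "WA": "cm", "WM": "cm", "WV": "cm^2",
    "WP": "-", "LWR": "-", "LTA": "rad", "LOA": "rad", "ROA": "rad",
    "MOA": "rad", "MTA": "rad", "MTV": "rad^2", "A": "cm^2", "FA": "rad",
    "FV": "rad^2", "TP": "cm", "RUP": "cm", "LUP": "cm", "RLP": "cm",
    "LLP": "cm", "BP": "cm", "UP": "cm", "LP": "cm", "L": "cm", "W": "cm",
    "UL": "cm", "LW": "-",
}
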