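import numpy as np
import pytest
from hypothesis import settings

import leafatlas as la
from leafatlas.arap import arap_flatten
from leafatlas.preprocess import normalize_mesh, sqrt3_subdivide

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def make_rect_leaf(n_transects: int = 5, length: float = 20.0, width: float = 4.0,
                   line_id: str = "R", sample_id: str = "R_r0") -> la.DigitizedLeaf:
    """Planar rectangular leaf: midvein along +x, tip at (length, 0, 0).

    Transects at x = t * length / n, columns at y = -w/2 .. w/2, so the
    midvein polyline (stations + tip) has arclength exactly ``length``.
    """
    n = n_transects
    xs = np.arange(n) * length / n
    ys = np.linspace(-width / 2, width / 2, 5)
    transects = np.zeros((n, 5, 3))
    for t in range(n):
        transects[t, :, 0] = xs[t]
        transects[t, :, 1] = ys
    leaf = la.DigitizedLeaf(line_id, sample_id, transects, np.array([length, 0.0, 0.0]))
    return leaf


@pytest.fixture
def rect_leaf():
    return make_rect_leaf()


@pytest.fixture
def rect_mesh(rect_leaf):
    return la.triangulate_grid(rect_leaf)


@pytest.fixture(scope="session")
def bent_leaf_mesh():
    """Subdivided normalized mesh of a gently deformed (non-planar) leaf."""
    params = la.LeafParams(length_cm=80, max_width_cm=9, bend_curvature=0.03,
                           twist_total=0.2, wave_amp=0.3, fold_amp=0.15, seed=3)
    mesh = la.triangulate_grid(la.generate_leaf(params))
    return sqrt3_subdivide(normalize_mesh(mesh), 2)


@pytest.fixture(scope="session")
def pop50():
    """50-leaf synthetic population processed through ARAP flattening.

    Returns per-leaf area ratios, energy traces, and the processed meshes;
    deformation magnitudes follow the generator's standard population
    ranges (moderate bend, twist, margin waves, small folds).
    """
    spec = la.PopulationSpec(n_lines=50, replicates=1, master_seed=7)
    leaves, truth = la.generate_population(spec)
    ratios, traces, pairs = [], [], []
    for leaf in leaves:
        mesh3d = sqrt3_subdivide(normalize_mesh(la.triangulate_grid(leaf)), 2)
        mesh2d, report, trace = arap_flatten(mesh3d)
        ratios.append(report.area_ratio)
        traces.append(trace["energy"])
        pairs.append((mesh3d, mesh2d))
    return {"leaves": leaves, "truth": truth, "ratios": np.array(ratios),
            "traces": traces, "pairs": pairs}


@pytest.fixture(scope="session")
def pipeline100(tmp_path_factory):
    """Full pipeline run on the default 100-line, 3-replicate population."""
    out = tmp_path_factory.mktemp("run100")
    config = la.PipelineConfig(out_dir=str(out), n_lines=100, replicates=3, seed=7)
    report = la.run_pipeline(config)
    import pandas as pd
    table = pd.read_csv(out / "features.csv")
    return {"report": report, "table": table, "out": out, "config": config}


@pytest.fixture(scope="session")
def recovery30():
    """30 leaves with known length / max width / widest position, processed
    end to end; used for parameter-recovery checks."""
    rng = np.random.default_rng(11)
    rows = []
    for i in range(30):
        params = la.LeafParams(
            length_cm=float(rng.uniform(60, 105)),
            max_width_cm=float(rng.uniform(6, 12)),
            widest_frac=float(rng.uniform(0.3, 0.5)),
            bend_curvature=float(rng.uniform(0.005, 0.045)),
            twist_total=float(rng.uniform(-0.3, 0.3)),
            wave_amp=float(rng.uniform(0, 0.3)),
            fold_amp=float(rng.uniform(0, 0.15)),
            n_transects=int(rng.integers(13, 19)),
            seed=int(rng.integers(0, 2**31)),
        )
        leaf = la.generate_leaf(params)
        leaf.line_id, leaf.sample_id = f"T{i:02d}", f"T{i:02d}_r0"
        _, _, _, feats, _ = la.process_leaf(leaf)
        rows.append((params, feats))
    return rows
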