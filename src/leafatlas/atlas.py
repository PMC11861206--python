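"""Semantic feature selection, weight search, the L2D index and the atlas.

From the 29-feature table the redundant features are pruned by hierarchical
clustering on the correlation distance ``1 - r`` (average linkage, cut at
0.25), keeping one medoid representative per cluster.  Per-feature weights
are then found by a greedy grid search over {0, 0.5, ..., 3}, scoring each
candidate by leave-one-replicate-out identification ability, and normalized
to sum to one.  The composite shape index

    L2D = sum_i  w_i * f_i

over min-max standardized semantic features ranks the per-line averaged
contour models into the 2D leaf-shape atlas; identification of an unknown
leaf is nearest-neighbour retrieval under weighted cosine similarity
against the per-line gallery, scored by Top-X accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .contour import SampledContour
from .errors import ConfigError, FeatureError, IdentificationError
from .features import FEATURE_NAMES

__all__ = [
    "SemanticModel",
    "AtlasEntry",
    "Atlas",
    "feature_distance_matrix",
    "cluster_and_select",
    "standardize",
    "loo_identification",
    "greedy_weight_search",
    "compute_L2D",
    "build_atlas",
    "plot_atlas",
    "identify",
    "lookup_by_semantics",
    "top_x_accuracy",
]

DEFAULT_CLUSTER_THRESHOLD = 0.25
DEFAULT_WEIGHT_GRID = tuple(np.arange(0.0, 3.0 + 1e-9, 0.5))
#: The 11 semantic features selected on the original study population.
REFERENCE_SEMANTIC_FEATURES = ("WP", "LWR", "L", "LTA", "WV", "W",
                               "FA", "MTV", "MTA", "LOA", "ROA")


@dataclass
class SemanticModel:
    """Selected semantic features, their weights and standardization."""

    selected: tuple
    weights: np.ndarray
    minima: np.ndarray
    maxima: np.ndarray
    raw_weights: np.ndarray | None = None
    threshold: float = DEFAULT_CLUSTER_THRESHOLD

    def __post_init__(self):
        self.selected = tuple(self.selected)
        if len(set(self.selected)) != len(self.selected):
            raise ConfigError("selected features must be distinct")
        unknown = set(self.selected) - set(FEATURE_NAMES)
        if unknown:
            raise ConfigError(f"unknown feature identifiers: {sorted(unknown)}")
        self.weights = np.asarray(self.weights, dtype=float)
        self.minima = np.asarray(self.minima, dtype=float)
        self.maxima = np.asarray(self.maxima, dtype=float)
        k = len(self.selected)
        if not (len(self.weights) == len(self.minima) == len(self.maxima) == k):
            raise ConfigError("weights/standardization must match selected features")
        if np.any(self.weights < 0):
            raise ConfigError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ConfigError("weights must sum to 1")

    def standardize(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Min-max standardize the selected features to [0, 1] (clipping
        values outside the atlas population range)."""
        if isinstance(table, pd.DataFrame):
            X = table.loc[:, list(self.selected)].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(table, dtype=float))
        span = np.where(self.maxima - self.minima > 0, self.maxima - self.minima, 1.0)
        return np.clip((X - self.minima) / span, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "weights": self.weights.tolist(),
            "minima": self.minima.tolist(),
            "maxima": self.maxima.tolist(),
            "raw_weights": None if self.raw_weights is None else list(self.raw_weights),
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SemanticModel":
        raw = d.get("raw_weights")
        return cls(tuple(d["selected"]), np.asarray(d["weights"]),
                   np.asarray(d["minima"]), np.asarray(d["maxima"]),
                   None if raw is None else np.asarray(raw),
                   d.get("threshold", DEFAULT_CLUSTER_THRESHOLD))


# ---------------------------------------------------------------------------
# Feature clustering and selection
# ---------------------------------------------------------------------------

def feature_distance_matrix(table: pd.DataFrame,
                            features: tuple = FEATURE_NAMES) -> pd.DataFrame:
    """Pairwise correlation distance ``1 - r`` between feature columns."""
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    if len(X) < 3:
        raise FeatureError("need at least 3 leaves for feature correlations")
    stds = X.std(axis=0)
    if np.any(stds == 0):
        bad = [features[i] for i in np.flatnonzero(stds == 0)]
        raise FeatureError(f"constant feature column(s): {bad}")
    D = 1.0 - np.corrcoef(X, rowvar=False)
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)  # exact symmetry against round-off
    return pd.DataFrame(D, index=list(features), columns=list(features))


def cluster_and_select(dist: pd.DataFrame,
                       threshold: float = DEFAULT_CLUSTER_THRESHOLD) -> tuple:
    """Average-linkage clustering of features cut at ``threshold``.

    Returns the ordered tuple of representative feature identifiers: the
    medoid (smallest mean distance to its cluster) of each cluster, with
    clusters ordered by first column appearance.
    """
    if threshold <= 0:
        raise ConfigError("clustering threshold must be positive")
    names = list(dist.index)
    D = dist.to_numpy(dtype=float)
    Z = sch.linkage(ssd.squareform(D, checks=False), method="average")
    labels = sch.fcluster(Z, t=threshold, criterion="distance")
    selected = []
    seen = set()
    for i, lab in enumerate(labels):
        if lab in seen:
            continue
        seen.add(lab)
        members = np.flatnonzero(labels == lab)
        sub = D[np.ix_(members, members)]
        medoid = members[int(np.argmin(sub.mean(axis=1)))]
        selected.append(names[int(medoid)])
    return tuple(selected)


def standardize(table: pd.DataFrame, features: tuple):
    """Population min-max bounds and the standardized [0, 1] matrix."""
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    minima, maxima = X.min(axis=0), X.max(axis=0)
    span = np.where(maxima - minima > 0, maxima - minima, 1.0)
    return minima, maxima, (X - minima) / span


# ---------------------------------------------------------------------------
# Identification machinery (shared by weight search and evaluation)
# ---------------------------------------------------------------------------

def _weighted_cosine(Q: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Cosine similarity between element-wise weighted rows of Q and G."""
    Qw, Gw = Q * w, G * w
    qn = np.linalg.norm(Qw, axis=1, keepdims=True)
    gn = np.linalg.norm(Gw, axis=1, keepdims=True)
    if np.any(qn == 0) or np.any(gn == 0):
        raise IdentificationError("zero-norm weighted vector: similarity undefined")
    return (Qw / qn) @ (Gw / gn).T


def loo_identification(S: np.ndarray, line_ids: np.ndarray, w: np.ndarray,
                       top_x: tuple = tuple(range(1, 11))):
    """Leave-one-replicate-out Top-X accuracies.

    ``S`` holds standardized semantic vectors (one row per leaf) and
    ``line_ids`` the true line of each row.  Each leaf from a line with at
    least two replicates is queried in turn against a gallery of per-line
    mean vectors with the query replicate excluded from its own line's
    mean, so a leaf never matches against itself.

    Returns ``(accuracies, n_queries)`` with one rate per entry of ``top_x``.
    """
    lines, inv = np.unique(line_ids, return_inverse=True)
    n_lines = len(lines)
    counts = np.bincount(inv, minlength=n_lines)
    sums = np.zeros((n_lines, S.shape[1]))
    np.add.at(sums, inv, S)
    base_gallery = sums / counts[:, None]

    queries = np.flatnonzero(counts[inv] >= 2)
    if len(queries) == 0:
        raise IdentificationError("no line has >= 2 replicates: cannot evaluate")
    ranks = np.empty(len(queries), dtype=int)
    for qi, q in enumerate(queries):
        li = inv[q]
        G = base_gallery.copy()
        G[li] = (sums[li] - S[q]) / (counts[li] - 1)
        sims = _weighted_cosine(S[q][None, :], G, w)[0]
        order = np.argsort(-sims, kind="stable")
        ranks[qi] = int(np.flatnonzero(order == li)[0]) + 1
    accs = np.array([(ranks <= x).mean() for x in top_x])
    return accs, len(queries)


def greedy_weight_search(table: pd.DataFrame, selected: tuple,
                         grid: tuple = DEFAULT_WEIGHT_GRID,
                         threshold: float = DEFAULT_CLUSTER_THRESHOLD) -> SemanticModel:
    """Greedy per-feature weight search on the identification objective.

    For each selected feature in turn, every grid value (default the 7
    values 0, 0.5, ..., 3) is tried as that feature's raw weight with all
    other raw weights held at 1; the value maximizing the mean of Top-1
    through Top-10 leave-one-replicate-out accuracy is kept (ties go to the
    smaller weight).  The per-feature winners form the raw weight vector,
    normalized to sum to 1.

    ``table`` must carry ``line_id`` plus the feature columns; at least two
    lines need two or more replicates.
    """
    grid = tuple(grid)
    if len(grid) == 0:
        raise ConfigError("empty weight grid")
    minima, maxima, S = standardize(table, selected)
    line_ids = table["line_id"].to_numpy()

    raw = np.ones(len(selected))
    for i in range(len(selected)):
        best_score, best_g = -np.inf, None
        for g in grid:  # ascending: first max wins, ties -> smaller weight
            w = np.ones(len(selected))
            w[i] = g
            if np.all(w == 0):
                continue
            accs, _ = loo_identification(S, line_ids, w)
            score = float(accs.mean())
            if score > best_score + 1e-12:
                best_score, best_g = score, g
        raw[i] = best_g
    if raw.sum() == 0:
        raise IdentificationError("degenerate weights: all grid winners are zero")
    return SemanticModel(selected, raw / raw.sum(), minima, maxima,
                         raw_weights=raw, threshold=threshold)


# ---------------------------------------------------------------------------
# L2D and the atlas
# ---------------------------------------------------------------------------

def compute_L2D(v_f: np.ndarray, model: SemanticModel, modulus: bool = False) -> float:
    """Composite shape index of one standardized semantic vector.

    ``L2D = sum_i w_i * v_i`` (weights sum to 1, features in [0, 1], so
    L2D is in [0, 1] and grows as every trait becomes more pronounced).
    ``modulus=True`` computes the Euclidean norm of the weighted vector
    instead.
    """
    v_f = np.asarray(v_f, dtype=float).reshape(-1)
    if len(v_f) != len(model.selected):
        raise IdentificationError(
            f"semantic vector has {len(v_f)} entries, model expects {len(model.selected)}")
    wv = model.weights * v_f
    return float(np.linalg.norm(wv)) if modulus else float(wv.sum())


@dataclass
class AtlasEntry:
    """One ranked inbred line: averaged contour + semantic vector + L2D."""

    line_id: str
    contour: SampledContour
    semantic: np.ndarray
    l2d: float
    rank: int = 0


@dataclass
class Atlas:
    """Per-line averaged contour models ranked ascending by L2D."""

    model: SemanticModel
    entries: list = field(default_factory=list)

    @property
    def line_ids(self) -> list:
        return [e.line_id for e in self.entries]

    def semantic_matrix(self) -> np.ndarray:
        return np.stack([e.semantic for e in self.entries])

    def entry(self, line_id: str) -> AtlasEntry:
        for e in self.entries:
            if e.line_id == line_id:
                return e
        raise KeyError(line_id)

    def to_json(self, path) -> None:
        payload = {
            "model": self.model.to_dict(),
            "entries": [{
                "line_id": e.line_id,
                "semantic": e.semantic.tolist(),
                "l2d": e.l2d,
                "rank": e.rank,
                "contour": e.contour.points.tolist(),
            } for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "Atlas":
        payload = json.loads(Path(path).read_text())
        model = SemanticModel.from_dict(payload["model"])
        entries = [AtlasEntry(d["line_id"],
                              SampledContour(np.asarray(d["contour"]),
                                             line_id=d["line_id"], sample_id="mean"),
                              np.asarray(d["semantic"]), d["l2d"], d["rank"])
                   for d in payload["entries"]]
        return cls(model, entries)


def build_atlas(line_contours: dict, line_semantics: dict,
                model: SemanticModel) -> Atlas:
    """Assemble and rank the atlas from per-line averaged data.

    ``line_contours`` maps line_id to the line's averaged
    :class:`SampledContour`, ``line_semantics`` to the line's mean
    *standardized* semantic vector.  Entries are sorted ascending by L2D
    (ties broken by line_id) and ranks assigned from 1.
    """
    ids = list(line_contours)
    if len(set(ids)) != len(ids) or set(ids) != set(line_semantics):
        raise IdentificationError("line ids of contours and semantics must match 1:1")
    entries = []
    for line_id in ids:
        v = np.asarray(line_semantics[line_id], dtype=float)
        entries.append(AtlasEntry(line_id, line_contours[line_id], v,
                                  compute_L2D(v, model)))
    entries.sort(key=lambda e: (e.l2d, e.line_id))
    for r, e in enumerate(entries, start=1):
        e.rank = r
    return Atlas(model, entries)


def plot_atlas(atlas: Atlas, path=None, leaves_per_ring: int = 24, ax=None):
    """Circular atlas plot: contours arranged on concentric rings, L2D
    increasing from the inside out.  Returns the matplotlib axes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 10))
    for i, e in enumerate(atlas.entries):
        ring = i // leaves_per_ring + 1
        theta = 2.0 * np.pi * (i % leaves_per_ring) / leaves_per_ring
        pts = e.contour.points
        scale = 0.35 / max(np.abs(pts).max(), 1e-12)
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        placed = (pts * scale) @ R.T + ring * np.array([c, s])
        ax.plot(placed[:, 0], placed[:, 1], lw=0.5)
    ax.set_aspect("equal")
    ax.set_axis_off()
    if path is not None:
        ax.figure.savefig(path, dpi=120)
        plt.close(ax.figure)
    return ax


def identify(query: np.ndarray, atlas: Atlas,
             model: SemanticModel | None = None) -> list[tuple[str, float]]:
    """Rank atlas lines by weighted cosine similarity to a standardized
    query vector (descending; ties broken by line_id)."""
    model = model or atlas.model
    query = np.asarray(query, dtype=float).reshape(-1)
    if len(query) != len(model.selected):
        raise IdentificationError("query/model feature mismatch")
    sims = _weighted_cosine(query[None, :], atlas.semantic_matrix(), model.weights)[0]
    order = sorted(range(len(sims)), key=lambda i: (-sims[i], atlas.entries[i].line_id))
    return [(atlas.entries[i].line_id, float(sims[i])) for i in order]


def lookup_by_semantics(query: np.ndarray, atlas: Atlas,
                        model: SemanticModel | None = None,
                        match_threshold: float = 0.9):
    """Best-matching atlas entry for a semantic query, or ``None``.

    Returns the top entry (with its averaged contour, for drawing) when its
    weighted cosine similarity reaches ``match_threshold``; otherwise the
    queried leaf shape is taken not to exist in the population.
    """
    ranked = identify(query, atlas, model)
    top_line, top_sim = ranked[0]
    if top_sim < match_threshold:
        return None
    return atlas.entry(top_line)


def top_x_accuracy(queries: list, atlas: Atlas, x: int,
                   model: SemanticModel | None = None) -> float:
    """Fraction of ``(true_line_id, vector)`` queries whose true line ranks
    within the top ``x`` results."""
    if x < 1:
        raise ConfigError("X must be >= 1")
    ids = set(atlas.line_ids)
    hits = 0
    for true_line, vec in queries:
        if true_line not in ids:
            raise IdentificationError(f"query label {true_line!r} not in atlas")
        ranked = identify(vec, atlas, model)
        top = [line for line, _ in ranked[:x]]
        hits += true_line in top
    return hits / len(queries)
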