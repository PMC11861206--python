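import numpy as np
import pandas as pd
import pytest

import leafatlas as la
from leafatlas.atlas import (DEFAULT_WEIGHT_GRID, Atlas, SemanticModel,
                             build_atlas, cluster_and_select, compute_L2D,
                             feature_distance_matrix, greedy_weight_search,
                             identify, loo_identification, lookup_by_semantics,
                             standardize, top_x_accuracy)
from leafatlas.contour import SampledContour
from leafatlas.errors import ConfigError, FeatureError, IdentificationError
from leafatlas.features import FEATURE_NAMES


def random_feature_table(n_leaves=60, n_lines=20, seed=0):
    """Feature table with plausible correlated columns for clustering tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_leaves):
        li = i % n_lines
        base = rng.normal()
        row = {"line_id": f"L{li:03d}", "sample_id": f"L{li:03d}_r{i // n_lines}"}
        for j, name in enumerate(FEATURE_NAMES):
            row[name] = base * (j % 3 == 0) + rng.normal(loc=j, scale=1.0)
        rows.append(row)
    return pd.DataFrame(rows)


def toy_semantic_setup(n_lines=8, k=4, seed=3):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.1, 0.9, size=(n_lines, k))
    model = SemanticModel(FEATURE_NAMES[:k], np.full(k, 1.0 / k),
                          np.zeros(k), np.ones(k))
    contours = {f"L{i}": SampledContour(np.tile([[1.0, 0.0]], (12, 1)) * (i + 1))
                for i in range(n_lines)}
    semantics = {f"L{i}": X[i] for i in range(n_lines)}
    return build_atlas(contours, semantics, model), model, X


class TestDistanceMatrix:
    def test_self_distance_zero_and_negation_two(self):
        table = random_feature_table()
        D = feature_distance_matrix(table)
        assert np.allclose(np.diag(D), 0.0)
        X = table["LL"].to_numpy()
        r = np.corrcoef(X, -X)[0, 1]
        assert 1 - r == pytest.approx(2.0)
        assert D.to_numpy().min() >= -1e-12 and D.to_numpy().max() <= 2.0

    def test_definitional_duplicate_has_zero_distance(self):
        """A column equal to ML/WA (the LWR definition) sits at distance 0
        from LWR."""
        table = random_feature_table()
        table["LWR"] = table["ML"] / table["WA"]
        dup = table.copy()
        dup["WP"] = dup["ML"] / dup["WA"]  # hijack a column with the identity
        D = feature_distance_matrix(dup)
        assert D.loc["LWR", "WP"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_rejected(self):
        table = random_feature_table()
        table["WP"] = 1.0
        with pytest.raises(FeatureError, match="WP"):
            feature_distance_matrix(table)


class TestClusterAndSelect:
    def test_threshold_extremes(self):
        D = feature_distance_matrix(random_feature_table())
        assert len(cluster_and_select(D, threshold=10.0)) == 1
        assert len(cluster_and_select(D, threshold=1e-12)) == 29

    def test_correlated_pair_shares_cluster(self):
        """Two perfectly correlated features always merge below 0.25."""
        rng = np.random.default_rng(1)
        n = 200
        table = pd.DataFrame({name: rng.normal(size=n) for name in FEATURE_NAMES})
        table["RL"] = 2.0 * table["LL"] + 1.0  # exact linear dependence
        D = feature_distance_matrix(table)
        selected = cluster_and_select(D, threshold=0.25)
        assert not ({"LL", "RL"} <= set(selected))  # one represents both

    def test_invalid_threshold(self):
        D = feature_distance_matrix(random_feature_table())
        with pytest.raises(ConfigError):
            cluster_and_select(D, threshold=0.0)


class TestGreedyWeightSearch:
    def test_grid_has_seven_values(self):
        assert len(DEFAULT_WEIGHT_GRID) == 7
        np.testing.assert_allclose(DEFAULT_WEIGHT_GRID,
                                   [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0])

    def test_weights_normalized_and_on_grid(self):
        table = random_feature_table(n_leaves=40, n_lines=10, seed=2)
        model = greedy_weight_search(table, FEATURE_NAMES[:5])
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert all(g in DEFAULT_WEIGHT_GRID for g in model.raw_weights)

    def test_informative_feature_gets_top_weight(self):
        """When a single feature separates the lines and the rest is pure
        noise, that feature receives the largest normalized weight."""
        rng = np.random.default_rng(4)
        rows = []
        for li in range(12):
            for rep in range(3):
                rows.append({
                    "line_id": f"L{li}", "sample_id": f"L{li}_r{rep}",
                    "ML": li * 10.0 + rng.normal(scale=0.1),  # informative
                    "WV": rng.normal(), "FA": rng.normal(), "LTA": rng.normal(),
                })
        table = pd.DataFrame(rows)
        model = greedy_weight_search(table, ("ML", "WV", "FA", "LTA"))
        assert model.selected[int(np.argmax(model.weights))] == "ML"

    def test_equal_raw_weights_normalize_uniformly(self):
        k = 4
        model = SemanticModel(FEATURE_NAMES[:k],
                              np.full(k, 2.5) / (2.5 * k),
                              np.zeros(k), np.ones(k), raw_weights=np.full(k, 2.5))
        np.testing.assert_allclose(model.weights, 1.0 / k)


class TestL2D:
    @pytest.fixture
    def model(self):
        k = 3
        return SemanticModel(FEATURE_NAMES[:k], np.array([0.5, 0.3, 0.2]),
                             np.zeros(k), np.ones(k))

    def test_bounds(self, model):
        assert compute_L2D(np.zeros(3), model) == 0.0
        assert compute_L2D(np.ones(3), model) == pytest.approx(1.0)

    def test_monotone_in_each_feature(self, model):
        v = np.array([0.4, 0.4, 0.4])
        base = compute_L2D(v, model)
        for i in range(3):
            up = v.copy()
            up[i] += 0.1
            assert compute_L2D(up, model) > base

    def test_modulus_option(self, model):
        v = np.array([0.2, 0.9, 0.5])
        assert compute_L2D(v, model, modulus=True) == pytest.approx(
            np.linalg.norm(model.weights * v))

    def test_vector_length_mismatch(self, model):
        with pytest.raises(IdentificationError):
            compute_L2D(np.zeros(5), model)


class TestAtlas:
    def test_sorted_by_l2d_with_ranks(self):
        atlas, model, X = toy_semantic_setup()
        l2ds = [e.l2d for e in atlas.entries]
        assert l2ds == sorted(l2ds)
        assert [e.rank for e in atlas.entries] == list(range(1, len(X) + 1))

    def test_permutation_invariant(self):
        atlas, model, X = toy_semantic_setup()
        contours = {e.line_id: e.contour for e in atlas.entries}
        semantics = {e.line_id: e.semantic for e in atlas.entries}
        rev_c = dict(reversed(list(contours.items())))
        rev_s = dict(reversed(list(semantics.items())))
        atlas2 = build_atlas(rev_c, rev_s, atlas.model)
        assert atlas.line_ids == atlas2.line_ids

    def test_ranks_follow_dominant_feature(self):
        """With all weight on one feature, atlas rank sorts that feature."""
        n, k = 10, 3
        X = np.linspace(0, 1, n)[:, None] * np.array([1.0, 0, 0]) + 0.2
        model = SemanticModel(FEATURE_NAMES[:k], np.array([1.0, 0.0, 0.0]),
                              np.zeros(k), np.ones(k))
        contours = {f"L{i}": SampledContour(np.ones((4, 2))) for i in range(n)}
        semantics = {f"L{i}": X[i] for i in range(n)}
        atlas = build_atlas(contours, semantics, model)
        assert atlas.line_ids == [f"L{i}" for i in range(n)]

    def test_json_roundtrip(self, tmp_path):
        atlas, _, _ = toy_semantic_setup()
        p = tmp_path / "atlas.json"
        atlas.to_json(p)
        back = Atlas.from_json(p)
        assert back.line_ids == atlas.line_ids
        np.testing.assert_allclose(back.semantic_matrix(), atlas.semantic_matrix())
        assert back.model.selected == atlas.model.selected

    def test_circular_plot_renders(self, tmp_path):
        from leafatlas.atlas import plot_atlas
        atlas, _, _ = toy_semantic_setup()
        plot_atlas(atlas, path=tmp_path / "atlas.png")
        assert (tmp_path / "atlas.png").exists()

    def test_duplicate_line_rejected(self):
        atlas, model, _ = toy_semantic_setup()
        contours = {"L0": atlas.entries[0].contour}
        with pytest.raises(IdentificationError):
            build_atlas(contours, {"L1": np.zeros(4)}, model)


class TestIdentify:
    def test_self_query_is_rank_one_with_similarity_one(self):
        atlas, model, X = toy_semantic_setup()
        for e in atlas.entries:
            ranked = identify(e.semantic, atlas)
            assert ranked[0][0] == e.line_id
            assert ranked[0][1] == pytest.approx(1.0)

    def test_orthogonal_query_zero_similarity(self):
        atlas, model, _ = toy_semantic_setup(k=4)
        q = np.array([1.0, 0, 0, 0])
        entry_vec = np.array([0.0, 1.0, 0, 0])
        atlas.entries[0].semantic = entry_vec
        sims = dict(identify(q, atlas))
        assert sims[atlas.entries[0].line_id] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        atlas, model, X = toy_semantic_setup()
        r1 = identify(X[3], atlas)
        r2 = identify(X[3] * 7.5, atlas)
        assert [l for l, _ in r1] == [l for l, _ in r2]

    def test_lookup_threshold_contract(self):
        atlas, model, X = toy_semantic_setup()
        entry = lookup_by_semantics(atlas.entries[2].semantic, atlas,
                                    match_threshold=0.9)
        assert entry.line_id == atlas.entries[2].line_id
        # an adversarial query far from every entry returns None
        far = np.array([1.0, 0.0, 0.0, 0.0])
        if identify(far, atlas)[0][1] < 0.9:
            assert lookup_by_semantics(far, atlas, match_threshold=0.9) is None
        # threshold 1.0+eps can never be met by a non-identical query
        assert lookup_by_semantics(X[0] + 0.3 * np.array([1, -1, 1, -1]), atlas,
                                   match_threshold=1.0 + 1e-9) is None

    def test_lookup_matches_identify_rank_one(self):
        atlas, model, X = toy_semantic_setup()
        q = X[5] * 0.97
        best = identify(q, atlas)[0][0]
        entry = lookup_by_semantics(q, atlas, match_threshold=0.0)
        assert entry.line_id == best


class TestTopX:
    def test_full_size_is_one_and_monotone(self):
        atlas, model, X = toy_semantic_setup()
        rng = np.random.default_rng(0)
        queries = [(f"L{i}", np.clip(X[i] + rng.normal(scale=0.1, size=4), 0, 1))
                   for i in range(len(X))]
        accs = [top_x_accuracy(queries, atlas, x) for x in range(1, len(X) + 1)]
        assert accs[-1] == 1.0
        assert all(b >= a for a, b in zip(accs, accs[1:]))

    def test_exact_copies_top1(self):
        atlas, model, X = toy_semantic_setup()
        queries = [(e.line_id, e.semantic) for e in atlas.entries]
        assert top_x_accuracy(queries, atlas, 1) == 1.0

    def test_invalid_x(self):
        atlas, _, X = toy_semantic_setup()
        with pytest.raises(ConfigError):
            top_x_accuracy([("L0", X[0])], atlas, 0)

    def test_unknown_label_rejected(self):
        atlas, _, X = toy_semantic_setup()
        with pytest.raises(IdentificationError):
            top_x_accuracy([("nope", X[0])], atlas, 1)


class TestLooIdentification:
    def test_separable_lines_identified(self):
        """Well-separated lines with tight replicates give near-perfect
        leave-one-out Top-1."""
        rng = np.random.default_rng(6)
        S, ids = [], []
        for li in range(15):
            center = rng.uniform(0.1, 0.9, size=5)
            for rep in range(3):
                S.append(np.clip(center + rng.normal(scale=0.003, size=5), 0, 1))
                ids.append(f"L{li}")
        accs, n = loo_identification(np.array(S), np.array(ids), np.ones(5))
        assert n == 45
        assert accs[0] > 0.9
        assert np.all(np.diff(accs) >= 0)

    def test_single_replicate_lines_not_queried(self):
        rng = np.random.default_rng(7)
        S = rng.uniform(size=(4, 3))
        ids = np.array(["A", "A", "B", "C"])
        _, n = loo_identification(S, ids, np.ones(3))
        assert n == 2  # only line A has >= 2 replicates
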