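import networkx as nx
import numpy as np
import pytest

from concord.features import (
    FEATURE_NAMES,
    PairFeaturizer,
    compute_embedding,
    compute_simrank,
    extract_features,
    minmax_scale_columns,
)


class TestSimRank:
    def test_path_endpoints(self):
        # a-b-c: N(a)={b}=N(c), so s(a,c) = C * s(b,b) = C
        g = nx.Graph([(0, 1), (1, 2)])
        S, idx = compute_simrank(g, C=0.8)
        assert S[idx[0], idx[2]] == pytest.approx(0.8, abs=1e-5)

    def test_self_similarity_one(self):
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        S, idx = compute_simrank(g)
        for v in g.nodes():
            assert S[idx[v], idx[v]] == pytest.approx(1.0)

    def test_isolated_nodes_zero(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        g.add_edge(1, 2)
        S, idx = compute_simrank(g)
        assert S[idx[0], idx[1]] == 0.0
        assert S[idx[0], idx[2]] == 0.0

    def test_agrees_with_networkx_fixed_point(self):
        # independent oracle: networkx's SimRank on a small random graph
        g = nx.gnp_random_graph(15, 0.3, seed=7)
        S, idx = compute_simrank(g, C=0.8, tol=1e-6, max_iter=300)
        ref = nx.simrank_similarity(g, importance_factor=0.8, tolerance=1e-6,
                                    max_iterations=300)
        for u in g.nodes():
            for v in g.nodes():
                assert S[idx[u], idx[v]] == pytest.approx(ref[u][v], abs=5e-3)


class TestEmbedding:
    def test_every_node_gets_requested_dims(self):
        g = nx.gnp_random_graph(20, 0.3, seed=1)
        emb = compute_embedding(g, dims=16, seed=0)
        assert set(emb) == set(g.nodes())
        assert all(v.shape == (16,) for v in emb.values())

    def test_self_cosine_is_one(self):
        g = nx.karate_club_graph()
        emb = compute_embedding(g, dims=8, seed=2)
        v = emb[0]
        assert v @ v / (np.linalg.norm(v) ** 2) == pytest.approx(1.0)

    def test_cliques_separate_in_embedding_space(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        emb = compute_embedding(g, dims=8, seed=1)

        def cos(a, b):
            return emb[a] @ emb[b] / (np.linalg.norm(emb[a]) * np.linalg.norm(emb[b]))

        within = np.mean([cos(a, b) for a in range(6) for b in range(a + 1, 6)])
        cross = np.mean([cos(a, b) for a in range(6) for b in range(6, 12)])
        assert within > cross

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(25, 0.3, seed=4)
        e1 = compute_embedding(g, dims=8, seed=9)
        e2 = compute_embedding(g, dims=8, seed=9)
        for v in g.nodes():
            np.testing.assert_allclose(e1[v], e2[v])


class TestExtractFeatures:
    @pytest.fixture(scope="class")
    def tri_featurizer(self, triangle):
        return PairFeaturizer(triangle, seed=0)

    def test_triangle_pair_values(self, tri_featurizer):
        X = tri_featurizer([(0, 1)])
        row = dict(zip(FEATURE_NAMES, X[0]))
        assert row["shared_edge"] == 1.0
        assert row["common_neighbors"] == 1.0
        assert row["shortest_path_score"] == 1.0
        assert row["cosine_similarity"] == pytest.approx(0.5)
        assert row["neighborhood_jaccard"] == pytest.approx(1 / 3)

    def test_disconnected_pair_gets_zero_path_score(self):
        g = nx.Graph([(0, 1), (2, 3)])
        fz = PairFeaturizer(g, seed=0)
        X = fz([(0, 2)])
        row = dict(zip(FEATURE_NAMES, X[0]))
        assert row["shortest_path_score"] == 0.0
        assert row["shared_edge"] == 0.0

    def test_features_symmetric_in_pair_order(self, small_benchmark, rng):
        g, _ = small_benchmark
        fz = PairFeaturizer(g, simrank_max_iter=10, n_walks=3, walk_length=20,
                            window=3, seed=0)
        nodes = sorted(g.nodes())
        pairs = [tuple(rng.choice(nodes, 2, replace=False)) for _ in range(20)]
        X_fwd = fz(pairs)
        X_rev = fz([(v, u) for u, v in pairs])
        np.testing.assert_allclose(X_fwd, X_rev, atol=1e-9)

    def test_common_neighbors_matches_brute_force(self, rng):
        g = nx.gnp_random_graph(50, 0.15, seed=5)
        fz = PairFeaturizer(g, simrank_max_iter=5, n_walks=2, walk_length=10,
                            window=2, seed=0)
        pairs = [(u, v) for u in range(50) for v in range(u + 1, 50)]
        X = fz(pairs)
        col = list(FEATURE_NAMES).index("common_neighbors")
        for (u, v), val in zip(pairs, X[:, col]):
            assert val == len(set(g.neighbors(u)) & set(g.neighbors(v)))

    def test_unknown_node_rejected(self, tri_featurizer):
        with pytest.raises(ValueError, match="absent"):
            tri_featurizer([(0, 99)])

    def test_scaled_matrix_in_unit_interval(self, small_benchmark, rng):
        g, _ = small_benchmark
        fz = PairFeaturizer(g, simrank_max_iter=10, n_walks=3, walk_length=20,
                            window=3, seed=0)
        nodes = sorted(g.nodes())
        pairs = [tuple(rng.choice(nodes, 2, replace=False)) for _ in range(50)]
        X = extract_features(pairs, fz, scale=True)
        assert X.shape == (50, 7)
        assert X.min() >= 0.0 and X.max() <= 1.0


class TestScaling:
    def test_constant_column_maps_to_zero(self):
        X = np.column_stack([np.ones(5), np.arange(5, dtype=float)])
        Xs, _, _ = minmax_scale_columns(X)
        assert (Xs[:, 0] == 0).all()
        assert Xs[:, 1].min() == 0.0 and Xs[:, 1].max() == 1.0


class TestSerialization:
    def test_feature_tsv_round_trip(self, tmp_path, triangle):
        import pandas as pd

        from concord.features import write_feature_tsv

        fz = PairFeaturizer(triangle, seed=0)
        pairs = [(0, 1), (1, 2)]
        X = fz(pairs)
        p = tmp_path / "features.tsv"
        write_feature_tsv(X, p, pairs=pairs)
        back = pd.read_csv(p, sep="\t")
        assert list(back.columns) == ["u", "v", *FEATURE_NAMES]
        np.testing.assert_allclose(back[list(FEATURE_NAMES)].to_numpy(), X, atol=1e-5)

    def test_wrong_width_rejected(self, tmp_path):
        from concord.features import write_feature_tsv

        with pytest.raises(ValueError):
            write_feature_tsv(np.zeros((3, 4)), tmp_path / "x.tsv")
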