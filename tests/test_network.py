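import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nitronet import network, simulate


def _corr_df(R, names=None):
    names = names or [f"o{i}" for i in range(R.shape[0])]
    return pd.DataFrame(R, index=names, columns=names)


class TestCorrelationMatrix:
    def test_basic_properties(self, rng):
        x = rng.normal(size=(30, 4))
        df = pd.DataFrame(x, columns=list("abcd"))
        df["e"] = -df["a"]
        R = network.correlation_matrix(df)
        assert np.allclose(np.diag(R), 1.0)
        assert R.loc["a", "e"] == pytest.approx(-1.0)
        assert np.allclose(R.values, R.values.T)

    def test_zero_variance_excluded(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        df["flat"] = 1.0
        R = network.correlation_matrix(df)
        assert "flat" not in R.columns

    def test_independent_gaussians_weakly_correlated(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(1000, 30)))
        R = network.correlation_matrix(df).to_numpy()
        off = R[np.triu_indices_from(R, 1)]
        assert np.abs(off).max() < 0.15

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="3 samples"):
            network.correlation_matrix(pd.DataFrame(np.ones((2, 5))))


class TestRMTThreshold:
    def test_exponential_spacings_pass_ks(self):
        """Direct null property: Exp(1) spacings should be accepted."""
        passed = 0
        for s in range(20):
            sp = np.random.default_rng(s).exponential(size=200)
            _, p, _ = network.nnsd_test(sp / sp.mean())
            passed += p > 0.05
        assert passed >= 18

    def test_planted_blocks_threshold_separates_signal_from_noise(self):
        """r_T must land between the noise correlations and the planted
        within-module correlations."""
        rng = np.random.default_rng(5)
        n, p = 100, 150
        blocks = [(list(range(i * 25, (i + 1) * 25)), 0.85) for i in range(3)]
        C = simulate.generate_planted_correlation(p, blocks)
        lam, U = np.linalg.eigh(C)
        X = rng.standard_normal((n, p)) @ (U * np.sqrt(np.clip(lam, 0, None))).T
        R = _corr_df(np.corrcoef(X, rowvar=False))
        scan = network.rmt_threshold(R)
        Rv = R.to_numpy()
        mod = np.zeros(p, dtype=bool)
        mod[: 3 * 25] = True
        noise = np.abs(Rv[np.ix_(~mod, ~mod)][np.triu_indices(p - 75, 1)])
        within = [np.abs(Rv[np.ix_(b, b)][np.triu_indices(25, 1)]).mean()
                  for b, _ in blocks]
        assert scan.r_t is not None
        assert scan.r_t < min(within)
        assert scan.r_t >= np.quantile(noise, 0.95)

    def test_grid_validation(self, rng):
        R = _corr_df(np.eye(60))
        with pytest.raises(ValueError, match="t_grid"):
            network.rmt_threshold(R, t_grid=[0.9, 0.5])

    def test_no_transition_flagged(self):
        # GOE-like dense correlation stays significant across the grid
        rng = np.random.default_rng(0)
        A = rng.standard_normal((80, 80)) * 0.02
        R = np.clip((A + A.T) / 2 + 0.995 * np.eye(80), -1, 1)
        np.fill_diagonal(R, 1.0)
        scan = network.rmt_threshold(_corr_df(R), t_grid=np.array([0.9, 0.95]))
        assert scan.r_t is None


class TestBuildGraph:
    def test_single_edge_isolated_node_removed(self):
        R = _corr_df(np.array([
            [1.0, 0.9, 0.2],
            [0.9, 1.0, 0.1],
            [0.2, 0.1, 1.0],
        ]), names=list("abc"))
        G = network.build_graph(R, 0.85, n_samples=50)
        assert set(G.edges()) == {("a", "b")}
        assert "c" not in G

    def test_threshold_one_gives_empty_flag(self):
        R = _corr_df(np.array([[1.0, 0.5], [0.5, 1.0]]))
        G = network.build_graph(R, 1.0, n_samples=30)
        assert G.graph.get("empty") is True

    def test_edge_count_monotone_in_threshold(self, rng):
        X = rng.normal(size=(40, 30))
        X[:, 1] = X[:, 0] + rng.normal(0, 0.3, 40)
        R = _corr_df(np.corrcoef(X, rowvar=False))
        counts = [network.build_graph(R, t, n_samples=40).number_of_edges()
                  for t in (0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_sign_kept_on_edges(self):
        R = _corr_df(np.array([[1.0, -0.95], [-0.95, 1.0]]), names=list("ab"))
        G = network.build_graph(R, 0.9, n_samples=60)
        assert G["a"]["b"]["weight"] == pytest.approx(-0.95)


class TestTopologyMetrics:
    def test_triangle_oracle(self):
        G = nx.complete_graph(3)
        nx.set_edge_attributes(G, 1.0, "weight")
        t = network.topology_metrics(G)
        assert (t.diameter, t.avg_path_length) == (1, 1.0)
        assert t.clustering_coefficient == 1.0
        assert t.connectance == 1.0
        assert t.avg_connectivity == 2.0

    def test_path_graph_oracle(self):
        G = nx.path_graph(4)
        nx.set_edge_attributes(G, 1.0, "weight")
        t = network.topology_metrics(G)
        assert t.diameter == 3
        assert t.avg_connectivity == pytest.approx(1.5)
        assert t.clustering_coefficient == 0.0

    def test_negative_edges_excluded(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=0.9)
        G.add_edge("b", "c", weight=-0.9)
        t = network.topology_metrics(G, positive_only=True)
        assert t.nodes == 2 and t.edges == 1

    def test_disconnected_flagged(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=1.0)
        G.add_edge("c", "d", weight=1.0)
        t = network.topology_metrics(G)
        assert not t.connected
        assert t.diameter == 1  # largest component


class TestErNull:
    def test_mean_degree_degenerate(self):
        # mean degree is fixed by (n, m): every null draw equals the observed
        p = network.er_null_test("avg_connectivity", 2 * 30 / 20, 20, 30,
                                 reps=50, seed=0)
        assert p == 1.0

    def test_clustered_graph_significant(self):
        G = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        G.add_edge(0, 6)
        obs = nx.transitivity(G)
        p = network.er_null_test("clustering_coefficient", obs,
                                 G.number_of_nodes(), G.number_of_edges(),
                                 reps=200, seed=0)
        assert p <= 2 / 200

    def test_too_many_edges_error(self):
        with pytest.raises(ValueError, match="capacity"):
            network.er_null_test("clustering_coefficient", 0.5, 4, 10)


class TestModules:
    def test_two_cliques_two_modules(self):
        G = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        mods = network.detect_modules(G, min_size=5)
        assert sorted(len(m) for m in mods) == [6, 6]

    def test_barbell_bridge_has_highest_betweenness(self):
        G = nx.barbell_graph(5, 0)
        eb = nx.edge_betweenness_centrality(G)
        bridge = max(eb, key=eb.get)
        assert set(bridge) == {4, 5}
        mods = network.detect_modules(G, min_size=5)
        assert sorted(len(m) for m in mods) == [5, 5]

    def test_min_size_filters_small_groups(self):
        G = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(3))
        mods = network.detect_modules(G, min_size=5)
        assert [len(m) for m in mods] == [6]

    def test_planted_modules_recovered(self, small_study):
        """End-to-end: clr -> correlation -> RMT -> graph -> modules vs truth."""
        from sklearn.metrics import adjusted_rand_score

        from nitronet import composition
        counts, frame, _, truth = small_study
        clr = composition.clr_transform(
            composition.impute_zeros(counts.iloc[:, :150]))
        sub = clr.loc[frame["treatment"] == "unfertilized"]
        corr = network.correlation_matrix(sub)
        scan = network.rmt_threshold(corr)
        G = network.build_graph(corr, scan.r_t, n_samples=sub.shape[0])
        mods = network.detect_modules(network.positive_subgraph(G), min_size=5)
        node2mod = {n: i for i, m in enumerate(mods) for n in m}
        truth_lab, pred_lab = [], []
        for name, members in truth.modules.items():
            for o in members:
                if o in node2mod:
                    truth_lab.append(name)
                    pred_lab.append(node2mod[o])
        assert len(truth_lab) >= 0.7 * sum(len(m) for m in truth.modules.values())
        assert adjusted_rand_score(truth_lab, pred_lab) >= 0.8


class TestEigengene:
    def test_perfectly_correlated_module(self, rng):
        base = rng.normal(size=50)
        df = pd.DataFrame({f"o{i}": base * (i + 1) for i in range(5)})
        eg = network.module_eigengene(df, df.columns, "m")
        assert eg.variance_explained == pytest.approx(1.0)
        assert np.linalg.norm(eg.eigenvector) == pytest.approx(1.0)

    def test_iid_noise_variance_explained_limit(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(5000, 5)),
                          columns=[f"o{i}" for i in range(5)])
        eg = network.module_eigengene(df, df.columns, "m")
        assert abs(eg.variance_explained - 0.2) < 0.03

    def test_orientation_invariant_to_member_negation(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 6)),
                          columns=[f"o{i}" for i in range(6)])
        df["o1"] += df["o0"]
        e1 = network.module_eigengene(df, df.columns, "m")
        e2 = network.module_eigengene(-df, df.columns, "m")
        assert np.allclose(e1.eigenvector, -e2.eigenvector) or np.allclose(
            e1.eigenvector, e2.eigenvector)
        assert e1.variance_explained == pytest.approx(e2.variance_explained)

    def test_invariance_to_scaling_and_order(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 6)),
                          columns=[f"o{i}" for i in range(6)])
        e1 = network.module_eigengene(df, df.columns, "m")
        scaled = df * [1, 10, 0.1, 5, 2, 7]
        e2 = network.module_eigengene(scaled, scaled.columns, "m")
        assert e1.variance_explained == pytest.approx(e2.variance_explained)

    def test_small_module_errors(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="5 members"):
            network.module_eigengene(df, df.columns, "m")


class TestCorrelateModules:
    def test_monotone_pairs(self, rng):
        x = rng.normal(size=30)
        eg = pd.DataFrame({"m1": x}, index=range(30))
        cov = pd.DataFrame({"up": np.exp(x), "down": -x}, index=range(30))
        rho, p = network.correlate_modules(eg, cov)
        assert rho.loc["m1", "up"] == pytest.approx(1.0)
        assert rho.loc["m1", "down"] == pytest.approx(-1.0)
        assert (p.loc["m1"] < 1e-6).all()
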