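"""Windowed correlation networks, the density metric, and planted-structure
recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dynatrauma as dt
from dynatrauma.dyna import AnalysisWindow


def _corr(names, fill):
    n = len(names)
    m = np.full((n, n), fill, dtype=float)
    np.fill_diagonal(m, 1.0)
    return pd.DataFrame(m, index=names, columns=names)


def _net_from_edges(nodes, edges):
    return dt.CorrelationNetwork(
        group="g", window=AnalysisWindow(0, 8), nodes=tuple(nodes),
        edges={e: 0.9 for e in edges}, threshold=0.7,
    )


class TestWindowMatrix:
    def test_patient_without_in_window_draw_absent(self):
        df = pd.DataFrame({"patient_id": ["a", "b"], "time_h": [4.0, 12.0],
                           "mediator": ["IL-6"] * 2, "value": [10.0, 10.0],
                           "censored": [False] * 2})
        mat = dt.window_patient_matrix(df, AnalysisWindow(8, 16), ["a", "b"],
                                       min_pairs=1)
        assert list(mat.index) == ["b"]

    def test_window_mean_on_log_scale(self):
        df = pd.DataFrame({"patient_id": ["a", "a"], "time_h": [2.0, 6.0],
                           "mediator": ["IL-6"] * 2, "value": [100.0, 1000.0],
                           "censored": [False] * 2})
        mat = dt.window_patient_matrix(df, AnalysisWindow(0, 8), ["a"],
                                       min_pairs=1)
        assert mat.loc["a", "IL-6"] == pytest.approx(2.5)

    def test_row_count_matches_generator_draws(self, default_cohort,
                                               cohort_groups):
        _, patients, samples = default_cohort
        pids = patients["patient_id"].tolist()
        mat = dt.window_patient_matrix(samples, AnalysisWindow(0, 8), pids)
        with_draw = samples[(samples["time_h"] == 4.0)]["patient_id"].nunique()
        assert len(mat) == with_draw

    def test_insufficient_data_is_error(self):
        df = pd.DataFrame({"patient_id": ["a"], "time_h": [4.0],
                           "mediator": ["IL-6"], "value": [10.0],
                           "censored": [False]})
        with pytest.raises(ValueError, match="insufficient"):
            dt.window_patient_matrix(df, AnalysisWindow(0, 8), ["a"],
                                     min_pairs=8)


class TestCorrelationMatrix:
    def test_self_correlation_unit(self, rng):
        mat = pd.DataFrame({"x": rng.normal(size=20)})
        assert dt.correlation_matrix(mat, min_pairs=2).loc["x", "x"] == 1.0

    def test_linear_and_monotone_closed_forms(self):
        x = np.linspace(1, 10, 20)
        mat = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": x ** 3})
        pear = dt.correlation_matrix(mat, "pearson", min_pairs=2)
        assert pear.loc["x", "y"] == pytest.approx(1.0)
        spear = dt.correlation_matrix(mat, "spearman", min_pairs=2)
        assert spear.loc["x", "z"] == pytest.approx(1.0)

    def test_matches_brute_force_covariance(self, rng):
        mat = pd.DataFrame(rng.normal(size=(30, 5)),
                           columns=list("abcde"))
        corr = dt.correlation_matrix(mat, min_pairs=2)
        for i, j in itertools.combinations("abcde", 2):
            x, y = mat[i].to_numpy(), mat[j].to_numpy()
            r = (np.sum((x - x.mean()) * (y - y.mean()))
                 / np.sqrt(np.sum((x - x.mean()) ** 2)
                           * np.sum((y - y.mean()) ** 2)))
            assert corr.loc[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_column_goes_missing(self, rng):
        mat = pd.DataFrame({"x": rng.normal(size=15), "c": np.ones(15)})
        corr = dt.correlation_matrix(mat, min_pairs=2)
        assert np.isnan(corr.loc["x", "c"])

    def test_min_pairs_floor_blocks_thin_overlap(self, rng):
        x = rng.normal(size=20)
        y = x.copy()
        y[5:] = np.nan  # only 5 complete pairs
        mat = pd.DataFrame({"x": x, "y": y})
        corr = dt.correlation_matrix(mat, min_pairs=8)
        assert np.isnan(corr.loc["x", "y"])


class TestBuildNetwork:
    def test_below_threshold_yields_no_edges(self):
        net = dt.build_network(_corr(list("abcd"), 0.69))
        assert net.n_edges == 0

    def test_threshold_is_inclusive(self):
        net = dt.build_network(_corr(list("ab"), 0.70))
        assert net.n_edges == 1

    def test_signed_mode_ignores_negative_correlations(self):
        c = _corr(list("ab"), -0.9)
        assert dt.build_network(c, mode="signed").n_edges == 0
        assert dt.build_network(c, mode="absolute").n_edges == 1

    def test_edge_set_matches_double_loop(self, rng):
        n = 8
        a = rng.uniform(-1, 1, (n, n))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        names = [f"m{i}" for i in range(n)]
        corr = pd.DataFrame(m, index=names, columns=names)
        net = dt.build_network(corr, threshold=0.3)
        brute = {
            (names[i], names[j])
            for i in range(n) for j in range(i + 1, n)
            if m[i, j] >= 0.3
        }
        assert set(net.edges) == brute

    def test_threshold_monotonicity(self, rng):
        a = rng.uniform(0, 1, (10, 10))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        names = [f"m{i}" for i in range(10)]
        corr = pd.DataFrame(m, index=names, columns=names)
        prev = None
        for thr in (0.3, 0.5, 0.7, 0.9):
            edges = set(dt.build_network(corr, threshold=thr).edges)
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            dt.build_network(_corr(list("ab"), 0.5), threshold=1.5)


class TestDensity:
    def test_complete_graph_density_equals_n(self):
        nodes = [f"m{i}" for i in range(10)]
        edges = list(itertools.combinations(nodes, 2))
        d = dt.network_density(_net_from_edges(nodes, edges))
        assert d.E == 45 and d.N == 10
        assert d.density == pytest.approx(10.0)

    def test_path_on_four_nodes(self):
        d = dt.network_density(
            _net_from_edges("abcd", [("a", "b"), ("b", "c"), ("c", "d")]))
        assert d.density == pytest.approx(2.0)

    def test_empty_network_zero(self):
        d = dt.network_density(_net_from_edges("abcd", []))
        assert d.density == 0.0

    def test_node_rule_all_vs_connected(self):
        net = _net_from_edges("abcde", [("a", "b")])
        assert dt.network_density(net, "connected").N == 2
        assert dt.network_density(net, "all").N == 5

    @given(st.integers(2, 14), st.integers(0, 42))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_closed_form_identity_on_random_graphs(self, n, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"m{i}" for i in range(n)]
        pairs = list(itertools.combinations(nodes, 2))
        k = int(rng.integers(0, len(pairs) + 1))
        idx = rng.choice(len(pairs), size=k, replace=False)
        net = _net_from_edges(nodes, [pairs[i] for i in idx])
        d = dt.network_density(net)
        if d.E == 0 or d.N < 2:
            assert d.density == 0.0
        else:
            assert d.density == pytest.approx(2 * d.E / (d.N - 1))

    def test_node_permutation_invariance(self, rng):
        nodes = [f"m{i}" for i in range(8)]
        pairs = list(itertools.combinations(nodes, 2))
        idx = rng.choice(len(pairs), size=10, replace=False)
        edges = [pairs[i] for i in idx]
        perm = dict(zip(nodes, rng.permutation(nodes)))
        p_edges = [tuple(sorted((perm[a], perm[b]))) for a, b in edges]
        d1 = dt.network_density(_net_from_edges(nodes, edges))
        d2 = dt.network_density(_net_from_edges(nodes, p_edges))
        assert (d1.E, d1.N, d1.density) == (d2.E, d2.N, d2.density)


class TestCompareNetworks:
    def test_identical_networks_jaccard_one(self):
        n1 = _net_from_edges("abc", [("a", "b")])
        n2 = _net_from_edges("abc", [("a", "b")])
        assert dt.compare_networks(n1, n2)["jaccard"] == 1.0

    def test_disjoint_sets_jaccard_zero_and_empty_convention(self):
        n1 = _net_from_edges("abc", [("a", "b")])
        n2 = _net_from_edges("abc", [("b", "c")])
        assert dt.compare_networks(n1, n2)["jaccard"] == 0.0
        e1 = _net_from_edges("abc", [])
        e2 = _net_from_edges("abc", [])
        assert dt.compare_networks(e1, e2)["jaccard"] == 0.0

    def test_mismatched_universe_rejected(self):
        n1 = _net_from_edges("abc", [])
        n2 = _net_from_edges("abd", [])
        with pytest.raises(ValueError, match="universe"):
            dt.compare_networks(n1, n2)

    def test_matches_brute_force_sets(self, rng):
        nodes = list("abcdef")
        pairs = list(itertools.combinations(nodes, 2))
        e1 = [pairs[i] for i in rng.choice(len(pairs), 6, replace=False)]
        e2 = [pairs[i] for i in rng.choice(len(pairs), 6, replace=False)]
        out = dt.compare_networks(_net_from_edges(nodes, e1),
                                  _net_from_edges(nodes, e2))
        assert set(out["shared"]) == set(e1) & set(e2)
        assert out["jaccard"] == pytest.approx(
            len(set(e1) & set(e2)) / len(set(e1) | set(e2)))


class TestDynaRun:
    def test_planted_block_density_contrast(self, default_cohort,
                                            cohort_groups):
        """BD_GE4 (carrying the rho=0.85 block in the first two windows)
        shows higher density there; both strata converge in 16-24 h."""
        _, _, samples = default_cohort
        res = dt.dyna_run(samples, cohort_groups)
        d = res.density_table().set_index(["group", "window"])["density"]
        assert d["BD_GE4", "0-8h"] > d["BD_LT4", "0-8h"]
        assert d["BD_GE4", "8-16h"] > d["BD_LT4", "8-16h"]
        assert abs(d["BD_GE4", "16-24h"] - d["BD_LT4", "16-24h"]) < 2.0

    def test_null_cohort_networks_are_sparse(self):
        cfg = dt.default_config(seed=77, n_per_group=(40, 40),
                                planted_blocks=())
        patients, samples = dt.generate_cohort(cfg)
        groups = patients.set_index("patient_id")["group"]
        res = dt.dyna_run(samples, groups)
        # with independent log residuals, P(r >= 0.7) at n ~ 35 is tiny
        assert res.density_table()["edges"].sum() <= 3

    def test_rerun_is_deterministic(self, default_cohort, cohort_groups):
        _, _, samples = default_cohort
        r1 = dt.dyna_run(samples, cohort_groups)
        r2 = dt.dyna_run(samples, cohort_groups)
        for key in r1.networks:
            assert r1.networks[key].edges == r2.networks[key].edges

    def test_graphml_round_trip(self, default_cohort, cohort_groups, tmp_path):
        import networkx as nx

        _, _, samples = default_cohort
        res = dt.dyna_run(samples, cohort_groups)
        net = res.networks[("BD_GE4", "0-8h")]
        p = tmp_path / "net.graphml"
        net.to_graphml(p)
        g = nx.read_graphml(p)
        assert set(g.nodes) == set(net.nodes)
        assert g.number_of_edges() == net.n_edges
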