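"""Correlation networks, binarization, threshold selection, graph metrics."""

import numpy as np
import pytest

from pacnet import (
    binarize,
    correlation_matrix,
    network_features,
    select_threshold,
)
from pacnet.network import CorrelationMatrix, edges_dataframe


def cm_from_r(r):
    r = np.asarray(r, float)
    return CorrelationMatrix(r=r, channels=[f"C{i}" for i in range(len(r))])


def brute_force_metrics(adj):
    """Exhaustive degree / clustering oracle via explicit triangle counting."""
    n = len(adj)
    degree = adj.sum(axis=1)
    clustering = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            continue
        e = sum(
            adj[a, b] for ai, a in enumerate(nbrs) for b in nbrs[ai + 1:]
        )
        clustering[i] = 2 * e / (k * (k - 1))
    return degree, clustering


def random_symmetric_r(rng, n):
    r = rng.uniform(-1, 1, size=(n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    return r


class TestCorrelationMatrix:
    def test_copy_has_unit_correlation(self, make_recording, rng):
        x = rng.standard_normal(500)
        rec = make_recording(labels=["a", "b"], data=np.vstack([x, x]), n_samples=500)
        cm = correlation_matrix(rec)
        assert cm.r[0, 1] == pytest.approx(1.0)

    def test_negation_has_minus_one(self, make_recording, rng):
        x = rng.standard_normal(500)
        rec = make_recording(labels=["a", "b"], data=np.vstack([x, -x]), n_samples=500)
        assert correlation_matrix(rec).r[0, 1] == pytest.approx(-1.0)

    def test_matches_hand_computed_definition(self, make_recording):
        # 3 channels x 5 samples against the explicit covariance formula
        data = np.array(
            [[1.0, 2.0, 3.0, 4.0, 5.0],
             [2.0, 1.0, 4.0, 3.0, 6.0],
             [5.0, 3.0, 2.0, 2.0, 1.0]]
        )
        rec = make_recording(labels=["x", "y", "z"], data=data, n_samples=5)
        cm = correlation_matrix(rec)
        for i in range(3):
            for j in range(3):
                xi, yj = data[i] - data[i].mean(), data[j] - data[j].mean()
                expected = (xi * yj).sum() / np.sqrt((xi**2).sum() * (yj**2).sum())
                assert cm.r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_channel_named(self, make_recording):
        data = np.vstack([np.arange(5.0), np.full(5, 2.0)])
        rec = make_recording(labels=["ok", "flat"], data=data, n_samples=5)
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(rec)


class TestBinarize:
    def test_dense_matrix_gives_complete_graph(self):
        r = np.full((5, 5), 0.9)
        np.fill_diagonal(r, 1.0)
        net = binarize(cm_from_r(r), 0.5)
        assert np.all(net.degree == 4)
        assert np.all(net.clustering == 1.0)
        assert net.density == pytest.approx(1.0)

    def test_weak_matrix_gives_empty_graph(self):
        r = np.full((5, 5), 0.1)
        np.fill_diagonal(r, 1.0)
        net = binarize(cm_from_r(r), 0.5)
        assert np.all(net.degree == 0)
        assert np.all(net.clustering == 0.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            net = binarize(cm_from_r(random_symmetric_r(rng, 8)), 0.3)
            deg, clust = brute_force_metrics(net.adjacency)
            np.testing.assert_array_equal(net.degree, deg)
            np.testing.assert_allclose(net.clustering, clust)
            assert net.degree.sum() % 2 == 0
            assert np.all((net.clustering >= 0) & (net.clustering <= 1))

    def test_threshold_monotonicity(self, rng):
        cm = cm_from_r(random_symmetric_r(rng, 12))
        prev = binarize(cm, 0.1)
        for thr in (0.3, 0.5, 0.7, 0.9):
            cur = binarize(cm, thr)
            assert np.all(cur.degree <= prev.degree)
            assert cur.adjacency.sum() <= prev.adjacency.sum()
            prev = cur

    def test_absolute_mode_keeps_negative_edges(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = -0.8
        assert binarize(cm_from_r(r), 0.5).degree[0] == 0
        assert binarize(cm_from_r(r), 0.5, absolute=True).degree[0] == 1

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            binarize(cm_from_r(np.eye(3)), 1.5)


def grid_scan_oracle(r, lo, hi):
    """Independent scan: largest 0.01-grid threshold meeting both criteria."""
    for thr in np.round(np.arange(0.99, 0.0, -0.01), 2):
        adj = (r >= thr).astype(int)
        np.fill_diagonal(adj, 0)
        n = len(adj)
        density = adj.sum() / (n * (n - 1))
        if adj.sum(axis=1).min() >= 1 and lo <= density <= hi:
            return float(thr)
    return None


class TestSelectThreshold:
    def test_complete_graph_picks_largest_grid_value(self):
        # edges are inclusive (r >= thr), so 0.90 itself still qualifies
        r = np.full((6, 6), 0.9)
        np.fill_diagonal(r, 1.0)
        thr = select_threshold(cm_from_r(r), (0.5, 1.0))
        assert thr == pytest.approx(grid_scan_oracle(r, 0.5, 1.0)) == 0.90

    def test_block_structure_matches_grid_scan_oracle(self):
        n = 8
        r = np.full((n, n), 0.2)
        r[:4, :4] = r[4:, 4:] = 0.8
        r[3, 4] = r[4, 3] = 0.6  # bridge
        np.fill_diagonal(r, 1.0)
        thr = select_threshold(cm_from_r(r), (0.1, 0.5))
        assert thr == pytest.approx(grid_scan_oracle(r, 0.1, 0.5))
        assert binarize(cm_from_r(r), thr).degree.min() >= 1

    def test_random_matrices_match_grid_scan_oracle(self, rng):
        for _ in range(10):
            r = random_symmetric_r(rng, 10)
            expected = grid_scan_oracle(r, 0.05, 0.45)
            if expected is None:
                continue
            assert select_threshold(cm_from_r(r), (0.05, 0.45)) == pytest.approx(expected)

    def test_uncorrelated_input_rejected(self):
        with pytest.raises(ValueError, match="no threshold"):
            select_threshold(cm_from_r(np.eye(5)))

    def test_fallback_warns_when_density_unreachable(self):
        r = np.full((6, 6), 0.9)
        np.fill_diagonal(r, 1.0)
        with pytest.warns(UserWarning, match="no-isolated-node"):
            thr = select_threshold(cm_from_r(r), (0.1, 0.2))  # density always 1
        assert thr == pytest.approx(0.90)


class TestNetworkFeatures:
    def test_triangle_graph(self):
        r = np.full((3, 3), 0.9)
        np.fill_diagonal(r, 1.0)
        net = binarize(cm_from_r(r), 0.5)
        table = network_features(net, "s01", "wm", "task", "gamma")
        per = table[table["channel"] != "_network_"]
        assert set(per[per["feature_name"] == "degree"]["value"]) == {2.0}
        assert set(per[per["feature_name"] == "clustering"]["value"]) == {1.0}
        mean_rows = table[table["channel"] == "_network_"]
        assert mean_rows.set_index("feature_name")["value"]["degree"] == 2.0

    def test_star_graph(self):
        r = np.eye(5)
        r[0, 1:] = r[1:, 0] = 0.9
        net = binarize(cm_from_r(r), 0.5)
        assert net.degree[0] == 4
        assert np.all(net.degree[1:] == 1)
        assert np.all(net.clustering == 0.0)

    def test_mean_rows_match_oracle(self, rng):
        net = binarize(cm_from_r(random_symmetric_r(rng, 8)), 0.3)
        table = network_features(net, "s", "wm", "task", "delta")
        deg, clust = brute_force_metrics(net.adjacency)
        means = table[table["channel"] == "_network_"].set_index("feature_name")["value"]
        assert means["degree"] == pytest.approx(deg.mean())
        assert means["clustering"] == pytest.approx(clust.mean())

    def test_edge_list_round_trips_adjacency(self, rng):
        net = binarize(cm_from_r(random_symmetric_r(rng, 6)), 0.3)
        edges = edges_dataframe(net)
        assert len(edges) == net.adjacency.sum() // 2
        for a, b in edges.itertuples(index=False):
            i, j = net.channels.index(a), net.channels.index(b)
            assert net.adjacency[i, j] == 1
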