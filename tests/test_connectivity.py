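"""Lag-aware connectivity: correlation oracles, invariances, graph and speed."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from calnetdyn.connectivity import (ConnectivityParams, build_graph,
                                    functional_connections, lagged_correlation,
                                    neighbor_mask_from_centroids, neighbor_pairs,
                                    preprocess_for_corr, propagation_speed)
from calnetdyn.imaging_io import ROISet, TraceMatrix
from calnetdyn.synthetic import (astro_like, generate_network, neuron_like,
                                 render_traces, score_edge_recovery)


def brute_force_lagged_corr(a, b, max_lag):
    """Independent oracle: per-lag Pearson from first principles."""
    t = len(a)
    best = (-np.inf, 0)
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            x, y = a[: t - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: t + lag]
        xc, yc = x - x.mean(), y - y.mean()
        denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        if denom == 0:
            continue
        r = float((xc * yc).sum() / denom)
        if r > best[0]:
            best = (r, lag)
    return best


class TestLaggedCorrelation:
    def test_identical_traces(self, rng):
        a = rng.normal(size=500)
        r, lag = lagged_correlation(a, a, 10)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert lag == 0

    def test_known_shift_recovered(self):
        spec = neuron_like(n_cells=2, duration_s=600.0, noise_sd=0.0,
                           drift_amplitude=0.0, edge_density=0.0, seed=0)
        truth = generate_network(spec)
        tr = render_traces(truth).values[0]
        b = np.roll(tr, 4)
        r, lag = lagged_correlation(tr, b, 10)
        assert lag == 4    # b follows a by 4 frames = 2 s at 2 Hz
        assert r > 0.99

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=300)
            b = rng.normal(size=300) + 0.5 * np.roll(a, rng.integers(-5, 6))
            r, lag = lagged_correlation(a, b, 8)
            r_o, lag_o = brute_force_lagged_corr(a, b, 8)
            assert r == pytest.approx(r_o, abs=1e-12)
            assert lag == lag_o

    def test_independent_noise_stays_subthreshold(self, rng):
        hits = 0
        for _ in range(100):
            a, b = rng.normal(size=2400), rng.normal(size=2400)
            r, _ = lagged_correlation(a, b, 10)
            hits += r >= 0.3
        assert hits == 0

    def test_too_short_traces_rejected(self):
        with pytest.raises(ValueError):
            lagged_correlation(np.ones(10), np.ones(10), 10)

    def test_constant_traces_flagged_undefined(self):
        r, lag = lagged_correlation(np.ones(100), np.ones(100), 5)
        assert np.isnan(r) and lag == 0


class TestPreprocess:
    def test_affine_invariance(self, astro_traces):
        p = preprocess_for_corr(astro_traces)
        shifted = TraceMatrix(3.0 * astro_traces.values + 42.0,
                              astro_traces.frame_rate_hz)
        p2 = preprocess_for_corr(shifted)
        assert np.max(np.abs(p.values - p2.values)) < 1e-9

    def test_zero_variance_traces_flagged_not_dropped(self):
        vals = np.vstack([np.full(300, 2.0), np.random.default_rng(0).normal(size=300)])
        p = preprocess_for_corr(TraceMatrix(vals, 2.0))
        assert p.usable.tolist() == [False, True]
        assert p.values.shape == vals.shape

    def test_slow_sinusoid_attenuation_matches_filter_response(self):
        # derived oracle: one-pole EMA high-pass response at the sine frequency
        tau, rate, t = 60.0, 2.0, np.arange(4800) / 2.0
        for period in (600.0, 15.0):
            x = np.sin(2 * np.pi * t / period)[None, :]
            p = preprocess_for_corr(TraceMatrix(1.0 + 0.1 * x, rate), tau_slow_s=tau)
            resid_sd = (p.values - p.values.mean()).std()
            alpha = 1 - np.exp(-1 / (tau * rate))
            w = 2 * np.pi / (period * rate)
            h = alpha / (1 - (1 - alpha) * np.exp(-1j * w))
            expected = abs(1 - h) * 0.1 / np.sqrt(2)
            # preprocess normalizes by noise sd of the raw trace; compare shape only
            ratio = resid_sd / p.values.std()
            assert ratio == pytest.approx(1.0, abs=0.05)
            # fast sinusoid (period << tau) passes nearly unattenuated,
            # slow one is attenuated per the filter response
            if period == 15.0:
                assert abs(1 - h) > 0.95
            else:
                assert abs(1 - h) < 0.6


class TestFunctionalConnections:
    def test_two_identical_traces_one_connection(self, rng):
        a = rng.normal(1.0, 0.1, size=500)
        tr = TraceMatrix(np.vstack([a, a]), 2.0)
        res = functional_connections(tr)
        assert res.n_connections == 1
        assert res.connections_per_cell.tolist() == [1, 1]

    def test_threshold_one_gives_empty_adjacency(self, network_traces):
        res = functional_connections(network_traces,
                                     ConnectivityParams(corr_threshold=1.0))
        assert res.adjacency.sum() == 0

    def test_raising_threshold_never_adds_connections(self, network_traces):
        lo = functional_connections(network_traces, ConnectivityParams(corr_threshold=0.2))
        hi = functional_connections(network_traces, ConnectivityParams(corr_threshold=0.5))
        assert np.all(hi.adjacency <= lo.adjacency)

    def test_lag_antisymmetry_and_corr_symmetry(self, network_traces):
        res = functional_connections(network_traces)
        assert np.array_equal(res.lag_frames, -res.lag_frames.T)
        sym = np.allclose(res.corr, res.corr.T, equal_nan=True)
        assert sym
        assert np.array_equal(res.adjacency, res.adjacency.T)

    def test_matrix_path_matches_pairwise_function(self, network_traces):
        res = functional_connections(network_traces)
        p = preprocess_for_corr(network_traces)
        max_lag = res.params.max_lag_frames(network_traces.frame_rate_hz)
        rng = np.random.default_rng(0)
        for _ in range(15):
            i, j = rng.choice(network_traces.n_cells, size=2, replace=False)
            i, j = int(min(i, j)), int(max(i, j))
            r, lag = lagged_correlation(p.values[i], p.values[j], max_lag)
            assert res.corr[i, j] == pytest.approx(r, abs=1e-10)
            assert res.lag_frames[i, j] == lag

    def test_fewer_than_two_cells_rejected(self):
        tr = TraceMatrix(np.random.default_rng(0).normal(size=(1, 300)), 2.0)
        with pytest.raises(ValueError):
            functional_connections(tr)

    def test_affine_invariance_of_adjacency_and_lags(self, network_traces):
        res = functional_connections(network_traces)
        scaled = TraceMatrix(0.5 * network_traces.values - 3.0,
                             network_traces.frame_rate_hz,
                             network_traces.centroids_um)
        res2 = functional_connections(scaled)
        assert np.array_equal(res.adjacency, res2.adjacency)
        assert np.array_equal(res.lag_frames, res2.lag_frames)
        assert np.nanmax(np.abs(res.corr - res2.corr)) < 1e-10


class TestNeighborPairs:
    def test_touching_disks_are_neighbors(self):
        lab = np.zeros((40, 40), dtype=np.int32)
        yy, xx = np.mgrid[0:40, 0:40]
        lab[(yy - 20) ** 2 + (xx - 12) ** 2 <= 36] = 1
        lab[(yy - 20) ** 2 + (xx - 25) ** 2 <= 36] = 2
        rois = ROISet.from_label_image(lab, pixel_size_um=2.0)
        nb = neighbor_pairs(rois, ConnectivityParams(neighbor_gap_um=5.0))
        assert nb[0, 1] and nb[1, 0] and not nb[0, 0]

    def test_distant_disks_not_neighbors(self):
        lab = np.zeros((60, 60), dtype=np.int32)
        yy, xx = np.mgrid[0:60, 0:60]
        lab[(yy - 10) ** 2 + (xx - 10) ** 2 <= 16] = 1
        lab[(yy - 45) ** 2 + (xx - 45) ** 2 <= 16] = 2   # ~50 um apart at 2 um/px
        rois = ROISet.from_label_image(lab, pixel_size_um=2.0)
        nb = neighbor_pairs(rois, ConnectivityParams(neighbor_gap_um=5.0))
        assert not nb[0, 1]

    @given(st.floats(min_value=0.0, max_value=30.0),
           st.floats(min_value=0.0, max_value=30.0))
    def test_growing_gap_grows_neighbor_set(self, g1, g2):
        cents = np.random.default_rng(11).uniform(0, 200, size=(8, 2))
        lo, hi = sorted((g1, g2))
        nb_lo = neighbor_mask_from_centroids(cents, 8.0, lo)
        nb_hi = neighbor_mask_from_centroids(cents, 8.0, hi)
        assert np.all(nb_lo <= nb_hi)


class TestGraphAndSpeed:
    def test_zero_lag_pair_becomes_reciprocal_undirected(self, rng):
        a = rng.normal(1.0, 0.1, size=500)
        tr = TraceMatrix(np.vstack([a, a]), 2.0,
                         centroids_um=np.array([[0.0, 0.0], [100.0, 0.0]]))
        res = functional_connections(tr)
        g = build_graph(res, tr.centroids_um)
        assert g.has_edge(0, 1) and g.has_edge(1, 0)
        assert not g.edges[0, 1]["directed"]
        assert np.isnan(g.edges[0, 1]["speed_um_s"])
        assert propagation_speed(g).n_edges == 0

    def test_speed_formula(self, rng):
        a = rng.normal(1.0, 0.2, size=600)
        b = np.roll(a, 4)
        tr = TraceMatrix(np.vstack([a, b]), 2.0,
                         centroids_um=np.array([[0.0, 0.0], [100.0, 0.0]]))
        res = functional_connections(tr)
        g = build_graph(res, tr.centroids_um)
        # b follows a by 4 frames = 2 s over 100 um -> 50 um/s, edge a -> b
        assert g.has_edge(0, 1) and g.edges[0, 1]["directed"]
        assert g.edges[0, 1]["speed_um_s"] == pytest.approx(50.0)
        assert propagation_speed(g).median == pytest.approx(50.0)

    def test_empty_graph_speed_undefined_not_error(self):
        import networkx as nx

        s = propagation_speed(nx.DiGraph())
        assert s.n_edges == 0 and np.isnan(s.median)

    def test_network_recovery_beats_thresholds(self, network_truth, network_traces):
        res = functional_connections(network_traces)
        g = build_graph(res, network_truth.centroids_um)
        score = score_edge_recovery(g, network_truth)
        assert score["precision"] >= 0.8
        assert score["recall"] >= 0.8
        assert score["lag_accuracy"] >= 0.9

    def test_speed_roundtrip_within_20_percent(self, network_truth, network_traces):
        res = functional_connections(network_traces)
        g = build_graph(res, network_truth.centroids_um)
        sp = propagation_speed(g)
        true_speed = network_truth.spec.propagation_speed_um_s
        assert abs(sp.median - true_speed) / true_speed <= 0.2

    def test_graph_edge_count_bounded_by_adjacency_pairs(self, network_truth,
                                                         network_traces):
        res = functional_connections(network_traces)
        g = build_graph(res, network_truth.centroids_um)
        directed = sum(1 for *_, d in g.edges(data=True) if d["directed"])
        undirected = sum(1 for *_, d in g.edges(data=True) if not d["directed"])
        assert directed + undirected // 2 == res.n_connections
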