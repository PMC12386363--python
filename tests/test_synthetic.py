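"""Generator correctness: geometry, delays, event statistics, rendering."""

import dataclasses

import numpy as np
import pytest

from calnetdyn.imaging_io import extract_traces
from calnetdyn.synthetic import (GroundTruth, SizingError, SyntheticSpec, astro_like,
                                 delay_frames, generate_network, neuron_like,
                                 render_movie, render_traces, transient_kernel)


def small_spec(**kw):
    base = dict(n_cells=6, duration_s=300.0, seed=0)
    base.update(kw)
    return astro_like(**base)


class TestSpecValidation:
    @pytest.mark.parametrize("bad", [
        dict(n_cells=1),
        dict(frame_rate_hz=0.0),
        dict(edge_density=1.5),
        dict(transmission_prob=-0.1),
        dict(duration_s=2.0),                 # < 16 frames
        dict(event_rate_per_min=10.0),        # unreachable with refractory
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            small_spec(**bad)

    def test_field_too_small_for_cells(self):
        with pytest.raises(SizingError):
            generate_network(small_spec(n_cells=200, field_um=80.0))


class TestNetwork:
    def test_zero_density_gives_no_edges_and_only_spontaneous(self):
        truth = generate_network(small_spec(edge_density=0.0))
        assert truth.edges == []
        counts = np.array([len(o) for o in truth.event_onsets])
        assert np.array_equal(counts, truth.spontaneous_counts)

    def test_geometric_delay_formula(self):
        # 100 um at 50 um/s sampled at 2 Hz -> 4 frames
        assert delay_frames(100.0, 50.0, 2.0) == 4
        assert delay_frames(1.0, 50.0, 2.0) == 1  # floor at one frame

    def test_two_cell_network_edge_delay(self):
        spec = astro_like(n_cells=2, edge_density=1.0, transmission_prob=1.0,
                          duration_s=300.0, seed=1)
        cent = np.array([[100.0, 100.0], [200.0, 100.0]])
        truth = generate_network(spec, centroids_um=cent)
        assert len(truth.edges) == 1
        _, _, d = truth.edges[0]
        assert d == 4

    def test_all_edge_delays_consistent_with_geometry(self, network_truth):
        spec = network_truth.spec
        for s, t, d in network_truth.edges:
            dist = np.hypot(*(network_truth.centroids_um[s] - network_truth.centroids_um[t]))
            assert d == delay_frames(dist, spec.propagation_speed_um_s, spec.frame_rate_hz)
            assert d >= 1 and s != t

    def test_min_separation_between_centroids(self, network_truth):
        c = network_truth.centroids_um
        d = np.hypot(*(c[:, None, :] - c[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * network_truth.spec.cell_radius_um - 1e-9

    def test_seeded_determinism(self):
        spec = small_spec(n_cells=12, edge_density=0.1, seed=7)
        a, b = generate_network(spec), generate_network(spec)
        assert np.array_equal(a.centroids_um, b.centroids_um)
        assert a.edges == b.edges
        for x, y in zip(a.event_onsets, b.event_onsets):
            assert np.array_equal(x, y)

    def test_onsets_strictly_increasing_and_respect_refractory(self, network_truth):
        refr = max(1, round(network_truth.spec.effective_refractory_s
                            * network_truth.spec.frame_rate_hz))
        for onsets in network_truth.event_onsets:
            if len(onsets) > 1:
                assert np.all(np.diff(onsets) >= refr)

    def test_degree_caps_and_feedforward(self, network_truth):
        spec = network_truth.spec
        indeg = np.zeros(spec.n_cells, int)
        outdeg = np.zeros(spec.n_cells, int)
        for s, t, _ in network_truth.edges:
            outdeg[s] += 1
            indeg[t] += 1
        assert indeg.max() <= spec.max_in_degree
        assert outdeg.max() <= spec.max_out_degree
        # feed-forward: no cell is both a source and a target
        assert not np.any((indeg > 0) & (outdeg > 0))

    def test_mean_spontaneous_rate_matches_nominal(self):
        # dead-time renewal is constructed to realize the nominal mean rate
        counts = []
        for seed in range(40):
            truth = generate_network(small_spec(edge_density=0.0, seed=seed,
                                                n_cells=4, duration_s=1200.0))
            counts.extend(len(o) for o in truth.event_onsets)
        counts = np.asarray(counts, float)
        expected = 1.0 * 20.0  # 1 event/min for 20 min
        sem = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 3 * sem + 0.5

    def test_cascade_propagates_events_along_edge(self):
        spec = astro_like(n_cells=2, edge_density=1.0, transmission_prob=1.0,
                          duration_s=600.0, seed=2)
        cent = np.array([[100.0, 100.0], [200.0, 100.0]])
        truth = generate_network(spec, centroids_um=cent)
        (s, t, d) = truth.edges[0]
        src, tgt = truth.event_onsets[s], set(truth.event_onsets[t].tolist())
        # with transmission 1, every source event not censored by the target's
        # refractory period appears at source onset + delay
        hits = sum(1 for f in src if f + d in tgt)
        assert hits >= 0.5 * len(src)
        assert hits >= 1


class TestKernelAndTraces:
    def test_kernel_zero_before_onset_and_peak_amplitude(self):
        t = np.linspace(-5, 60, 2000)
        k = transient_kernel(t, 3.0, 8.0, amplitude=0.25)
        assert np.all(k[t < 0] == 0)
        assert k.max() <= 0.25 + 1e-12
        t_peak = 3.0 * np.log1p(8.0 / 3.0)   # analytic argmax of the kernel
        assert transient_kernel(np.array([t_peak]), 3.0, 8.0, 0.25)[0] == \
            pytest.approx(0.25, abs=1e-12)

    def test_constant_trace_without_events_noise_or_drift(self):
        spec = small_spec(noise_sd=0.0, drift_amplitude=0.0, edge_density=0.0)
        truth = generate_network(spec)
        truth = dataclasses.replace(truth, event_onsets=[np.array([], int)] * spec.n_cells)
        tr = render_traces(truth)
        assert np.allclose(tr.values, 1.0)

    def test_single_onset_peak_at_kernel_argmax(self):
        spec = small_spec(n_cells=2, noise_sd=0.0, drift_amplitude=0.0)
        truth = generate_network(spec)
        onset = 100
        truth = dataclasses.replace(
            truth, event_onsets=[np.array([onset]), np.array([], int)])
        tr = render_traces(truth)
        # independent oracle: evaluate the kernel on the frame grid
        tg = np.arange(spec.n_frames - onset) / spec.frame_rate_hz
        kernel = transient_kernel(tg, spec.transient_rise_s, spec.transient_decay_s,
                                  spec.amplitude)
        expected_peak = onset + int(np.argmax(kernel))
        assert abs(int(np.argmax(tr.values[0])) - expected_peak) <= 1

    def test_traces_bitwise_reproducible(self):
        spec = small_spec(seed=9)
        t1 = render_traces(generate_network(spec))
        t2 = render_traces(generate_network(spec))
        assert np.array_equal(t1.values, t2.values)

    def test_trace_length_and_centroids(self, astro_truth, astro_traces):
        assert astro_traces.n_frames == astro_truth.spec.n_frames
        assert np.array_equal(astro_traces.centroids_um, astro_truth.centroids_um)


class TestMovie:
    def test_label_image_has_all_cells(self):
        truth = generate_network(small_spec(n_cells=5, duration_s=60.0))
        movie, rois = render_movie(truth, px=160)
        labels = np.unique(rois.label_image)
        assert set(labels.tolist()) == set(range(6))  # 0 background + 5 cells
        assert rois.n_cells == 5

    def test_noiseless_roundtrip_movie_to_traces(self):
        spec = small_spec(n_cells=4, duration_s=60.0, noise_sd=0.0)
        truth = generate_network(spec)
        movie, rois = render_movie(truth, px=160)
        extracted = extract_traces(movie, rois)
        clean = render_traces(truth)
        assert np.max(np.abs(extracted.values - clean.values)) < 1e-9

    def test_too_coarse_rendering_rejected(self):
        truth = generate_network(small_spec(n_cells=4, duration_s=60.0))
        with pytest.raises(ValueError):
            render_movie(truth, px=32)

    def test_background_pixels_uncorrelated_with_events(self):
        spec = small_spec(n_cells=3, duration_s=120.0, seed=21)
        truth = generate_network(spec)
        movie, rois = render_movie(truth, px=96)
        clean = render_traces(truth)
        bg = movie.frames[:, rois.label_image == 0].mean(axis=1)
        r = np.corrcoef(bg, clean.values[0] - clean.values[0].mean())[0, 1]
        assert abs(r) < 0.2
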