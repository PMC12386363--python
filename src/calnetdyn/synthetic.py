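"""Ground-truth simulator for network calcium dynamics.

Generates (i) a spatial directed network of cells with geometry-consistent
propagation delays, (ii) per-cell calcium event trains (spontaneous events plus
events propagated along edges), (iii) fluorescence traces built from a
double-exponential indicator kernel with baseline drift and sensor noise, and
(iv) optionally a rendered movie plus matching ROI label image. Every stage of
the analysis pipeline can therefore be scored against known ground truth.

The default parameters describe an astrocyte-like culture imaged at 2 Hz for
20 min in a 639 x 639 um field: sparse quasi-periodic somatic events of
15-20 s, waves travelling at ~50 um/s between nearby (gap-junction-coupled)
cells, a few-percent slow baseline drift, and additive Gaussian sensor noise
at one fifth of the transient amplitude.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .imaging_io import Movie, ROISet, TraceMatrix

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "neuron_like",
    "astro_like",
    "transient_kernel",
    "generate_network",
    "render_traces",
    "render_movie",
    "score_event_recovery",
    "score_edge_recovery",
    "write_ground_truth",
]


class SizingError(ValueError):
    """Field too small to place the requested number of cells."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a simulated culture recording.

    Distances in micrometres, times in seconds, rates in Hz unless suffixed.
    ``amplitude`` and ``noise_sd`` are fractions of the resting baseline
    (Delta F over F0); the default amplitude is five noise sd.
    """

    n_cells: int = 20
    field_um: float = 639.0
    frame_rate_hz: float = 2.0
    duration_s: float = 1200.0
    event_rate_per_min: float = 1.0
    transient_rise_s: float = 3.0
    transient_decay_s: float = 8.0
    amplitude: float = 0.25
    noise_sd: float = 0.05
    drift_amplitude: float = 0.02
    drift_period_s: float = 300.0
    edge_density: float = 0.1
    propagation_speed_um_s: float = 50.0
    transmission_prob: float = 0.9
    connection_radius_um: float = 200.0
    refractory_s: float | None = None
    max_in_degree: int = 1
    max_out_degree: int = 2
    feedforward: bool = True
    cell_radius_um: float = 8.0
    cascade_cap_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        for name in ("field_um", "frame_rate_hz", "duration_s", "event_rate_per_min",
                     "transient_rise_s", "transient_decay_s", "amplitude",
                     "drift_period_s", "propagation_speed_um_s", "cell_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("noise_sd", "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("edge_density", "transmission_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frame_rate_hz * self.duration_s < 16:
            raise ValueError("recording must span at least 16 frames")
        if self.refractory_s is not None and self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")
        if self.max_in_degree < 0 or self.max_out_degree < 0:
            raise ValueError("degree caps must be >= 0")
        mean_gap_s = 60.0 / self.event_rate_per_min
        if self.effective_refractory_s >= mean_gap_s:
            raise ValueError(
                f"event_rate_per_min {self.event_rate_per_min} is unachievable with a "
                f"{self.effective_refractory_s:.1f} s minimum inter-event interval"
            )

    @property
    def effective_refractory_s(self) -> float:
        """Minimum onset-to-onset interval; defaults to the transient time scale
        rise + 2 * decay (a cell cannot re-initiate during its own event)."""
        if self.refractory_s is not None:
            return self.refractory_s
        return self.transient_rise_s + 2.0 * self.transient_decay_s

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


def neuron_like(**overrides) -> SyntheticSpec:
    """Neuron-like kinetics: fast transients of a few seconds, ~1 event/min."""
    base = dict(transient_rise_s=0.5, transient_decay_s=2.0,
                event_rate_per_min=1.0, refractory_s=3.0)
    base.update(overrides)
    return SyntheticSpec(**base)


def astro_like(**overrides) -> SyntheticSpec:
    """Astrocyte-like kinetics: slow transients with full width near 15-20 s."""
    base = dict(transient_rise_s=3.0, transient_decay_s=8.0, event_rate_per_min=1.0)
    base.update(overrides)
    return SyntheticSpec(**base)


@dataclass
class GroundTruth:
    """The simulated network and event trains that generated a recording."""

    centroids_um: np.ndarray                 # (n_cells, 2), (x, y)
    edges: list[tuple[int, int, int]]        # (source, target, delay_frames >= 1)
    event_onsets: list[np.ndarray]           # per cell, strictly increasing frames
    spec: SyntheticSpec
    spontaneous_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_cells(self) -> int:
        return self.centroids_um.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(s, t) for s, t, _ in self.edges}


def delay_frames(distance_um: float, speed_um_s: float, frame_rate_hz: float) -> int:
    """Geometric propagation delay, at least one frame."""
    return max(1, int(round(distance_um / speed_um_s * frame_rate_hz)))


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _place_centroids(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform placement with a minimum separation of two cell radii."""
    r = spec.cell_radius_um
    lo, hi = r, spec.field_um - r
    if hi <= lo:
        raise SizingError("field smaller than one cell diameter")
    min_sep = 2.0 * r
    pts: list[np.ndarray] = []
    max_tries = 200 * spec.n_cells
    tries = 0
    while len(pts) < spec.n_cells:
        if tries >= max_tries:
            raise SizingError(
                f"could not place {spec.n_cells} cells with {min_sep:.0f} um separation "
                f"in a {spec.field_um:.0f} um field"
            )
        tries += 1
        p = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(p - q)) >= min_sep for q in pts):
            pts.append(p)
    return np.array(pts)


def _spontaneous_onsets(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Dead-time renewal train realizing the nominal mean event rate.

    Inter-onset interval = refractory + Exp(mean_gap - refractory), so the mean
    interval equals 60 / event_rate_per_min while onsets never violate the
    minimum spacing (sparse, quasi-periodic events).
    """
    mean_gap = 60.0 / spec.event_rate_per_min
    refr = spec.effective_refractory_s
    excess = mean_gap - refr
    onsets = []
    # random start phase so trains are stationary rather than locked to t=0
    t = rng.uniform(0.0, mean_gap)
    while t < spec.duration_s:
        frame = int(np.floor(t * spec.frame_rate_hz))
        if frame < spec.n_frames:
            onsets.append(frame)
        t += refr + rng.exponential(excess)
    return np.array(sorted(set(onsets)), dtype=int)


def generate_network(spec: SyntheticSpec,
                     centroids_um: np.ndarray | None = None) -> GroundTruth:
    """Sample the ground-truth network and simulate the event cascade.

    Cells are placed uniformly (minimum separation two cell radii); directed
    edges are sampled at ``edge_density`` among ordered pairs within the
    connection radius, with delay = round(distance / speed * frame_rate)
    (minimum 1 frame). Spontaneous onsets follow the dead-time renewal train;
    each accepted event then propagates along every outgoing edge with
    probability ``transmission_prob``, inserting a child onset at
    source_onset + delay. A cell ignores arrivals during its refractory
    interval, and total accepted events per cell are capped at
    ``cascade_cap_factor`` x max(1, spontaneous count) to bound cascades.
    """
    rng = _substream(spec.seed, 0)
    if centroids_um is None:
        centroids = _place_centroids(spec, rng)
    else:
        centroids = np.asarray(centroids_um, dtype=float)
        if centroids.shape != (spec.n_cells, 2):
            raise ValueError("centroids_um must have shape (n_cells, 2)")

    # candidate couplings: local pairs only, oriented along a random topological
    # order so the ground-truth graph is acyclic and lead-lag direction is well
    # defined; degree caps bound convergence/divergence, and the feed-forward
    # option restricts the graph to driver -> follower couplings (depth 1)
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    eligible = (dist <= spec.connection_radius_um) & ~np.eye(spec.n_cells, dtype=bool)
    n_ordered = int(eligible.sum())
    order = rng.permutation(spec.n_cells)
    rank = np.empty(spec.n_cells, dtype=int)
    rank[order] = np.arange(spec.n_cells)
    ii, jj = np.nonzero(eligible & (rank[:, None] < rank[None, :]))
    n_edges = int(round(spec.edge_density * n_ordered))
    edges: list[tuple[int, int, int]] = []
    if n_edges > 0 and ii.size > 0:
        in_deg = np.zeros(spec.n_cells, dtype=int)
        out_deg = np.zeros(spec.n_cells, dtype=int)
        for k in rng.permutation(ii.size):
            if len(edges) >= n_edges:
                break
            s, t = int(ii[k]), int(jj[k])
            if in_deg[t] >= spec.max_in_degree or out_deg[s] >= spec.max_out_degree:
                continue
            if spec.feedforward and (in_deg[s] > 0 or out_deg[t] > 0):
                continue
            in_deg[t] += 1
            out_deg[s] += 1
            edges.append((s, t, delay_frames(dist[s, t], spec.propagation_speed_um_s,
                                             spec.frame_rate_hz)))
        edges.sort()

    spont = [_spontaneous_onsets(spec, _substream(spec.seed, 1, c))
             for c in range(spec.n_cells)]
    spont_counts = np.array([len(s) for s in spont], dtype=int)

    out_edges: list[list[tuple[int, int]]] = [[] for _ in range(spec.n_cells)]
    for s, t, d in edges:
        out_edges[s].append((t, d))

    refr_frames = max(1, int(round(spec.effective_refractory_s * spec.frame_rate_hz)))
    caps = np.maximum(1, spont_counts) * spec.cascade_cap_factor
    rng_cascade = _substream(spec.seed, 2)

    heap: list[tuple[int, int, int]] = []
    seq = 0
    for c, frames in enumerate(spont):
        for f in frames:
            heap.append((int(f), seq, c))
            seq += 1
    heapq.heapify(heap)

    accepted: list[list[int]] = [[] for _ in range(spec.n_cells)]
    n_frames = spec.n_frames
    while heap:
        frame, _, cell = heapq.heappop(heap)
        if accepted[cell] and frame - accepted[cell][-1] < refr_frames:
            continue
        if len(accepted[cell]) >= caps[cell]:
            continue
        accepted[cell].append(frame)
        for tgt, d in out_edges[cell]:
            if rng_cascade.random() < spec.transmission_prob:
                child = frame + d
                if child < n_frames:
                    heapq.heappush(heap, (child, seq, tgt))
                    seq += 1

    onsets = [np.array(a, dtype=int) for a in accepted]
    return GroundTruth(centroids_um=centroids, edges=edges, event_onsets=onsets,
                       spec=spec, spontaneous_counts=spont_counts)


def transient_kernel(t_s: np.ndarray, rise_s: float, decay_s: float,
                     amplitude: float = 1.0) -> np.ndarray:
    """Calcium-indicator impulse response (1 - e^(-t/rise)) e^(-t/decay).

    Normalized so the peak equals ``amplitude``; zero for t < 0. The peak sits
    at t* = rise * ln(1 + decay / rise).
    """
    t = np.asarray(t_s, dtype=float)
    t_peak = rise_s * np.log1p(decay_s / rise_s)
    peak = (1.0 - np.exp(-t_peak / rise_s)) * np.exp(-t_peak / decay_s)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s) / peak * amplitude
    return np.where(t >= 0.0, k, 0.0)


def _kernel_on_grid(spec: SyntheticSpec) -> np.ndarray:
    """Kernel sampled on the frame grid, truncated when < 1e-8 of peak."""
    n = int(np.ceil((spec.transient_rise_s * np.log1p(spec.transient_decay_s / spec.transient_rise_s)
                     + spec.transient_decay_s * np.log(1e8)) * spec.frame_rate_hz)) + 1
    t = np.arange(n) / spec.frame_rate_hz
    return transient_kernel(t, spec.transient_rise_s, spec.transient_decay_s, spec.amplitude)


def render_traces(truth: GroundTruth, include_noise: bool = True) -> TraceMatrix:
    """Fluorescence traces: baseline 1 + sinusoidal drift + transients + noise.

    Per-cell randomness (drift phase, noise) comes from fixed substreams of the
    spec seed, so traces are reproducible independently of network sampling.
    """
    spec = truth.spec
    n_frames = spec.n_frames
    t = np.arange(n_frames) / spec.frame_rate_hz
    kernel = _kernel_on_grid(spec)
    values = np.empty((truth.n_cells, n_frames), dtype=float)
    for c in range(truth.n_cells):
        rng = _substream(spec.seed, 3, c)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        trace = 1.0 + spec.drift_amplitude * np.sin(2.0 * np.pi * t / spec.drift_period_s + phase)
        for onset in truth.event_onsets[c]:
            stop = min(n_frames, onset + kernel.size)
            trace[onset:stop] += kernel[: stop - onset]
        if include_noise and spec.noise_sd > 0:
            trace = trace + rng.normal(0.0, spec.noise_sd, size=n_frames)
        values[c] = trace
    return TraceMatrix(values=values, frame_rate_hz=spec.frame_rate_hz,
                       centroids_um=truth.centroids_um.copy())


def render_movie(truth: GroundTruth, px: int = 128,
                 background: float = 0.2) -> tuple[Movie, ROISet]:
    """Draw each cell as a filled disk whose pixels follow the cell's trace.

    Pixel noise is i.i.d. Gaussian with the spec's noise sd, added per pixel
    (trace extraction therefore averages it down by sqrt(ROI area)). Also
    returns the matching ROI label image. Pixels claimed by two disks (possible
    only through pixelation of tangent disks) go to the nearer centroid.
    """
    spec = truth.spec
    if px < 32:
        raise ValueError("px must be >= 32")
    pixel_size = spec.field_um / px
    r_px = spec.cell_radius_um / pixel_size
    if np.pi * r_px ** 2 < 4:
        raise ValueError(
            f"px={px} makes cell disks smaller than 4 px; increase px "
            f"(cell radius {spec.cell_radius_um} um = {r_px:.1f} px)"
        )
    yy, xx = np.mgrid[0:px, 0:px]
    # pixel centres in um, (x, y) convention
    x_um = (xx + 0.5) * pixel_size
    y_um = (yy + 0.5) * pixel_size
    label = np.zeros((px, px), dtype=np.int32)
    best_d2 = np.full((px, px), np.inf)
    r2 = spec.cell_radius_um ** 2
    for c, (cx, cy) in enumerate(truth.centroids_um):
        d2 = (x_um - cx) ** 2 + (y_um - cy) ** 2
        claim = (d2 <= r2) & (d2 < best_d2)
        label[claim] = c + 1
        best_d2[claim] = d2[claim]
    present = np.unique(label[label > 0])
    if present.size != truth.n_cells:
        raise ValueError("some cells rendered with zero pixels; increase px")

    clean = render_traces(truth, include_noise=False)
    n_frames = spec.n_frames
    frames = np.full((n_frames, px, px), float(background))
    for c in range(truth.n_cells):
        mask = label == c + 1
        frames[:, mask] = clean.values[c][:, None]
    if spec.noise_sd > 0:
        rng = _substream(spec.seed, 4)
        frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)
    movie = Movie(frames=frames, frame_rate_hz=spec.frame_rate_hz,
                  pixel_size_um=pixel_size)
    rois = ROISet.from_label_image(label, pixel_size)
    return movie, rois


# ---------------------------------------------------------------------------
# Recovery scoring against ground truth
# ---------------------------------------------------------------------------

def score_event_recovery(events, truth: GroundTruth, tol_frames: int = 2,
                         censor_end_frames: int = 4) -> dict[str, float]:
    """Match detected events to ground-truth onsets and score recovery.

    Greedy one-to-one matching per cell: a detected event matches the nearest
    unmatched true onset with |detected onset - true onset| <= tol_frames.
    True onsets within ``censor_end_frames`` of the end of the recording are
    censored (no detector can resolve an event whose minimal support is cut
    off). Returns recall, precision, spurious fraction (unmatched detections /
    true events) and the mean absolute onset error of matched events.
    """
    n_true = n_det = n_matched = 0
    horizon = truth.spec.n_frames - censor_end_frames
    abs_errors: list[int] = []
    for c in range(truth.n_cells):
        true_onsets = [t for t in truth.event_onsets[c] if t < horizon]
        det_onsets = list(events.onsets_for(c))
        n_true += len(true_onsets)
        n_det += len(det_onsets)
        used = [False] * len(true_onsets)
        for d in det_onsets:
            best, best_err = -1, tol_frames + 1
            for k, to in enumerate(true_onsets):
                if not used[k] and abs(d - to) < best_err:
                    best, best_err = k, abs(d - to)
            if best >= 0:
                used[best] = True
                n_matched += 1
                abs_errors.append(best_err)
    recall = n_matched / n_true if n_true else float("nan")
    precision = n_matched / n_det if n_det else float("nan")
    spurious = (n_det - n_matched) / n_true if n_true else float("nan")
    return {
        "n_true": float(n_true),
        "n_detected": float(n_det),
        "recall": recall,
        "precision": precision,
        "spurious_fraction": spurious,
        "onset_mae_frames": float(np.mean(abs_errors)) if abs_errors else float("nan"),
    }


def score_edge_recovery(graph, truth: GroundTruth,
                        lag_tol_frames: int = 1) -> dict[str, float]:
    """Score recovered directed edges against the ground-truth edge list.

    Precision / recall over directed (source, target) pairs; among recovered
    true edges, the fraction whose inferred lag is within ``lag_tol_frames``
    of the simulated delay.
    """
    true_delays = {(s, t): d for s, t, d in truth.edges}
    recovered = [(u, v, data) for u, v, data in graph.edges(data=True)
                 if data.get("directed", True)]
    n_rec = len(recovered)
    hits = 0
    lag_ok = 0
    for u, v, data in recovered:
        if (u, v) in true_delays:
            hits += 1
            if abs(abs(data["lag_frames"]) - true_delays[(u, v)]) <= lag_tol_frames:
                lag_ok += 1
    n_true = len(true_delays)
    return {
        "n_true_edges": float(n_true),
        "n_recovered_edges": float(n_rec),
        "precision": hits / n_rec if n_rec else float("nan"),
        "recall": hits / n_true if n_true else float("nan"),
        "lag_accuracy": lag_ok / hits if hits else float("nan"),
    }


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    """JSON dump of the spec echo, centroids, edges and event onsets."""
    payload = {
        "spec": {k: getattr(truth.spec, k) for k in truth.spec.__dataclass_fields__},
        "centroids_um": truth.centroids_um.tolist(),
        "edges": [[s, t, d] for s, t, d in truth.edges],
        "event_onsets": [o.tolist() for o in truth.event_onsets],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def spec_with(spec: SyntheticSpec, **overrides) -> SyntheticSpec:
    """Convenience wrapper around dataclasses.replace."""
    return replace(spec, **overrides)
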