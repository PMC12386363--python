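# calnetdyn

Network calcium-dynamics analysis for neuron–glial and astrocytic cultures.

Time-lapse calcium imaging of primary cultures (e.g. OGB-1–loaded hippocampal
or monoastrocytic cultures recorded at 2 Hz over a 639 × 639 µm field) yields
one fluorescence trace per cell. `calnetdyn` turns those movies (or trace
tables) into the quantities used to compare treatment groups in such
experiments:

- **calcium events** per cell — onset, duration, frequency, and the fraction
  of active cells — detected with an adaptive dual **exponential-moving-average
  (EMA)** threshold;
- **functional connectivity** — best lagged Pearson correlation between
  detrended cell signals within a ±5 s window; pairs above a threshold of 0.3
  are functionally connected;
- a **directed network graph** — when the correlation peaks at a significant
  temporal delay, the edge runs from the leading to the lagging cell;
- **calcium-wave propagation speed** — centroid distance divided by lag time,
  summarized per recording;
- **group statistics** — median [Q1; Q3] summaries and Kruskal–Wallis
  comparisons across treatment groups, with Dunn–Holm pairwise tests as an
  extension.

A first-class synthetic-data module simulates cultures with known ground truth
(event trains, directed couplings with geometry-consistent delays, rendered
movies), so every stage of the pipeline is validated end to end without any
recorded data.

## The model in brief

The signal of cell *k* is the mean fluorescence over its ROI,
F_k(t) = mean over ROI pixels of the frame at t. A **calcium event** is a
maximal run of frames where F_k exceeds both EMAs of itself,

    y[t] = α x[t] + (1 − α) y[t−1],   α = 1 − exp(−1 / (τ f)),

with a fast (τ = 10 s) and a slow (τ = 60 s) time constant. Because both
references shift and scale with the signal, detection is insensitive to
baseline level and gain. Candidate runs shorter than 2 s or with peak excess
below 3 robust noise SDs are discarded.

For connectivity each trace is detrended by its slow EMA and scaled by its
noise SD; for every cell pair the Pearson correlation is maximized over
integer lags ℓ ∈ [−L, L] (L = 5 s × frame rate). Adjacency is `best r > 0.3`;
a lag |ℓ| ≥ 1 frame orients the edge, and the per-edge speed is
d(i,j) / (|ℓ| / f). Group comparisons use Kruskal–Wallis H on midranks with
tie correction (χ², k − 1 df), reporting median ± IQR.

## Worked example

```python
from calnetdyn import (neuron_like, generate_network, render_traces,
                       detect_events, activity_metrics, functional_connections,
                       build_graph, propagation_speed, score_edge_recovery)

spec = neuron_like(n_cells=30, edge_density=0.1, transmission_prob=0.9,
                   event_rate_per_min=2.0, seed=1)
truth = generate_network(spec)          # ground-truth network + event trains
traces = render_traces(truth)           # 30 cells x 2400 frames at 2 Hz

events = detect_events(traces)
act = activity_metrics(events)
res = functional_connections(traces)
graph = build_graph(res, truth.centroids_um)
speed = propagation_speed(graph)
score = score_edge_recovery(graph, truth)
```

Printed for this seed:

```
cells: 30, true couplings: 18
active fraction: 1.00
event frequency: 2.10 per min (median cell)
event duration: 4.5 s (median)
functional connections per cell: 1.33
directed edges: 20
propagation speed: 51.7 [48.9; 57.0] um/s
edge precision/recall vs ground truth: 0.90/1.00
```

Every cell is active; the detected event frequency matches the simulated
2/min; the median propagation speed recovers the simulated 50 µm/s within a
few percent; and 90% of inferred directed edges are true couplings.

The same analysis runs from the shell:

```bash
calnetdyn simulate --out sim/ --preset neuron --seed 1 --movie-px 256
calnetdyn analyze  --out run/ --movie sim/movie.tif --rois sim/rois.tif
calnetdyn experiment --config experiment.yaml --out exp/ --seed 1
```

`analyze` writes traces/events/edges CSVs, a correlation matrix, a GraphML
graph, per-recording metrics JSON, and a manifest with config echo and
checksums.

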