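# Methods

This note documents the models, parameter defaults, numerical choices, and
benchmark design behind `calnetdyn`, and states what the synthetic validation
does and does not demonstrate about real recordings.

## Signals and event detection

The per-cell signal is the arithmetic mean of fluorescence over the cell's ROI
in each frame (0-based frames; time t = frame / frame rate; centroids reported
as (x, y) = (col, row) × pixel size). Movies may be denoised first: the default
is a separable spatiotemporal Gaussian (σ = 1 frame temporally, `strength`
pixels spatially, bounded by the input range); frame-wise BM3D is dispatched to
the optional `bm3d` package when installed. The noise scale of a trace is
estimated robustly from temporal first differences, σ̂ = 1.4826·MAD(Δx)/√2,
which ignores sparse transients and any additive baseline.

A calcium event is a maximal run of frames on which the signal exceeds **both**
causal EMAs of itself (conjunction; the disjunction is strictly looser and
admits noise crossings). EMAs use α = 1 − exp(−1/(τf)), initialized at the
first sample; the first τ_slow seconds are flagged burn-in, and events ending
inside burn-in are marked but kept. Defaults and rationale:

| parameter | default | why |
|---|---|---|
| τ_fast | 10 s | follows event onsets but smooths frame noise |
| τ_slow | 60 s | tracks drift, not 15–20 s astrocytic transients |
| min duration | 2 s | 4 frames at 2 Hz; drops noise runs |
| min amplitude | 3 σ̂ | peak excess over the slow EMA |
| threshold margin | 0 σ̂ | crossings at the EMAs themselves |
| mask pre-smoothing | 0.375 s Gaussian | see below |
| min separation | 5 s | drops decay-tail re-crossings |

Two guards were added after quantitative failure analysis on ground-truth
simulations. (1) The threshold *mask* is computed on a lightly smoothed copy
of the trace (Gaussian σ = 0.375 s, i.e. below one frame at 2 Hz) while σ̂ and
the amplitude filter stay anchored to the raw trace; this mirrors the
denoise-before-analysis ordering of the acquisition pipeline and removes
single-frame noise dips that otherwise fragment onsets. (2) A surviving
candidate starting less than 5 s after the previous event's offset is treated
as a re-crossing of the decaying transient tail and discarded; without it,
long astrocytic transients generate ~4× more spurious "events" than real ones.
Events are never merged; boundaries are the crossings themselves, with no
sub-frame interpolation. Adding any constant to a trace, or scaling it by a
positive factor, leaves the detected intervals identical (EMAs, σ̂ and the
margin all transform together).

Activity metrics per recording: active fraction (cells with ≥ 1 event / all
cells), per-cell events/min, per-event durations, summarized as median [Q1; Q3]
(type-7 linear-interpolation quantiles). Panel-style normalization divides each
sample by the median of a reference (control) group.

## Connectivity, directed graph, propagation speed

Traces are preprocessed as (x − EMA_slow(x)) / σ̂: baseline- and
gain-invariant, high-passed above the τ_slow scale. Note the one-pole EMA
high-pass attenuates slowly: a sinusoid of period 10 τ_slow retains ≈ 53% of
its amplitude; ≥ 80% attenuation requires periods ≳ 30 τ_slow. Zero-variance
traces are flagged unusable and excluded from pair statistics (never silently
dropped).

For each unordered pair the Pearson correlation is evaluated at every integer
lag in ±round(5 s × f) on the truncated overlap (no wrap-around, which would
manufacture alignment); the maximum and its signed lag are kept, ties broken
toward smaller |lag| then toward the negative lag. The n×n computation is
vectorized (one standardized matrix product per lag) and agrees with the
scalar per-pair routine to 1e-10; the scalar routine is itself checked against
a brute-force oracle in the tests. Adjacency is `best r > 0.3` (strict). Pairs
with |lag| ≥ 1 frame (0.5 s at 2 Hz — the default reading of a "significant
temporal delay") become one directed edge from leader to lagger carrying
speed = centroid distance / (|lag|/f); zero-lag pairs are kept as reciprocal
edges flagged undirected and excluded from speed summaries. Per-recording
panel values: mean best-lag correlation over all usable pairs and over
neighbor pairs; connections per cell (adjacency row sums); median [Q1; Q3]
edge speed (undefined, not an error, for zero directed edges).

Neighbor pairs ("directly contacting" cells) use the minimum
boundary-to-boundary ROI distance ≤ 5 µm, computed from boundary pixels via
KD-trees; without a label image a centroid fallback (distance ≤ 2·radius + gap)
is used.

## Synthetic cultures and ground truth

The generator emulates the statistical structure the analysis assumes, with
every random draw taken from fixed substreams of one seed (placement/edges,
per-cell spontaneous trains, cascade transmission, per-cell drift phase and
noise, pixel noise), so all outputs are bit-reproducible.

- **Geometry.** n cells placed uniformly in a square field (default 639 µm)
  with minimum separation two cell radii (8 µm radius); sizing errors are
  raised when the field cannot hold the requested cells.
- **Couplings.** Directed edges are sampled among *local* ordered pairs
  (≤ 200 µm, the scale of gap-junction/wave coupling; note that with a ±5 s
  lag window and 50 µm/s waves, couplings beyond ~250 µm are invisible to the
  connectivity definition itself). `edge_density` is the fraction of eligible
  ordered pairs. Edges are oriented along a random topological order (acyclic)
  and constrained to a depth-1 feed-forward layer (driver → follower;
  in-degree ≤ 1, out-degree ≤ 2 by default). Delay = round(distance/speed × f),
  at least 1 frame.
- **Event trains.** Spontaneous onsets follow a dead-time renewal process:
  interval = refractory + Exp(mean gap − refractory), which realizes the
  nominal mean rate exactly while keeping events sparse and quasi-periodic.
  The refractory default is rise + 2·decay (a cell cannot re-initiate during
  its own transient). Each accepted event propagates along each outgoing edge
  with probability `transmission_prob`, creating a child onset at
  onset + delay; a cell ignores arrivals during its refractory interval, and
  accepted events per cell are capped at 10 × max(1, spontaneous count).
- **Traces.** baseline 1 + drift·sin(2πt/period + φ) + Σ kernels + N(0, σ²),
  kernel (1 − e^(−t/rise)) e^(−t/decay) normalized to peak `amplitude`
  (analytic peak at rise·ln(1 + decay/rise)). Defaults: amplitude 0.25,
  noise 0.05 (5 σ), drift 0.02 with period 300 s. Presets: *astro-like*
  (rise 3 s, decay 8 s → full width near 15–20 s) and *neuron-like*
  (rise 0.5 s, decay 2 s), both 1 event/min by default.
- **Movies.** Cells drawn as filled disks whose pixels follow the noiseless
  trace, plus per-pixel Gaussian noise and a constant background; the matching
  label image is emitted, and noiseless movies round-trip through trace
  extraction to 1e-9.

### Benchmark conditions and why

The ground-truth topology is deliberately *identifiable*: scratch analysis
showed that with transmission 0.9, transitive correlations through chains
(A→B→C) and siblings (B←A→C) reach r ≈ 0.31–0.40 — above the 0.3 threshold —
while edges converging on multi-parent hubs dilute below it. A pairwise
correlation-threshold rule cannot, even in principle, separate those motifs
from true couplings. The depth-1 feed-forward layer (think pacemaker/driver
cells initiating waves into followers) removes that ambiguity, so benchmark
scores measure the pipeline's correctness rather than the intrinsic limits of
correlation networks. The cascade machinery itself is general (any DAG,
multi-hop) and unit-tested with explicit truths.

Two benchmark regimes are fixed:

- **Event recovery** — astro kinetics, 20 independent cells, 2400 frames at
  2 Hz, amplitude 5 σ, onset spacing ≥ 40 s (termination-to-onset gaps ≥ 3
  decay times). Scoring censors true onsets in the final 4 frames, whose
  minimal support is cut off. Typical results: recall ≈ 0.96–0.97 at ±2-frame
  onset tolerance, spurious ≈ 3–4%.
- **Network recovery** — neuron kinetics at 2 events/min (refractory 3 s),
  30 cells, edge density 0.1, transmission 0.9, 50 µm/s. Sharp transients make
  the cross-correlogram peak land on the true delay essentially always; slow
  astro kernels in the same topology leave correlation margins straddling the
  0.3 threshold and lag estimates smeared by refractory censoring. Typical
  results: precision ≈ 0.9–1.0, recall ≈ 0.92–1.0, lag accuracy ≈ 1.0, median
  speed within a few percent of 50 µm/s.

The statistics layer is calibrated under the null with three i.i.d. groups of
n = 9 (three cultures × three fields): empirical rejection ≈ 0.045–0.048 at
α = 0.05, and a 2× event-rate difference is detected in essentially every
simulated experiment.

### What passing these benchmarks does not show

The simulator omits photobleaching, motion, overlapping or moving ROIs,
subcellular (microdomain) events, biophysical IP₃/ER calcium dynamics,
reverberating/cyclic coupling, and network bursts with global synchrony. Real
recordings containing those features can degrade every stage — most acutely
the directionality inference, which assumes acyclic, lag-consistent coupling.
The paper-style group medians from real cultures are not reproducible here
because the recordings are not public; all quantitative claims are therefore
about recovery of simulated ground truth under the stated conditions.

## Statistical layer

Kruskal–Wallis H is computed on midranks with tie correction (scipy), p from
the χ² approximation with k − 1 df; an all-identical sample is defined as
H = 0, p = 1. The experimental unit is one field of view. Dunn's pairwise
z-tests on pooled midranks with Holm adjustment are provided as an extension
(the omnibus decision comes from H). Quantiles everywhere are type-7
(linear interpolation) — IQRs differ across conventions, so this is stated
explicitly.

## Pipeline and determinism

Configs are versioned YAML validated by pydantic with unknown keys rejected
(silent typos corrupt analyses). A run writes traces, centroids, events,
metrics, correlation/lag matrices, edge list, scattergram, GraphML, and a
manifest (config echo, package version, SHA-256 of inputs and outputs,
timestamps). Identical config + seed reproduce byte-identical stage outputs;
only manifest timestamps differ. Stage failures abort with the stage name.
The CLI (`calnetdyn simulate | analyze | report | experiment`) is a thin layer
over these library calls.
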