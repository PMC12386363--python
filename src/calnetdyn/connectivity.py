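"""Lag-aware functional connectivity, directed network graphs, and propagation speed.

Pairwise coupling is the maximum Pearson correlation between two processed
traces over all integer lags within +/- max_lag_s (default 5 s). Traces are
first detrended by their slow EMA and scaled by their robust noise sd, which
makes every downstream quantity invariant to additive baseline shifts and to
positive rescaling of the raw fluorescence. Pairs whose best-lag correlation
exceeds the threshold (default 0.3) are functionally connected; a connection
whose maximum occurs at a nonzero lag becomes a directed edge from the leading
to the lagging cell, carrying a propagation speed = centroid distance / lag
time.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .filters import ema, robust_noise_sd
from .imaging_io import ROISet, TraceMatrix

__all__ = [
    "ConnectivityParams",
    "ConnectivityResult",
    "preprocess_for_corr",
    "lagged_correlation",
    "functional_connections",
    "neighbor_pairs",
    "neighbor_mask_from_centroids",
    "build_graph",
    "propagation_speed",
    "SpeedSummary",
    "scattergram",
]


@dataclass(frozen=True)
class ConnectivityParams:
    """Connectivity thresholds and windows.

    corr_threshold: minimum best-lag correlation for a functional connection
    (strict inequality). max_lag_s: half-width of the lag search window.
    neighbor_gap_um: maximum boundary-to-boundary distance for "directly
    contacting" cells. min_directed_lag_frames: smallest |lag| treated as a
    significant temporal delay (edges below it are reciprocal, undirected).
    tau_slow_s: EMA time constant of the detrending baseline.
    """

    corr_threshold: float = 0.3
    max_lag_s: float = 5.0
    neighbor_gap_um: float = 5.0
    min_directed_lag_frames: int = 1
    tau_slow_s: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 < self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must be in (0, 1]")
        if self.max_lag_s <= 0:
            raise ValueError("max_lag_s must be > 0")
        if self.neighbor_gap_um < 0:
            raise ValueError("neighbor_gap_um must be >= 0")
        if self.min_directed_lag_frames < 0:
            raise ValueError("min_directed_lag_frames must be >= 0")

    def max_lag_frames(self, frame_rate_hz: float) -> int:
        return int(round(self.max_lag_s * frame_rate_hz))


@dataclass
class ProcessedTraces:
    """Detrended, noise-normalized traces plus a usability mask."""

    values: np.ndarray
    frame_rate_hz: float
    centroids_um: np.ndarray | None
    usable: np.ndarray  # bool per cell; zero-variance traces excluded, reported

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def preprocess_for_corr(traces: TraceMatrix, tau_slow_s: float = 60.0) -> ProcessedTraces:
    """Replace each trace by (x - slow EMA of x) / robust noise sd.

    The slow EMA removes baseline level and slow drift; dividing by the noise
    sd removes the gain, so any affine transform a*x + b (a > 0) of a raw
    trace yields the identical processed trace. Traces with zero noise sd or
    zero residual variance are flagged unusable rather than silently dropped.
    """
    x = traces.values
    resid = x - ema(x, tau_slow_s, traces.frame_rate_hz)
    sd = np.atleast_1d(robust_noise_sd(x))
    usable = (sd > 0) & (resid.std(axis=1) > 0)
    values = np.where(usable[:, None], resid / np.where(sd[:, None] == 0, 1.0, sd[:, None]),
                      resid)
    return ProcessedTraces(values=values, frame_rate_hz=traces.frame_rate_hz,
                           centroids_um=traces.centroids_um, usable=usable)


def _lag_order(max_lag: int) -> list[int]:
    """Tie-break order: smaller |lag| first, then negative before positive."""
    return sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l))


def lagged_correlation(a: np.ndarray, b: np.ndarray,
                       max_lag_frames: int) -> tuple[float, int]:
    """Best Pearson correlation of b against a over integer lags in [-L, +L].

    A positive returned lag means b follows a by that many frames; the
    correlation at lag l >= 0 is computed on the truncated overlap
    (a[0:T-l], b[l:T]) with no wrap-around. Ties go to the smaller |lag|,
    then to the negative lag. Lags with zero variance in the overlap are
    skipped; if every lag is skipped the result is (nan, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1-D and equally long")
    t = a.size
    if t < 2 * max_lag_frames + 2:
        raise ValueError(
            f"traces of length {t} too short for max lag {max_lag_frames}"
        )
    best_corr = -np.inf
    best_lag = 0
    for lag in _lag_order(max_lag_frames):
        if lag >= 0:
            seg_a, seg_b = a[: t - lag], b[lag:]
        else:
            seg_a, seg_b = a[-lag:], b[: t + lag]
        if seg_a.std() == 0 or seg_b.std() == 0:
            continue
        r = float(np.corrcoef(seg_a, seg_b)[0, 1])
        if r > best_corr:
            best_corr, best_lag = r, lag
    if not np.isfinite(best_corr):
        return float("nan"), 0
    return best_corr, best_lag


@dataclass
class ConnectivityResult:
    """Best-lag correlation structure of one recording."""

    corr: np.ndarray                 # (n, n) best-lag correlation, nan diagonal
    lag_frames: np.ndarray           # (n, n) signed lag of j relative to i
    adjacency: np.ndarray            # bool, corr > threshold
    neighbor_mask: np.ndarray | None
    connections_per_cell: np.ndarray
    mean_corr_all: float
    mean_corr_neighbor: float
    usable: np.ndarray
    params: ConnectivityParams
    frame_rate_hz: float

    @property
    def n_cells(self) -> int:
        return self.corr.shape[0]

    @property
    def n_connections(self) -> int:
        return int(self.adjacency.sum() // 2)


def _corr_matrices_by_lag(v: np.ndarray, max_lag: int) -> dict[int, np.ndarray]:
    """Full pairwise Pearson matrices for each lag l in 0..L.

    M(l)[i, j] = corr(x_i[0:T-l], x_j[l:T]) ("j follows i by l"); the matrix
    for -l is M(l).T. Zero-variance overlap segments yield nan entries.
    """
    n, t = v.shape
    out: dict[int, np.ndarray] = {}
    for lag in range(max_lag + 1):
        a = v[:, : t - lag]
        b = v[:, lag:]
        a_c = a - a.mean(axis=1, keepdims=True)
        b_c = b - b.mean(axis=1, keepdims=True)
        a_sd = a_c.std(axis=1)
        b_sd = b_c.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            a_z = a_c / a_sd[:, None]
            b_z = b_c / b_sd[:, None]
        m = (a_z @ b_z.T) / (t - lag)
        m[a_sd == 0, :] = np.nan
        m[:, b_sd == 0] = np.nan
        out[lag] = m
    return out


def functional_connections(traces: TraceMatrix,
                           params: ConnectivityParams | None = None,
                           rois: ROISet | None = None,
                           neighbor_mask: np.ndarray | None = None) -> ConnectivityResult:
    """Evaluate every unordered cell pair with the best-lag correlation.

    Pairs whose best correlation strictly exceeds ``corr_threshold`` are
    functionally connected; ``connections_per_cell`` are the adjacency row
    sums. Also reports the mean best-lag correlation over all usable pairs and
    over neighboring pairs (from ``rois`` or an explicit ``neighbor_mask``).
    """
    if params is None:
        params = ConnectivityParams()
    proc = preprocess_for_corr(traces, params.tau_slow_s)
    n = proc.n_cells
    if int(proc.usable.sum()) < 2:
        raise ValueError("need at least 2 usable cells for connectivity")
    max_lag = params.max_lag_frames(traces.frame_rate_hz)
    if proc.n_frames < 2 * max_lag + 2:
        raise ValueError("recording too short for the requested lag window")

    mats = _corr_matrices_by_lag(proc.values, max_lag)
    corr = np.full((n, n), -np.inf)
    lags = np.zeros((n, n), dtype=int)
    iu, ju = np.triu_indices(n, k=1)
    for lag in _lag_order(max_lag):
        m = mats[lag] if lag >= 0 else mats[-lag].T
        vals = m[iu, ju]
        better = np.where(np.isnan(vals), -np.inf, vals) > corr[iu, ju]
        corr[iu[better], ju[better]] = vals[better]
        lags[iu[better], ju[better]] = lag
    corr[ju, iu] = corr[iu, ju]
    lags[ju, iu] = -lags[iu, ju]
    corr[~np.isfinite(corr)] = np.nan
    bad = ~proc.usable
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, np.nan)
    np.fill_diagonal(lags, 0)

    with np.errstate(invalid="ignore"):
        adjacency = np.where(np.isnan(corr), False, corr > params.corr_threshold)

    if neighbor_mask is None and rois is not None:
        neighbor_mask = neighbor_pairs(rois, params)

    pair_corr = corr[iu, ju]
    mean_all = float(np.nanmean(pair_corr)) if np.any(np.isfinite(pair_corr)) else float("nan")
    if neighbor_mask is not None:
        nb = neighbor_mask[iu, ju] & np.isfinite(pair_corr)
        mean_nb = float(np.mean(pair_corr[nb])) if np.any(nb) else float("nan")
    else:
        mean_nb = float("nan")

    return ConnectivityResult(
        corr=corr, lag_frames=lags, adjacency=adjacency, neighbor_mask=neighbor_mask,
        connections_per_cell=adjacency.sum(axis=1).astype(int),
        mean_corr_all=mean_all, mean_corr_neighbor=mean_nb,
        usable=proc.usable, params=params, frame_rate_hz=traces.frame_rate_hz,
    )


def neighbor_pairs(rois: ROISet, params: ConnectivityParams | None = None) -> np.ndarray:
    """Boolean matrix of directly contacting ROI pairs.

    Two cells are neighbors when the minimum boundary-to-boundary distance
    between their ROIs is at most ``neighbor_gap_um``. Symmetric, irreflexive.
    """
    if params is None:
        params = ConnectivityParams()
    lab = rois.label_image
    n = rois.n_cells
    px = rois.pixel_size_um
    boundaries = []
    for k in range(1, n + 1):
        mask = lab == k
        inner = ndimage.binary_erosion(mask)
        coords = np.argwhere(mask & ~inner)
        if coords.size == 0:  # ROI thinner than 2 px everywhere
            coords = np.argwhere(mask)
        boundaries.append(coords * px)
    trees = [cKDTree(b) for b in boundaries]
    out = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = trees[i].query(boundaries[j], k=1)
            if float(np.min(d)) <= params.neighbor_gap_um:
                out[i, j] = out[j, i] = True
    return out


def neighbor_mask_from_centroids(centroids_um: np.ndarray, cell_radius_um: float = 8.0,
                                 gap_um: float = 5.0) -> np.ndarray:
    """Neighbor mask for circular somata of known radius (no label image needed).

    Disk boundaries are within ``gap_um`` when centroid distance is at most
    2 * radius + gap.
    """
    c = np.asarray(centroids_um, dtype=float)
    diff = c[:, None, :] - c[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    out = dist <= (2.0 * cell_radius_um + gap_um)
    np.fill_diagonal(out, False)
    return out


def build_graph(result: ConnectivityResult, centroids_um: np.ndarray,
                params: ConnectivityParams | None = None,
                frame_rate_hz: float | None = None) -> nx.DiGraph:
    """Directed functional network from the connectivity result.

    For each connected pair with |lag| >= min_directed_lag_frames, one edge
    runs from the leading to the lagging cell with attributes corr, lag_frames
    (positive, in the edge direction), distance_um, and speed_um_s =
    distance / (|lag| / frame_rate). Pairs with |lag| below the minimum keep
    two reciprocal edges flagged ``directed=False`` with no speed.
    """
    if params is None:
        params = result.params
    if frame_rate_hz is None:
        frame_rate_hz = result.frame_rate_hz
    centroids = np.asarray(centroids_um, dtype=float)
    n = result.n_cells
    g = nx.DiGraph()
    for i in range(n):
        g.add_node(i, x_um=float(centroids[i, 0]), y_um=float(centroids[i, 1]))
    for i in range(n):
        for j in range(i + 1, n):
            if not result.adjacency[i, j]:
                continue
            lag = int(result.lag_frames[i, j])  # j relative to i
            corr = float(result.corr[i, j])
            dist = float(np.hypot(*(centroids[i] - centroids[j])))
            if abs(lag) >= params.min_directed_lag_frames and lag != 0:
                src, tgt = (i, j) if lag > 0 else (j, i)
                speed = dist / (abs(lag) / frame_rate_hz)
                g.add_edge(src, tgt, corr=corr, lag_frames=abs(lag),
                           distance_um=dist, speed_um_s=speed, directed=True)
            else:
                for src, tgt in ((i, j), (j, i)):
                    g.add_edge(src, tgt, corr=corr, lag_frames=abs(lag),
                               distance_um=dist, speed_um_s=float("nan"),
                               directed=False)
    return g


@dataclass
class SpeedSummary:
    """Median and IQR of per-edge propagation speeds (um/s)."""

    n_edges: int
    median: float
    q1: float
    q3: float

    @property
    def defined(self) -> bool:
        return self.n_edges > 0


def propagation_speed(graph: nx.DiGraph) -> SpeedSummary:
    """Summarize per-edge speeds of directed edges; undefined when none exist."""
    speeds = np.array([d["speed_um_s"] for _, _, d in graph.edges(data=True)
                       if d.get("directed", False)])
    if speeds.size == 0:
        return SpeedSummary(n_edges=0, median=float("nan"), q1=float("nan"),
                            q3=float("nan"))
    q1, med, q3 = np.quantile(speeds, [0.25, 0.5, 0.75])
    return SpeedSummary(n_edges=int(speeds.size), median=float(med),
                        q1=float(q1), q3=float(q3))


def scattergram(result: ConnectivityResult, centroids_um: np.ndarray) -> pd.DataFrame:
    """Pair-level table (distance, best-lag corr, neighbor flag, connected flag)."""
    c = np.asarray(centroids_um, dtype=float)
    n = result.n_cells
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append({
                "cell_i": i,
                "cell_j": j,
                "distance_um": float(np.hypot(*(c[i] - c[j]))),
                "corr": float(result.corr[i, j]),
                "lag_frames": int(result.lag_frames[i, j]),
                "neighbor": bool(result.neighbor_mask[i, j])
                if result.neighbor_mask is not None else False,
                "connected": bool(result.adjacency[i, j]),
            })
    return pd.DataFrame(rows)
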