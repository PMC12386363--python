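"""Calcium event detection with a dual exponential-moving-average adaptive threshold.

A calcium event is a maximal run of frames on which the cell's signal exceeds
both a fast and a slow causal EMA of itself. Because both reference curves
shift with any additive offset and scale with any positive gain, detection is
insensitive to the baseline fluorescence level and to the overall signal
scale; only relative excursions matter. Candidate runs shorter than a minimum
duration, or whose peak excess over the slow EMA is below a multiple of the
robust noise sd, are discarded as noise crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .filters import ema, robust_noise_sd
from .imaging_io import TraceMatrix

__all__ = [
    "EventParams",
    "EventTable",
    "ActivityMetrics",
    "detect_events",
    "activity_metrics",
    "normalize_to_reference",
    "ema",
]


@dataclass(frozen=True)
class EventParams:
    """Detection parameters.

    tau_fast_s / tau_slow_s
        Time constants of the two EMAs. The slow EMA (60 s) tracks baseline
        drift but not 15-20 s transients; the fast EMA (10 s) suppresses frame
        noise while following event onsets.
    min_duration_s
        Candidate runs shorter than this are discarded (default 2 s).
    min_amplitude_sd
        Minimum peak excess over the slow EMA, in units of the robust noise sd
        (default 3).
    threshold_margin_sd
        Additive margin above both EMAs, in noise-sd units, that the signal
        must clear (default 0). The margin scales with the noise estimate, so
        any nonzero value still preserves baseline and scale invariance.
    smooth_s
        Gaussian sd (seconds) of a light temporal pre-filter applied before
        thresholding (default 0.375 s, i.e. below one frame at 2 Hz). The
        noise sd used by the amplitude filter is always measured on the raw
        trace, so thresholds stay anchored to the sensor noise. Mirrors the
        denoise-before-analysis order of the acquisition pipeline.
    min_separation_s
        A surviving candidate starting less than this after the previous kept
        event's offset is treated as a re-crossing of the decaying transient
        tail and discarded (default 5 s).
    """

    tau_fast_s: float = 10.0
    tau_slow_s: float = 60.0
    min_duration_s: float = 2.0
    min_amplitude_sd: float = 3.0
    threshold_margin_sd: float = 0.0
    smooth_s: float = 0.375
    min_separation_s: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_fast_s < self.tau_slow_s:
            raise ValueError("need 0 < tau_fast_s < tau_slow_s")
        for name in ("min_duration_s", "min_amplitude_sd", "threshold_margin_sd",
                     "smooth_s", "min_separation_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


_EVENT_COLUMNS = ["cell", "onset_frame", "offset_frame", "duration_s",
                  "peak_excess", "in_burnin"]


@dataclass
class EventTable:
    """Detected events as half-open frame intervals [onset, offset) per cell."""

    df: pd.DataFrame
    n_cells: int
    n_frames: int
    frame_rate_hz: float

    def __post_init__(self) -> None:
        missing = [c for c in _EVENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")

    @property
    def n_events(self) -> int:
        return len(self.df)

    def onsets_for(self, cell: int) -> np.ndarray:
        sub = self.df[self.df["cell"] == cell]
        return sub["onset_frame"].to_numpy(dtype=int)

    def events_for(self, cell: int) -> pd.DataFrame:
        return self.df[self.df["cell"] == cell].reset_index(drop=True)

    def counts_per_cell(self) -> np.ndarray:
        counts = np.zeros(self.n_cells, dtype=int)
        for c, n in self.df["cell"].value_counts().items():
            counts[int(c)] = int(n)
        return counts


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open [start, stop) intervals."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_events(traces: TraceMatrix, params: EventParams | None = None) -> EventTable:
    """Detect per-cell calcium events by the dual-EMA adaptive threshold.

    A frame is "above" when the raw signal exceeds both EMAs (plus the noise
    margin); maximal above-runs become candidate events; short or low-amplitude
    candidates are dropped. Adjacent surviving events are never merged. Events
    ending inside the first ``tau_slow_s`` seconds (EMA burn-in) are flagged
    ``in_burnin`` but kept.
    """
    if params is None:
        params = EventParams()
    rate = traces.frame_rate_hz
    min_frames = max(1, int(np.ceil(params.min_duration_s * rate)))
    burnin_end = int(round(params.tau_slow_s * rate))
    rows: list[tuple] = []
    for c in range(traces.n_cells):
        x = traces.values[c]
        # light pre-smoothing for the threshold mask; noise anchor stays raw
        if params.smooth_s > 0:
            xs = ndimage.gaussian_filter1d(x, params.smooth_s * rate)
        else:
            xs = x
        fast = ema(xs, params.tau_fast_s, rate)
        slow = ema(xs, params.tau_slow_s, rate)
        sigma = float(robust_noise_sd(x))
        margin = params.threshold_margin_sd * sigma
        above = (xs > fast + margin) & (xs > slow + margin)
        last_offset = -np.inf
        for start, stop in _runs_above(above):
            if stop - start < min_frames:
                continue
            peak_excess = float(np.max(xs[start:stop] - slow[start:stop]))
            if sigma > 0 and peak_excess < params.min_amplitude_sd * sigma:
                continue
            if (start - last_offset) / rate < params.min_separation_s:
                continue
            last_offset = stop
            rows.append((c, int(start), int(stop), (stop - start) / rate,
                         peak_excess, bool(stop <= burnin_end)))
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    if df.empty:
        df = df.astype({"cell": int, "onset_frame": int, "offset_frame": int,
                        "duration_s": float, "peak_excess": float, "in_burnin": bool})
    return EventTable(df=df, n_cells=traces.n_cells, n_frames=traces.n_frames,
                      frame_rate_hz=rate)


@dataclass
class ActivityMetrics:
    """Per-recording activity summary (one culture field of view)."""

    active_fraction: float
    events_per_min: np.ndarray        # per cell
    durations_s: np.ndarray           # per event
    n_cells: int
    duration_min: float

    @property
    def median_events_per_min(self) -> float:
        return float(np.median(self.events_per_min))

    @property
    def median_duration_s(self) -> float:
        return float(np.median(self.durations_s)) if self.durations_s.size else float("nan")


def activity_metrics(events: EventTable, n_cells: int | None = None,
                     duration_s: float | None = None) -> ActivityMetrics:
    """Active-cell fraction, per-cell event frequency, and event durations.

    active_fraction = cells with at least one event / total cells;
    events_per_min = per-cell event count / recording duration in minutes.
    """
    n_cells = events.n_cells if n_cells is None else int(n_cells)
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    duration_s = events.n_frames / events.frame_rate_hz if duration_s is None else duration_s
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    counts = np.zeros(n_cells, dtype=int)
    for c, n in events.df["cell"].value_counts().items():
        counts[int(c)] = int(n)
    duration_min = duration_s / 60.0
    return ActivityMetrics(
        active_fraction=float(np.count_nonzero(counts) / n_cells),
        events_per_min=counts / duration_min,
        durations_s=events.df["duration_s"].to_numpy(dtype=float),
        n_cells=n_cells,
        duration_min=duration_min,
    )


def normalize_to_reference(samples, reference) -> np.ndarray:
    """Divide each sample by the median of the reference group's samples."""
    samples = np.asarray(samples, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("reference group is empty")
    ref_median = float(np.median(reference))
    if ref_median == 0:
        raise ValueError("reference group has zero median; cannot normalize")
    return samples / ref_median
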