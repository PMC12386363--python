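"""End-to-end orchestration: simulate -> extract -> detect -> connect -> report.

A single recording runs through the full stack and leaves a reproducible trail
of stage outputs (traces CSV, events CSV, metrics JSON, connectivity CSVs,
GraphML) plus a manifest with the config echo, software version, input
checksums and per-stage file hashes. A multi-group experiment repeats this per
recording and feeds the per-recording metric table to the Kruskal-Wallis layer.
Everything is deterministic under a fixed config and seed (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .connectivity import (ConnectivityParams, build_graph, functional_connections,
                           neighbor_mask_from_centroids, neighbor_pairs,
                           propagation_speed, scattergram)
from .events import EventParams, activity_metrics, detect_events, normalize_to_reference
from .group_stats import compare_metric_table
from .imaging_io import (ROISet, TraceMatrix, denoise, extract_traces,
                         read_label_image, read_movie, read_traces_csv,
                         write_traces_csv)
from .synthetic import (SyntheticSpec, generate_network, render_movie,
                        render_traces, write_ground_truth)

__all__ = [
    "AcquisitionConfig",
    "DenoiseConfig",
    "EventConfig",
    "ConnectivityConfig",
    "PipelineConfig",
    "RunManifest",
    "PipelineError",
    "analyze_traces",
    "run_analysis",
    "run_experiment",
    "simulate_recording",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "active_fraction",
    "events_per_min",
    "event_duration_s",
    "corr_all_pairs",
    "corr_neighbors",
    "connections_per_cell",
    "propagation_speed_um_s",
)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionConfig(_StrictModel):
    frame_rate_hz: float = 2.0
    pixel_size_um: float = 639.0 / 512.0


class DenoiseConfig(_StrictModel):
    method: Literal["none", "gaussian-spatiotemporal", "bm3d-framewise"] = "none"
    strength: float | None = None


class EventConfig(_StrictModel):
    tau_fast_s: float = 10.0
    tau_slow_s: float = 60.0
    min_duration_s: float = 2.0
    min_amplitude_sd: float = 3.0
    threshold_margin_sd: float = 0.0
    smooth_s: float = 0.375
    min_separation_s: float = 5.0

    def to_params(self) -> EventParams:
        return EventParams(**self.model_dump())


class ConnectivityConfig(_StrictModel):
    corr_threshold: float = 0.3
    max_lag_s: float = 5.0
    neighbor_gap_um: float = 5.0
    min_directed_lag_frames: int = 1
    tau_slow_s: float = 60.0

    def to_params(self) -> ConnectivityParams:
        return ConnectivityParams(**self.model_dump())


class PipelineConfig(_StrictModel):
    """Versioned pipeline configuration; unknown keys are rejected."""

    schema_version: int = 1
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    denoise: DenoiseConfig = Field(default_factory=DenoiseConfig)
    events: EventConfig = Field(default_factory=EventConfig)
    connectivity: ConnectivityConfig = Field(default_factory=ConnectivityConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(data or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


@dataclasses.dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    inputs: dict[str, str]          # path -> sha256
    outputs: dict[str, str]         # stage name -> path
    output_checksums: dict[str, str]
    started_utc: str
    finished_utc: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclasses.dataclass
class RecordingResult:
    """In-memory results of one analyzed recording."""

    traces: TraceMatrix
    events: object
    activity: object
    connectivity: object
    graph: nx.DiGraph
    speeds: object
    metrics: dict[str, float]


def analyze_traces(traces: TraceMatrix,
                   event_params: EventParams | None = None,
                   conn_params: ConnectivityParams | None = None,
                   rois: ROISet | None = None,
                   neighbor_mask: np.ndarray | None = None,
                   cell_radius_um: float = 8.0) -> RecordingResult:
    """Core per-recording analysis shared by the file pipeline and simulations.

    When no ROI label image is available, neighbor pairs fall back to the
    centroid rule (boundary gap for disks of ``cell_radius_um``).
    """
    conn_params = conn_params or ConnectivityParams()
    events = detect_events(traces, event_params)
    activity = activity_metrics(events)
    if neighbor_mask is None:
        if rois is not None:
            neighbor_mask = neighbor_pairs(rois, conn_params)
        elif traces.centroids_um is not None:
            neighbor_mask = neighbor_mask_from_centroids(
                traces.centroids_um, cell_radius_um, conn_params.neighbor_gap_um)
    conn = functional_connections(traces, conn_params, neighbor_mask=neighbor_mask)
    if traces.centroids_um is None:
        raise PipelineError("stage 'connect' failed: traces carry no centroids")
    graph = build_graph(conn, traces.centroids_um, conn_params, traces.frame_rate_hz)
    speeds = propagation_speed(graph)
    metrics = {
        "active_fraction": activity.active_fraction,
        "events_per_min": activity.median_events_per_min,
        "event_duration_s": activity.median_duration_s,
        "corr_all_pairs": conn.mean_corr_all,
        "corr_neighbors": conn.mean_corr_neighbor,
        "connections_per_cell": float(np.mean(conn.connections_per_cell)),
        "propagation_speed_um_s": speeds.median,
    }
    return RecordingResult(traces=traces, events=events, activity=activity,
                           connectivity=conn, graph=graph, speeds=speeds,
                           metrics=metrics)


def _write_recording_outputs(out: Path, res: RecordingResult) -> dict[str, str]:
    paths: dict[str, str] = {}

    def add(name: str, p: Path) -> None:
        paths[name] = str(p)

    write_traces_csv(out / "traces.csv", res.traces, out / "centroids.csv")
    add("traces", out / "traces.csv")
    add("centroids", out / "centroids.csv")
    res.events.df.to_csv(out / "events.csv", index=False, float_format="%.9g")
    add("events", out / "events.csv")
    (out / "metrics.json").write_text(json.dumps(
        {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
         for k, v in res.metrics.items()}, indent=1, sort_keys=True))
    add("metrics", out / "metrics.json")
    n = res.connectivity.n_cells
    pd.DataFrame(res.connectivity.corr).to_csv(out / "corr_matrix.csv",
                                               index=False, float_format="%.9g")
    add("corr_matrix", out / "corr_matrix.csv")
    pd.DataFrame(res.connectivity.lag_frames).to_csv(out / "lag_matrix.csv", index=False)
    add("lag_matrix", out / "lag_matrix.csv")
    edges = [
        {"source": u, "target": v, "corr": d["corr"], "lag_frames": d["lag_frames"],
         "distance_um": d["distance_um"], "speed_um_s": d["speed_um_s"],
         "directed": d["directed"]}
        for u, v, d in res.graph.edges(data=True)
    ]
    pd.DataFrame(edges, columns=["source", "target", "corr", "lag_frames",
                                 "distance_um", "speed_um_s", "directed"]).to_csv(
        out / "edges.csv", index=False, float_format="%.9g")
    add("edges", out / "edges.csv")
    sc = scattergram(res.connectivity, res.traces.centroids_um)
    sc.to_csv(out / "scattergram.csv", index=False, float_format="%.9g")
    add("scattergram", out / "scattergram.csv")
    g = nx.DiGraph()
    g.add_nodes_from((n_, {k: float(v) for k, v in d.items()})
                     for n_, d in res.graph.nodes(data=True))
    for u, v, d in res.graph.edges(data=True):
        g.add_edge(u, v, **{k: (float(v_) if isinstance(v_, (int, float, np.floating))
                                else bool(v_)) for k, v_ in d.items()})
    nx.write_graphml(g, out / "graph.graphml")
    add("graphml", out / "graph.graphml")
    return paths


def run_analysis(config: PipelineConfig, out_dir: str | Path,
                 movie_path: str | Path | None = None,
                 roi_path: str | Path | None = None,
                 traces_path: str | Path | None = None,
                 centroids_path: str | Path | None = None) -> RunManifest:
    """Run the full analysis for one recording from files on disk.

    Either a movie + ROI label image, or a traces CSV (+ centroids CSV) must be
    given. Missing inputs and invalid configs raise before any computation;
    any stage failure aborts with the stage name.
    """
    started = datetime.now(timezone.utc).isoformat()
    out = Path(out_dir)
    inputs: dict[str, str] = {}
    for p in (movie_path, roi_path, traces_path, centroids_path):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"missing input file: {p}")
    if movie_path is None and traces_path is None:
        raise ValueError("need either movie_path + roi_path or traces_path")
    if movie_path is not None and roi_path is None:
        raise ValueError("movie input requires an ROI label image (roi_path)")
    out.mkdir(parents=True, exist_ok=True)
    for p in (movie_path, roi_path, traces_path, centroids_path):
        if p is not None:
            inputs[str(p)] = _sha256(Path(p))

    rois = None
    if movie_path is not None:
        try:
            movie = read_movie(movie_path, config.acquisition.frame_rate_hz,
                               config.acquisition.pixel_size_um)
            rois = ROISet.from_label_image(read_label_image(roi_path),
                                           config.acquisition.pixel_size_um)
        except Exception as exc:
            raise PipelineError(f"stage 'read' failed: {exc}") from exc
        try:
            movie = denoise(movie, config.denoise.method, config.denoise.strength)
        except Exception as exc:
            raise PipelineError(f"stage 'denoise' failed: {exc}") from exc
        try:
            traces = extract_traces(movie, rois)
        except Exception as exc:
            raise PipelineError(f"stage 'extract' failed: {exc}") from exc
    else:
        try:
            traces = read_traces_csv(traces_path, config.acquisition.frame_rate_hz,
                                     centroids_path)
        except Exception as exc:
            raise PipelineError(f"stage 'read' failed: {exc}") from exc

    try:
        res = analyze_traces(traces, config.events.to_params(),
                             config.connectivity.to_params(), rois=rois)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'analyze' failed: {exc}") from exc

    try:
        outputs = _write_recording_outputs(out, res)
    except Exception as exc:
        raise PipelineError(f"stage 'write' failed: {exc}") from exc

    checksums = {name: _sha256(Path(p)) for name, p in outputs.items()}
    manifest = RunManifest(
        config=config.model_dump(), version=__version__, inputs=inputs,
        outputs=outputs, output_checksums=checksums,
        started_utc=started, finished_utc=datetime.now(timezone.utc).isoformat(),
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def simulate_recording(spec: SyntheticSpec, out_dir: str | Path | None = None,
                       render_movie_px: int | None = None):
    """Generate one synthetic recording; optionally write simulator outputs."""
    truth = generate_network(spec)
    traces = render_traces(truth)
    movie = rois = None
    if render_movie_px is not None:
        movie, rois = render_movie(truth, px=render_movie_px)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_traces_csv(out / "traces.csv", traces, out / "centroids.csv")
        pd.DataFrame([(s, t, d) for s, t, d in truth.edges],
                     columns=["source", "target", "delay_frames"]).to_csv(
            out / "true_edges.csv", index=False)
        write_ground_truth(out / "ground_truth.json", truth)
        if movie is not None:
            from .imaging_io import write_label_image, write_movie

            write_movie(out / "movie.tif", movie, dtype="float32")
            write_label_image(out / "rois.tif", rois.label_image)
    return truth, traces, movie, rois


def run_experiment(group_specs: Mapping[str, Sequence[SyntheticSpec]] | None = None,
                   metric_table: pd.DataFrame | None = None,
                   reference_group: str | None = None,
                   event_params: EventParams | None = None,
                   conn_params: ConnectivityParams | None = None,
                   alpha: float = 0.05,
                   out_dir: str | Path | None = None) -> dict:
    """Multi-group experiment: per-recording metrics + Kruskal-Wallis comparisons.

    Either ``group_specs`` (label -> list of synthetic recording specs, each
    analyzed end to end) or a precomputed tidy ``metric_table`` with columns
    (group, recording, metric, value) must be provided. Active fraction and
    event frequency additionally get variants normalized to the reference
    group's median (the first group by default).
    """
    if (group_specs is None) == (metric_table is None):
        raise ValueError("provide exactly one of group_specs or metric_table")
    if group_specs is not None:
        if len(group_specs) < 2:
            raise ValueError("an experiment needs at least 2 groups")
        rows = []
        for label, specs in group_specs.items():
            if len(specs) == 0:
                raise ValueError(f"group {label!r} has zero recordings")
            for k, spec in enumerate(specs):
                _, traces, _, _ = simulate_recording(spec)
                res = analyze_traces(traces, event_params, conn_params,
                                     cell_radius_um=spec.cell_radius_um)
                for m in METRIC_NAMES:
                    rows.append({"group": label, "recording": f"{label}_{k}",
                                 "metric": m, "value": res.metrics[m]})
        metric_table = pd.DataFrame(rows)
    else:
        required = {"group", "recording", "metric", "value"}
        if not required.issubset(metric_table.columns):
            raise ValueError(f"metric_table must have columns {sorted(required)}")
        if metric_table["group"].nunique() < 2:
            raise ValueError("an experiment needs at least 2 groups")

    groups = list(dict.fromkeys(metric_table["group"]))
    reference_group = reference_group or groups[0]

    # normalized variants of the panel metrics reported relative to control
    extra_rows = []
    for m in ("active_fraction", "events_per_min"):
        sub = metric_table[metric_table["metric"] == m]
        ref = sub[sub["group"] == reference_group]["value"].to_numpy()
        if ref.size and np.median(ref) != 0:
            for _, r in sub.iterrows():
                extra_rows.append({
                    "group": r["group"], "recording": r["recording"],
                    "metric": f"{m}_norm",
                    "value": float(normalize_to_reference([r["value"]], ref)[0]),
                })
    table = pd.concat([metric_table, pd.DataFrame(extra_rows)], ignore_index=True)

    comparisons = compare_metric_table(table, alpha=alpha, posthoc=True)
    comp_rows = []
    for c in comparisons:
        row = {"metric": c.metric_name, "H": c.h_statistic, "p_value": c.p_value,
               "significant": c.significant}
        for gname, s in c.summaries.items():
            row[f"{gname}_median_iqr"] = s.formatted(3)
        comp_rows.append(row)
    comp_table = pd.DataFrame(comp_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metric_samples.csv", index=False, float_format="%.9g")
        comp_table.to_csv(out / "comparisons.csv", index=False, float_format="%.9g")
        (out / "comparisons.json").write_text(json.dumps(
            comp_rows, indent=1, sort_keys=True, default=str))
    return {"metric_table": table, "comparisons": comparisons,
            "comparison_table": comp_table, "reference_group": reference_group}
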