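"""Movie / ROI input-output, denoising, and per-cell mean-fluorescence trace extraction.

The cell signal is defined as the arithmetic mean of the fluorescence intensity
over every pixel belonging to the cell's ROI, one value per frame. ROIs arrive
as an integer label image (0 = background, k > 0 = cell k); segmentation itself
is out of scope. Coordinates: pixels are (row, col), 0-based; centroids are
reported as (x, y) = (col, row) * pixel_size_um; time t = frame / frame_rate_hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .filters import robust_noise_sd

__all__ = [
    "Movie",
    "ROISet",
    "TraceMatrix",
    "read_movie",
    "write_movie",
    "read_label_image",
    "write_label_image",
    "denoise",
    "estimate_movie_noise_sd",
    "extract_traces",
    "read_traces_csv",
    "write_traces_csv",
    "write_traces_h5",
    "read_traces_h5",
]

DENOISE_METHODS = ("none", "gaussian-spatiotemporal", "bm3d-framewise")


@dataclass
class Movie:
    """A time-lapse fluorescence stack (T x H x W) with acquisition metadata."""

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"movie must be a T x H x W stack, got shape {self.frames.shape}"
            )
        t, h, w = self.frames.shape
        if t < 2:
            raise ValueError(f"movie needs at least 2 frames, got {t}")
        if h < 8 or w < 8:
            raise ValueError(f"movie frames must be at least 8 x 8 px, got {h} x {w}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class ROISet:
    """Cell regions as an integer label image with derived centroids and areas.

    Labels must be consecutive 1..n; centroids are (x, y) in micrometres.
    """

    label_image: np.ndarray
    pixel_size_um: float
    centroids_um: np.ndarray = field(init=False)
    areas_px: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.label_image)
        if lab.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("label image must have an integer dtype")
        if lab.min() < 0:
            raise ValueError("label image must be non-negative")
        n = int(lab.max())
        if n < 1:
            raise ValueError("label image contains no cells")
        counts = np.bincount(lab.ravel(), minlength=n + 1)[1:]
        missing = np.nonzero(counts == 0)[0] + 1
        if missing.size:
            raise ValueError(
                f"labels must be consecutive 1..n; missing labels: {missing.tolist()}"
            )
        small = np.nonzero(counts < 4)[0] + 1
        if small.size:
            raise ValueError(f"ROIs smaller than 4 px: labels {small.tolist()}")
        # centre of mass in (row, col) -> report (x, y) = (col, row) * pixel size
        com = ndimage.center_of_mass(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        com = np.asarray(com, dtype=float)
        self.label_image = lab
        self.centroids_um = com[:, ::-1] * self.pixel_size_um
        self.areas_px = counts.astype(np.int64)

    @classmethod
    def from_label_image(cls, label_image: np.ndarray, pixel_size_um: float) -> "ROISet":
        return cls(label_image=label_image, pixel_size_um=pixel_size_um)

    @property
    def n_cells(self) -> int:
        return int(self.areas_px.shape[0])


@dataclass
class TraceMatrix:
    """Per-cell mean-fluorescence time series (cells x frames)."""

    values: np.ndarray
    frame_rate_hz: float
    centroids_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trace matrix must be 2-D (cells x frames)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace matrix contains non-finite values")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.centroids_um is not None:
            self.centroids_um = np.asarray(self.centroids_um, dtype=float)
            if self.centroids_um.shape != (self.values.shape[0], 2):
                raise ValueError("centroids_um must have shape (n_cells, 2)")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def read_movie(path: str | Path, frame_rate_hz: float, pixel_size_um: float) -> Movie:
    """Read a multi-page grayscale TIFF stack in acquisition order.

    Frame rate and pixel size come from the caller (acquisition config); TIFF
    metadata is not trusted.
    """
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        raise ValueError(f"{path}: single-page TIFF; a movie needs at least 2 frames")
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale T x H x W stack, got shape {arr.shape} "
            "(color or hyper-stacked TIFFs are not supported)"
        )
    return Movie(frames=arr, frame_rate_hz=frame_rate_hz, pixel_size_um=pixel_size_um)


def write_movie(path: str | Path, movie: Movie, dtype: str | None = None) -> None:
    """Write a movie as a multi-page TIFF. Float data is written as-is by default."""
    import tifffile

    frames = movie.frames if dtype is None else movie.frames.astype(dtype)
    tifffile.imwrite(str(path), frames)


def read_label_image(path: str | Path) -> np.ndarray:
    """Read an integer ROI label image from TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: label image must be 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{path}: label image must contain integers")
        arr = np.round(arr).astype(np.int32)
    return arr


def write_label_image(path: str | Path, label_image: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(label_image).astype(np.int32))


def estimate_movie_noise_sd(movie: Movie, max_pixels: int = 20000) -> float:
    """Robust sensor-noise sd from temporal first differences of pixel traces.

    Subsamples pixels for speed; the MAD-based estimator ignores transients.
    """
    t, h, w = movie.frames.shape
    n_px = h * w
    flat = movie.frames.reshape(t, n_px)
    if n_px > max_pixels:
        idx = np.linspace(0, n_px - 1, max_pixels).astype(int)
        flat = flat[:, idx]
    d = np.diff(flat.astype(float), axis=0)
    return float(np.median(np.abs(d - np.median(d))) * 1.4826 / np.sqrt(2.0))


def denoise(movie: Movie, method: str = "gaussian-spatiotemporal",
            strength: float | None = None) -> Movie:
    """Denoise a movie prior to trace extraction.

    Parameters
    ----------
    method
        ``none`` returns the input unchanged. ``gaussian-spatiotemporal``
        applies a separable 3-D Gaussian with spatial sigma = ``strength``
        pixels and temporal sigma = 1 frame. ``bm3d-framewise`` applies BM3D
        independently per frame with noise sd ``strength`` (requires the
        optional ``bm3d`` package).
    strength
        Interpretation depends on the method; when ``None`` it defaults to
        1 px for the Gaussian and to the estimated sensor noise sd for BM3D.
    """
    if method not in DENOISE_METHODS:
        raise ValueError(f"unknown denoise method {method!r}; choose from {DENOISE_METHODS}")
    if method == "none":
        return Movie(movie.frames.copy(), movie.frame_rate_hz, movie.pixel_size_um)
    if method == "gaussian-spatiotemporal":
        sigma_xy = 1.0 if strength is None else float(strength)
        out = ndimage.gaussian_filter(movie.frames.astype(float), sigma=(1.0, sigma_xy, sigma_xy))
        return Movie(out, movie.frame_rate_hz, movie.pixel_size_um)
    # bm3d-framewise
    try:
        import bm3d  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "method 'bm3d-framewise' requires the optional 'bm3d' package "
            "(pip install bm3d); 'gaussian-spatiotemporal' needs no extras"
        ) from exc
    sigma = estimate_movie_noise_sd(movie) if strength is None else float(strength)
    out = np.stack([bm3d.bm3d(f.astype(float), sigma_psd=sigma) for f in movie.frames])
    return Movie(out, movie.frame_rate_hz, movie.pixel_size_um)


def extract_traces(movie: Movie, rois: ROISet) -> TraceMatrix:
    """Mean fluorescence per ROI per frame.

    values[k, t] = mean of frame t over pixels with label k + 1.
    """
    lab = rois.label_image
    if lab.shape != movie.frames.shape[1:]:
        raise ValueError(
            f"label image shape {lab.shape} does not match movie frame shape "
            f"{movie.frames.shape[1:]}"
        )
    n = rois.n_cells
    flat = lab.ravel()
    counts = rois.areas_px.astype(float)
    t_frames = movie.n_frames
    values = np.empty((n, t_frames), dtype=float)
    for t in range(t_frames):
        sums = np.bincount(flat, weights=movie.frames[t].ravel().astype(float),
                           minlength=n + 1)
        values[:, t] = sums[1:] / counts
    return TraceMatrix(values=values, frame_rate_hz=movie.frame_rate_hz,
                       centroids_um=rois.centroids_um.copy())


def _cell_columns(n: int) -> list[str]:
    return [f"cell_{k + 1:03d}" for k in range(n)]


def write_traces_csv(path: str | Path, traces: TraceMatrix,
                     centroids_path: str | Path | None = None) -> None:
    """Write traces as CSV (rows = frames, columns = cells); centroids sidecar optional."""
    df = pd.DataFrame(traces.values.T, columns=_cell_columns(traces.n_cells))
    df.insert(0, "frame", np.arange(traces.n_frames))
    df.to_csv(path, index=False, float_format="%.9g")
    if centroids_path is not None and traces.centroids_um is not None:
        cdf = pd.DataFrame({
            "cell_id": _cell_columns(traces.n_cells),
            "x_um": traces.centroids_um[:, 0],
            "y_um": traces.centroids_um[:, 1],
        })
        cdf.to_csv(centroids_path, index=False, float_format="%.9g")


def read_traces_csv(path: str | Path, frame_rate_hz: float,
                    centroids_path: str | Path | None = None) -> TraceMatrix:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("cell_")]
    if not cols:
        raise ValueError(f"{path}: no 'cell_*' columns found")
    centroids = None
    if centroids_path is not None:
        cdf = pd.read_csv(centroids_path)
        centroids = cdf[["x_um", "y_um"]].to_numpy(dtype=float)
    return TraceMatrix(values=df[cols].to_numpy(dtype=float).T,
                       frame_rate_hz=frame_rate_hz, centroids_um=centroids)


def write_traces_h5(path: str | Path, traces: TraceMatrix) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=traces.values)
        f.attrs["frame_rate_hz"] = traces.frame_rate_hz
        if traces.centroids_um is not None:
            f.create_dataset("centroids_um", data=traces.centroids_um)


def read_traces_h5(path: str | Path) -> TraceMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        values = f["traces"][()]
        rate = float(f.attrs["frame_rate_hz"])
        centroids = f["centroids_um"][()] if "centroids_um" in f else None
    return TraceMatrix(values=values, frame_rate_hz=rate, centroids_um=centroids)


def trace_noise_sd(traces: TraceMatrix) -> np.ndarray:
    """Per-cell robust noise sd of the extracted traces."""
    return np.atleast_1d(robust_noise_sd(traces.values))


# dataclasses helper re-export used by pipeline manifests
def as_dict(obj) -> dict:
    return dataclasses.asdict(obj)
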