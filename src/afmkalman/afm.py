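"""HS-AFM specialization of the linear dynamical system.

High-speed AFM acquires one pixel height per time tick while the probe
raster-scans the stage, so a "frame" is assembled from measurements taken at
k different times.  This module fixes the measurement schedule (raster scan,
x fastest, always left to right), the one-hot measurement operator, the
spatially correlated Gaussian-kernel system noise, the identity or
one-pixel-diffusion transition matrix, and the frame assembly semantics, and
wires them into the filter/smoother drivers.

Conventions: pixel indices are 0-based and row-major with x fastest
(pixel = y * n_px + x); ticks are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
from scipy import sparse

from .lds import (
    DEFAULT_PRIOR_VARIANCE,
    GaussianBelief,
    LdsModel,
    Measurement,
    ParameterError,
    ScheduleError,
    run_filter,
    run_fixed_point_smoother,
)

__all__ = [
    "GridGeometry",
    "RasterSchedule",
    "HeightMovie",
    "MeasurementStream",
    "build_system_noise",
    "build_transition",
    "raster_pixel",
    "assemble_raw_afm",
    "build_lds_model",
    "reconstruct_movie",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridGeometry:
    """Scan grid: ``n_px`` pixels along x, ``n_py`` along y.

    ``pixel_size`` is optional physical metadata (nm per pixel edge).
    """

    n_px: int
    n_py: int
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if self.n_px < 1 or self.n_py < 1:
            raise ParameterError(f"grid must be at least 1x1, got {self.n_px}x{self.n_py}")

    @property
    def k(self) -> int:
        """Total number of pixels (state dimension)."""
        return self.n_px * self.n_py

    def pixel_index(self, x: int, y: int) -> int:
        return y * self.n_px + x

    def pixel_xy(self, index: int) -> tuple[int, int]:
        return index % self.n_px, index // self.n_px


def raster_pixel(tick: int, geometry: GridGeometry) -> int:
    """Pixel measured at a 1-based tick under the repeating raster scan.

    The probe sweeps x from 0 to n_px - 1 (always in that direction),
    advances y by one line per sweep, and restarts the frame after k ticks.
    """
    if tick < 1:
        raise ScheduleError(f"ticks are 1-based, got {tick}")
    u = (tick - 1) % geometry.k
    return u  # row-major with x fastest: index == u by construction


@dataclass(frozen=True)
class RasterSchedule:
    """The tick -> pixel mapping of the repeating raster scan."""

    geometry: GridGeometry

    def pixel_at(self, tick: int) -> int:
        return raster_pixel(tick, self.geometry)

    def frame_ticks(self, n_frames: int) -> np.ndarray:
        """Frame-end ticks k, 2k, ..., n_frames * k."""
        return self.geometry.k * np.arange(1, n_frames + 1)


@dataclass
class HeightMovie:
    """Ordered frames of 2-D height maps sharing one grid geometry.

    ``frames`` has shape (n_frames, n_py, n_px); ``frame_ticks[f]`` is the
    tick at which frame f is referenced (the frame-end tick under the raster
    protocol).  Heights are floating point in ``units``.
    """

    frames: np.ndarray
    geometry: GridGeometry
    frame_ticks: np.ndarray
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D, got shape {self.frames.shape}")
        expected = (self.geometry.n_py, self.geometry.n_px)
        if self.frames.shape[1:] != expected:
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} does not match geometry {expected}"
            )
        self.frame_ticks = np.asarray(self.frame_ticks, dtype=int).reshape(-1)
        if self.frame_ticks.shape[0] != self.frames.shape[0]:
            raise ValueError("frame_ticks length must equal the number of frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("heights must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_vector(self, f: int) -> np.ndarray:
        """Frame f stacked into a length-k state vector (x fastest)."""
        return self.frames[f].ravel()


@dataclass
class MeasurementStream:
    """Per-tick scalar height records (tick, pixel, value) plus geometry."""

    ticks: np.ndarray
    pixels: np.ndarray
    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.ticks = np.asarray(self.ticks, dtype=int).reshape(-1)
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1)
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        n = self.ticks.shape[0]
        if self.pixels.shape[0] != n or self.values.shape[0] != n:
            raise ValueError("ticks, pixels and values must have equal length")
        if n and np.any(np.diff(self.ticks) <= 0):
            raise ScheduleError("ticks must be strictly increasing")
        if n and (self.pixels.min() < 0 or self.pixels.max() >= self.geometry.k):
            raise ValueError("pixel index out of range for the grid")

    def __len__(self) -> int:
        return self.ticks.shape[0]

    def __iter__(self) -> Iterator[Measurement]:
        for t, p, v in zip(self.ticks, self.pixels, self.values):
            yield Measurement(int(t), int(p), float(v))

    def follows_raster(self) -> bool:
        """True if every record matches the repeating raster schedule."""
        expected = (self.ticks - 1) % self.geometry.k
        return bool(np.array_equal(expected, self.pixels))


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def build_system_noise(
    geometry: GridGeometry,
    q: float,
    dx_q: float = 1.0,
    dy_q: float = 1.0,
) -> np.ndarray:
    """Spatially correlated system-noise covariance Q for smooth specimens.

    Entry (r, s) for pixels r and s is
    ``q^2 exp(-(r_x - s_x)^2 / (2 dx_q^2) - (r_y - s_y)^2 / (2 dy_q^2))``:
    a separable Gaussian kernel on the grid, encoding that biomolecular
    height fields are continuous and smooth.  ``q`` sets the noise scale and
    the length scales default to one pixel.
    """
    if q < 0:
        raise ParameterError(f"q must be >= 0, got {q}")
    if dx_q <= 0 or dy_q <= 0:
        raise ParameterError(f"length scales must be > 0, got dx_q={dx_q}, dy_q={dy_q}")
    idx = np.arange(geometry.k)
    x = idx % geometry.n_px
    y = idx // geometry.n_px
    dx2 = (x[:, None] - x[None, :]) ** 2
    dy2 = (y[:, None] - y[None, :]) ** 2
    return q * q * np.exp(-dx2 / (2.0 * dx_q * dx_q) - dy2 / (2.0 * dy_q * dy_q))


def build_transition(geometry: GridGeometry, p: float) -> sparse.csr_matrix:
    """Transition matrix F: identity, or one-pixel diffusion with rate ``p``.

    ``p = 0`` gives the minimal static model F = I.  For ``p > 0`` every
    pixel sends weight p to each of its existing 4-neighbors (left, right,
    up, down) and keeps ``1 - (number of existing neighbors) * p`` on the
    diagonal, so each row sums to 1 and total height mass is conserved,
    including at the grid edges where pixels have fewer neighbors.
    Returned sparse (5 entries per row) so propagation stays O(k^2).
    """
    if not 0.0 <= p <= 0.25:
        raise ParameterError(f"diffusion probability p must be in [0, 0.25], got {p}")
    k = geometry.k
    if p == 0.0:
        return sparse.identity(k, format="csr")
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for idx in range(k):
        x, y = geometry.pixel_xy(idx)
        neighbors = []
        if x > 0:
            neighbors.append(idx - 1)
        if x < geometry.n_px - 1:
            neighbors.append(idx + 1)
        if y > 0:
            neighbors.append(idx - geometry.n_px)
        if y < geometry.n_py - 1:
            neighbors.append(idx + geometry.n_px)
        rows.append(idx)
        cols.append(idx)
        vals.append(1.0 - len(neighbors) * p)
        for nb in neighbors:
            rows.append(idx)
            cols.append(nb)
            vals.append(p)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(k, k))


def build_lds_model(
    geometry: GridGeometry,
    q: float,
    r: float = 1.0,
    p: float = 0.0,
    dx_q: float = 1.0,
    dy_q: float = 1.0,
) -> LdsModel:
    """Assemble the HS-AFM LdsModel from the scalar parameters q, r, p."""
    transition = None if p == 0.0 else build_transition(geometry, p)
    system_noise = None if q == 0.0 else build_system_noise(geometry, q, dx_q, dy_q)
    return LdsModel(
        k=geometry.k,
        transition=transition,
        system_noise=system_noise,
        meas_noise_var=r,
    )


# ---------------------------------------------------------------------------
# Frame assembly and reconstruction
# ---------------------------------------------------------------------------

def _complete_frames(stream: MeasurementStream) -> int:
    k = stream.geometry.k
    n_frames, leftover = divmod(len(stream), k)
    if leftover:
        logger.warning(
            "stream length %d is not a multiple of k=%d; dropping %d trailing ticks",
            len(stream), k, leftover,
        )
    return n_frames


def assemble_raw_afm(stream: MeasurementStream, geometry: GridGeometry) -> HeightMovie:
    """Assemble the raw AFM movie: each frame collects one scan's pixels.

    Frame f holds, at every pixel, the single value measured for that pixel
    during scan f — exactly what the instrument records, asynchronicity
    included.  Trailing partial scans are dropped.
    """
    if stream.geometry != geometry:
        raise ValueError("stream geometry does not match the requested geometry")
    if not stream.follows_raster():
        raise ScheduleError("stream does not follow the raster scan schedule")
    n_frames = _complete_frames(stream)
    k = geometry.k
    values = stream.values[: n_frames * k]
    frames = values.reshape(n_frames, geometry.n_py, geometry.n_px)
    frame_ticks = k * np.arange(1, n_frames + 1)
    return HeightMovie(frames=frames, geometry=geometry, frame_ticks=frame_ticks)


def reconstruct_movie(
    stream: MeasurementStream,
    geometry: GridGeometry,
    q: float,
    r: float = 1.0,
    p: float = 0.0,
    method: Literal["raw", "filter", "smoother"] = "smoother",
    lookahead: int | None = None,
    init_mean: np.ndarray | None = None,
    init_var: float = DEFAULT_PRIOR_VARIANCE,
) -> HeightMovie:
    """Reconstruct a height movie from a raster measurement stream.

    ``filter`` snapshots the filtered image at each frame-end tick k, 2k, ...
    (the estimate of the state given that scan and all earlier ones);
    ``smoother`` reports the fixed-point smoothed image at each frame-end
    tick using one further scan of measurements (lookahead defaults to k),
    so an N-frame stream yields N - 1 smoothed frames; ``raw`` assembles the
    measurements as the instrument would.
    """
    if method == "raw":
        return assemble_raw_afm(stream, geometry)
    if method not in ("filter", "smoother"):
        raise ParameterError(f"unknown method {method!r}")
    if stream.geometry != geometry:
        raise ValueError("stream geometry does not match the requested geometry")
    if not stream.follows_raster():
        raise ScheduleError("stream does not follow the raster scan schedule")
    n_frames = _complete_frames(stream)
    k = geometry.k
    model = build_lds_model(geometry, q=q, r=r, p=p)
    init = None
    if init_mean is not None or init_var != DEFAULT_PRIOR_VARIANCE:
        mean = np.zeros(k) if init_mean is None else np.asarray(init_mean, float)
        init = GaussianBelief(mean, init_var * np.eye(k))
    frame_end = [k * f for f in range(1, n_frames + 1)]
    stream_list = list(stream)[: n_frames * k]
    if method == "filter":
        snapshots = run_filter(stream_list, model, init=init, snapshot_ticks=frame_end)
        ticks = frame_end
        vectors = [snapshots[t].mean for t in ticks]
    else:
        look = k if lookahead is None else int(lookahead)
        smoothed = run_fixed_point_smoother(
            stream_list, model, init=init, fixed_ticks=frame_end, lookahead=look
        )
        ticks = sorted(smoothed)
        vectors = [smoothed[t] for t in ticks]
    frames = np.stack(vectors).reshape(len(ticks), geometry.n_py, geometry.n_px)
    return HeightMovie(frames=frames, geometry=geometry, frame_ticks=np.asarray(ticks))
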