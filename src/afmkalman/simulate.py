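"""Diffusing-cone twin experiment.

A circular cone of known geometry performs a random walk on the scan stage
while a virtual raster probe samples one pixel height per tick.  Because the
ground truth is known exactly, reconstructions can be scored against it —
the standard twin-experiment validation of a data-assimilation method.

Default conditions: 10 x 10 pixel stage, cone base radius 3 px and height 3
(arbitrary height units), 10,000 ticks (100 frames), per-tick vertex moves
drawn uniformly from s * [-1, 1] per axis with s = 0.1, and i.i.d. Gaussian
measurement noise of standard deviation 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

from .afm import (
    GridGeometry,
    HeightMovie,
    MeasurementStream,
    assemble_raw_afm,
    raster_pixel,
    reconstruct_movie,
)
from .lds import ParameterError
from .metrics import EvaluationReport, evaluate_movie

__all__ = [
    "ConeSpec",
    "WalkConfig",
    "simulate_walk",
    "cone_height_at",
    "render_truth_movie",
    "synthesize_measurements",
    "vertex_diagnostics",
    "make_twin_data",
    "run_twin_experiment",
]


@dataclass(frozen=True)
class ConeSpec:
    """A linear circular cone: height at distance d from the vertex is
    ``height * max(0, 1 - d / base_radius)``."""

    base_radius: float = 3.0
    height: float = 3.0
    vertex: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.base_radius <= 0 or self.height <= 0:
            raise ParameterError("cone base_radius and height must be > 0")


@dataclass(frozen=True)
class WalkConfig:
    """Conditions of the diffusing-cone twin experiment.

    ``scale`` is the random-walk step scale s: per tick, the vertex moves
    independently in x and y by draws from Uniform(-s, s), clamped to the
    observation area.  s = 1, 0.1, 0.01 correspond to fast, default, and
    slow diffusion relative to the scan time.
    """

    geometry: GridGeometry = GridGeometry(10, 10)
    cone: ConeSpec = ConeSpec()
    n_ticks: int = 10_000
    scale: float = 0.1
    noise_sd: float = 0.3
    seed: int = 0
    boundary: Literal["clamp", "reflect"] = "clamp"

    def __post_init__(self) -> None:
        if self.n_ticks < self.geometry.k:
            raise ParameterError("n_ticks must cover at least one full scan")
        if self.scale < 0:
            raise ParameterError(f"scale must be >= 0, got {self.scale}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _bound_inside(pos: np.ndarray, hi_x: float, hi_y: float, mode: str) -> np.ndarray:
    """Keep a (..., 2) position inside [0, hi_x] x [0, hi_y]."""
    if mode == "clamp":
        return np.clip(pos, [0.0, 0.0], [hi_x, hi_y])
    if mode == "reflect":
        out = pos.copy()
        for axis, hi in enumerate((hi_x, hi_y)):
            v = np.mod(out[..., axis], 2.0 * hi)
            out[..., axis] = np.where(v > hi, 2.0 * hi - v, v)
        return out
    raise ParameterError(f"unknown boundary mode {mode!r}")


def simulate_walk(config: WalkConfig) -> np.ndarray:
    """Random walk of the cone vertex: (n_ticks, 2) positions in pixel units.

    The walk starts at the stage center; each step adds independent
    Uniform(-s, s) increments in x and y, bound inside the observation area
    [0, n_px - 1] x [0, n_py - 1].  Deterministic given the seed; the walk
    consumes the generator before any measurement noise is drawn.
    """
    rng = np.random.default_rng(config.seed)
    hi_x = float(config.geometry.n_px - 1)
    hi_y = float(config.geometry.n_py - 1)
    steps = rng.uniform(-config.scale, config.scale, size=(config.n_ticks, 2))
    positions = np.empty((config.n_ticks, 2))
    pos = np.array([hi_x / 2.0, hi_y / 2.0])
    for t in range(config.n_ticks):
        pos = _bound_inside(pos + steps[t], hi_x, hi_y, config.boundary)
        positions[t] = pos
    return positions


def cone_height_at(spec: ConeSpec, point: tuple[float, float]) -> float:
    """Cone height at one (x, y) point, for the vertex stored in ``spec``."""
    return float(_cone_field(spec, np.asarray(spec.vertex, float),
                             np.asarray(point, float)[None, :])[0])


def _cone_field(spec: ConeSpec, vertex: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Vectorized cone heights at (n, 2) points for a given vertex."""
    d = np.hypot(points[..., 0] - vertex[0], points[..., 1] - vertex[1])
    return spec.height * np.clip(1.0 - d / spec.base_radius, 0.0, None)


def _pixel_centers(geometry: GridGeometry) -> np.ndarray:
    """(k, 2) representative points of all pixels: the pixel centers, at
    integer coordinates, ordered with x fastest."""
    idx = np.arange(geometry.k)
    return np.stack([idx % geometry.n_px, idx // geometry.n_px], axis=1).astype(float)


def render_truth_movie(trajectory: np.ndarray, config: WalkConfig) -> HeightMovie:
    """Ground-truth movie: the full cone height field at each frame-end tick.

    Frame f records the heights of every pixel simultaneously, evaluated at
    the vertex position of tick f*k — the synchronous image an instrument
    can never record.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    geom = config.geometry
    k = geom.k
    n_frames, leftover = divmod(trajectory.shape[0], k)
    if leftover:
        raise ParameterError("trajectory length must be a multiple of k")
    centers = _pixel_centers(geom)
    frames = np.empty((n_frames, geom.n_py, geom.n_px))
    for f in range(n_frames):
        vertex = trajectory[(f + 1) * k - 1]
        frames[f] = _cone_field(config.cone, vertex, centers).reshape(geom.n_py, geom.n_px)
    return HeightMovie(
        frames=frames,
        geometry=geom,
        frame_ticks=k * np.arange(1, n_frames + 1),
    )


def synthesize_measurements(trajectory: np.ndarray, config: WalkConfig) -> MeasurementStream:
    """Raster-scan measurement stream from a vertex trajectory.

    At tick t the probe reads the cone height at the center of the raster
    pixel of t, for the vertex position of tick t, plus Gaussian noise of
    standard deviation ``noise_sd``.  Noise is drawn from the same seeded
    generator as the walk, after the walk (fixed draw order for
    reproducibility), so truth and measurements come from one seed.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    geom = config.geometry
    n_ticks = trajectory.shape[0]
    if n_ticks < geom.k:
        raise ParameterError("trajectory must cover at least one full scan")
    ticks = np.arange(1, n_ticks + 1)
    pixels = (ticks - 1) % geom.k
    centers = _pixel_centers(geom)[pixels]
    d = np.hypot(centers[:, 0] - trajectory[:, 0], centers[:, 1] - trajectory[:, 1])
    clean = config.cone.height * np.clip(1.0 - d / config.cone.base_radius, 0.0, None)
    rng = np.random.default_rng(config.seed)
    rng.uniform(-config.scale, config.scale, size=(config.n_ticks, 2))  # walk draws
    noise = rng.normal(0.0, config.noise_sd, size=n_ticks) if config.noise_sd > 0 else 0.0
    return MeasurementStream(
        ticks=ticks, pixels=pixels, values=clean + noise, geometry=geom
    )


def vertex_diagnostics(
    trajectory: np.ndarray, geometry: GridGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame peak pixel and inter-frame travel distance.

    Returns ``(peak_pixels, travel)``: ``peak_pixels`` is the (n_frames, 2)
    integer (x, y) pixel containing the vertex at each frame-end tick;
    ``travel`` is the (n_frames - 1,) Euclidean distance, in pixel-edge
    units, between consecutive frame-end vertex positions.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    k = geometry.k
    n_frames, leftover = divmod(trajectory.shape[0], k)
    if leftover:
        raise ParameterError("trajectory length must be a multiple of k")
    ends = trajectory[k * np.arange(1, n_frames + 1) - 1]
    peak = np.rint(ends).astype(int)
    peak[:, 0] = np.clip(peak[:, 0], 0, geometry.n_px - 1)
    peak[:, 1] = np.clip(peak[:, 1], 0, geometry.n_py - 1)
    travel = np.hypot(*(np.diff(ends, axis=0).T))
    return peak, travel


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def make_twin_data(config: WalkConfig) -> tuple[HeightMovie, MeasurementStream]:
    """Ground-truth movie and noisy measurement stream for one experiment."""
    trajectory = simulate_walk(config)
    truth = render_truth_movie(trajectory, config)
    stream = synthesize_measurements(trajectory, config)
    return truth, stream


def run_twin_experiment(
    config: WalkConfig,
    q: float = 0.1,
    r: float = 1.0,
    methods: tuple[str, ...] = ("raw", "filter", "smoother"),
) -> dict[str, EvaluationReport]:
    """Full twin experiment: simulate, reconstruct, score against truth.

    Each requested method is evaluated by the uncentered correlation
    coefficient per frame against the ground-truth movie, restricted to the
    frames all methods share (the smoother cannot produce the final frame,
    so with the defaults 99 of 100 frames are scored).
    """
    truth, stream = make_twin_data(config)
    movies = {
        m: reconstruct_movie(stream, config.geometry, q=q, r=r, method=m)
        for m in methods
    }
    common = set(truth.frame_ticks)
    for movie in movies.values():
        common &= set(movie.frame_ticks)
    if not common:
        raise ValueError("no common frames across methods")
    return {m: evaluate_movie(movie, truth, ticks=sorted(common))
            for m, movie in movies.items()}
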