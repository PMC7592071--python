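"""Reconstruction quality metrics.

The similarity score used throughout is the uncentered (cosine-type)
correlation coefficient between two height maps,

    c.c. = sum_p H_p^truth H_p^image
           / sqrt(sum_p (H_p^truth)^2) / sqrt(sum_p (H_p^image)^2),

with no mean subtraction — for nonnegative height fields it lies in [0, 1]
and equals 1 only for proportional images.  Negative reconstructed heights
(possible in Kalman estimates) enter as-is; the form is well defined for
signed values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .afm import HeightMovie

__all__ = [
    "ZeroNormError",
    "EvaluationReport",
    "correlation_coefficient",
    "evaluate_movie",
]


class ZeroNormError(ValueError):
    """An image with all-zero norm makes the correlation undefined."""


@dataclass(frozen=True)
class EvaluationReport:
    """Per-frame correlation series and its summary statistics.

    ``sd_cc`` is the standard deviation of the per-frame values;
    ``sem_cc = sd_cc / sqrt(frames_used)`` is also provided since error bars
    on a mean are sometimes reported as the standard error.
    """

    per_frame_cc: np.ndarray
    frame_ticks: np.ndarray

    @property
    def frames_used(self) -> int:
        return self.per_frame_cc.shape[0]

    @property
    def mean_cc(self) -> float:
        return float(np.mean(self.per_frame_cc))

    @property
    def sd_cc(self) -> float:
        return float(np.std(self.per_frame_cc, ddof=0))

    @property
    def sem_cc(self) -> float:
        return self.sd_cc / np.sqrt(self.frames_used)

    def to_rows(self) -> list[tuple[int, float]]:
        """(frame tick, c.c.) rows for tabular output."""
        return [(int(t), float(c)) for t, c in zip(self.frame_ticks, self.per_frame_cc)]


def correlation_coefficient(truth: np.ndarray, image: np.ndarray) -> float:
    """Uncentered correlation between two equally shaped height maps.

    Raises :class:`ZeroNormError` if either input is identically zero
    (the metric is undefined, not silently zero).
    """
    truth = np.asarray(truth, dtype=float)
    image = np.asarray(image, dtype=float)
    if truth.shape != image.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {image.shape}")
    norm_t = np.linalg.norm(truth)
    norm_i = np.linalg.norm(image)
    if norm_t == 0.0 or norm_i == 0.0:
        raise ZeroNormError("correlation undefined for an all-zero image")
    return float(np.vdot(truth, image) / (norm_t * norm_i))


def evaluate_movie(
    reconstruction: "HeightMovie",
    truth: "HeightMovie",
    ticks: Sequence[int] | None = None,
) -> EvaluationReport:
    """Score a reconstructed movie against the ground truth frame by frame.

    Frames are paired by their frame-end tick; frames present in only one
    movie (e.g. the final frame the smoother cannot produce) are excluded.
    ``ticks`` optionally restricts the comparison further, so several
    methods can be scored on one common frame set.
    """
    if reconstruction.geometry != truth.geometry:
        raise ValueError("movies have different grid geometries")
    common = sorted(set(reconstruction.frame_ticks) & set(truth.frame_ticks))
    if ticks is not None:
        requested = sorted(set(int(t) for t in ticks))
        missing = set(requested) - set(common)
        if missing:
            raise ValueError(f"requested ticks absent from both movies: {sorted(missing)}")
        common = requested
    if not common:
        raise ValueError("no common frames to compare")
    rec_by_tick = {int(t): f for t, f in zip(reconstruction.frame_ticks, reconstruction.frames)}
    truth_by_tick = {int(t): f for t, f in zip(truth.frame_ticks, truth.frames)}
    cc = np.array([
        correlation_coefficient(truth_by_tick[t], rec_by_tick[t]) for t in common
    ])
    return EvaluationReport(per_frame_cc=cc, frame_ticks=np.asarray(common, dtype=int))
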