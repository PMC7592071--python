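"""Kalman filter and fixed-point smoother for linear dynamical systems.

The engine underlying HS-AFM movie reconstruction: a linear-Gaussian
state-space model

    x_t = F x_{t-1} + v_t,   v_t ~ N(0, Q)
    y_t = H_t x_t + w_t,     w_t ~ N(0, r)

where the state ``x_t`` is a stacked height image and each measurement
``y_t`` is a single scalar (one pixel per time tick, selected by a one-hot
row ``H_t``).  Because the innovation is scalar, every update is a rank-one
operation on a covariance column: O(k^2) per measurement, no matrix
inversion.

The fixed-point smoother tracks the joint Gaussian over ``(x_s, x_t)`` for a
fixed past time ``s`` while the filter advances ``t``, so that a frame can be
refined by the measurements of the following scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "SYMMETRY_TOL",
    "PSD_EIGENVALUE_TOL",
    "DEFAULT_PRIOR_VARIANCE",
    "ShapeError",
    "ScheduleError",
    "ParameterError",
    "SingularInnovationError",
    "Measurement",
    "GaussianBelief",
    "FixedPointBelief",
    "LdsModel",
    "predict",
    "filter_update",
    "fixedpoint_predict",
    "fixedpoint_update",
    "run_filter",
    "run_fixed_point_smoother",
]

# Numerical contracts: covariances are re-symmetrized after every update and
# must stay symmetric / positive semidefinite within these tolerances.
SYMMETRY_TOL = 1e-9
PSD_EIGENVALUE_TOL = -1e-8

#: Default prior variance v0 of the diffuse initial belief N(0, v0 I),
#: in squared height units. Its influence decays within the first scan.
DEFAULT_PRIOR_VARIANCE = 10.0


class ShapeError(ValueError):
    """Dimension mismatch between a belief, model, or measurement."""


class ScheduleError(ValueError):
    """Measurement stream violates the expected tick schedule."""


class ParameterError(ValueError):
    """A model or run parameter is outside its valid range."""


class SingularInnovationError(ArithmeticError):
    """Innovation variance H V H' + r is zero; the update is undefined."""


class Measurement(NamedTuple):
    """One scalar height observation: at time ``tick``, pixel ``pixel``."""

    tick: int
    pixel: int
    value: float


def _symmetrize(cov: np.ndarray) -> np.ndarray:
    return (cov + cov.T) / 2.0


@dataclass
class GaussianBelief:
    """Gaussian state belief N(mean, cov) over the k stacked pixel heights."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.k, self.k):
            raise ShapeError(
                f"cov shape {self.cov.shape} does not match mean length {self.k}"
            )

    @property
    def k(self) -> int:
        return self.mean.shape[0]

    @classmethod
    def diffuse(cls, k: int, variance: float = DEFAULT_PRIOR_VARIANCE) -> "GaussianBelief":
        """Diffuse-but-proper default prior: zero mean, ``variance * I``."""
        if variance < 0:
            raise ParameterError(f"prior variance must be >= 0, got {variance}")
        return cls(np.zeros(k), variance * np.eye(k))

    def validate(self) -> None:
        """Check the symmetry and PSD invariants (used in tests; O(k^3))."""
        if not np.all(np.isfinite(self.mean)) or not np.all(np.isfinite(self.cov)):
            raise ValueError("belief contains non-finite entries")
        asym = np.abs(self.cov - self.cov.T).max() if self.k else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"covariance asymmetry {asym:.3g} exceeds {SYMMETRY_TOL}")
        lo = float(np.linalg.eigvalsh(self.cov).min()) if self.k else 0.0
        if lo < PSD_EIGENVALUE_TOL:
            raise ValueError(f"covariance eigenvalue {lo:.3g} below {PSD_EIGENVALUE_TOL}")


@dataclass
class FixedPointBelief:
    """Joint Gaussian over (x_s, x_t): the fixed past state and the current one.

    Carries both means and the three covariance blocks V_ss, V_st, V_tt.
    The cross block ``cov_st`` need not be symmetric.
    """

    s_mean: np.ndarray
    t_mean: np.ndarray
    cov_ss: np.ndarray
    cov_st: np.ndarray
    cov_tt: np.ndarray
    fixed_tick: int
    current_tick: int

    def __post_init__(self) -> None:
        self.s_mean = np.asarray(self.s_mean, dtype=float).reshape(-1)
        self.t_mean = np.asarray(self.t_mean, dtype=float).reshape(-1)
        k = self.k
        for name in ("cov_ss", "cov_st", "cov_tt"):
            block = np.asarray(getattr(self, name), dtype=float)
            if block.shape != (k, k):
                raise ShapeError(f"{name} shape {block.shape}, expected {(k, k)}")
            setattr(self, name, block)
        if self.current_tick < self.fixed_tick:
            raise ValueError("current_tick must be >= fixed_tick")

    @property
    def k(self) -> int:
        return self.s_mean.shape[0]

    @classmethod
    def from_filtered(cls, belief: GaussianBelief, tick: int) -> "FixedPointBelief":
        """Start smoothing at the fixed time: x_s == x_t, all blocks equal."""
        return cls(
            s_mean=belief.mean.copy(),
            t_mean=belief.mean.copy(),
            cov_ss=belief.cov.copy(),
            cov_st=belief.cov.copy(),
            cov_tt=belief.cov.copy(),
            fixed_tick=tick,
            current_tick=tick,
        )

    def smoothed(self) -> GaussianBelief:
        """Marginal belief over the fixed state x_s given data through t."""
        return GaussianBelief(self.s_mean.copy(), self.cov_ss.copy())

    def validate(self) -> None:
        GaussianBelief(self.s_mean, self.cov_ss).validate()
        GaussianBelief(self.t_mean, self.cov_tt).validate()
        if not np.all(np.isfinite(self.cov_st)):
            raise ValueError("cov_st contains non-finite entries")


@dataclass
class LdsModel:
    """Time-invariant linear dynamical system for one-pixel-per-tick imaging.

    Parameters
    ----------
    k
        State dimension (number of pixels).
    transition
        State transition matrix F: ``None`` for the identity (static
        specimen), or a dense/sparse k-by-k matrix (e.g. the one-pixel
        diffusion operator).
    system_noise
        System noise covariance Q (k-by-k, symmetric PSD), or ``None`` for
        zero noise.
    meas_noise_var
        Scalar measurement noise variance r; R_t = r I with one measurement
        per tick. Default 1.
    """

    k: int
    transition: np.ndarray | sparse.spmatrix | None = None
    system_noise: np.ndarray | None = None
    meas_noise_var: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError(f"state dimension must be >= 1, got {self.k}")
        if self.meas_noise_var < 0:
            raise ParameterError(
                f"measurement noise variance must be >= 0, got {self.meas_noise_var}"
            )
        if self.transition is not None and not sparse.issparse(self.transition):
            self.transition = np.asarray(self.transition, dtype=float)
            if self.transition.shape != (self.k, self.k):
                raise ShapeError(
                    f"transition shape {self.transition.shape}, expected {(self.k, self.k)}"
                )
        elif sparse.issparse(self.transition) and self.transition.shape != (self.k, self.k):
            raise ShapeError(
                f"transition shape {self.transition.shape}, expected {(self.k, self.k)}"
            )
        if self.system_noise is not None:
            self.system_noise = np.asarray(self.system_noise, dtype=float)
            if self.system_noise.shape != (self.k, self.k):
                raise ShapeError(
                    f"system_noise shape {self.system_noise.shape}, expected {(self.k, self.k)}"
                )
            if np.abs(self.system_noise - self.system_noise.T).max() > SYMMETRY_TOL:
                raise ValueError("system_noise must be symmetric")

    # -- F application helpers (identity shortcut keeps the hot loop O(k^2)) --

    def apply_transition(self, vec: np.ndarray) -> np.ndarray:
        """F @ vec."""
        if self.transition is None:
            return vec.copy()
        return np.asarray(self.transition @ vec)

    def apply_transition_right(self, mat: np.ndarray) -> np.ndarray:
        """mat @ F'."""
        if self.transition is None:
            return mat.copy()
        return np.asarray((self.transition @ mat.T)).T

    def propagate_cov(self, cov: np.ndarray) -> np.ndarray:
        """F @ cov @ F' + Q."""
        if self.transition is None:
            out = cov.copy()
        else:
            out = np.asarray(self.transition @ np.asarray(self.transition @ cov).T).T
        if self.system_noise is not None:
            out = out + self.system_noise
        return out


def _check_dim(k_belief: int, model: LdsModel) -> None:
    if k_belief != model.k:
        raise ShapeError(f"belief dimension {k_belief} != model dimension {model.k}")


def _check_pixel(pixel: int, k: int) -> None:
    if not 0 <= pixel < k:
        raise ShapeError(f"pixel index {pixel} out of range [0, {k})")


# ---------------------------------------------------------------------------
# Kalman filter: prediction and rank-one filtering update
# ---------------------------------------------------------------------------

def predict(belief: GaussianBelief, model: LdsModel) -> GaussianBelief:
    """One prediction step: propagate the belief through the system model.

    Returns a new belief with mean F mean and covariance F cov F' + Q
    (re-symmetrized); the input is not mutated.
    """
    _check_dim(belief.k, model)
    mean = model.apply_transition(belief.mean)
    cov = _symmetrize(model.propagate_cov(belief.cov))
    return GaussianBelief(mean, cov)


def filter_update(
    belief: GaussianBelief, m: Measurement, model: LdsModel
) -> GaussianBelief:
    """Condition a predicted belief on one scalar pixel measurement.

    With the one-hot measurement row H selecting ``m.pixel`` the Kalman gain
    is the pixel's covariance column divided by the scalar innovation
    variance, so the whole update is a rank-one correction.
    """
    _check_dim(belief.k, model)
    _check_pixel(m.pixel, belief.k)
    col = belief.cov[:, m.pixel]
    s_var = col[m.pixel] + model.meas_noise_var
    if s_var == 0.0:
        raise SingularInnovationError(
            f"innovation variance is zero at pixel {m.pixel}, tick {m.tick}"
        )
    gain = col / s_var
    mean = belief.mean + gain * (m.value - belief.mean[m.pixel])
    cov = _symmetrize(belief.cov - np.outer(gain, col))
    return GaussianBelief(mean, cov)


# ---------------------------------------------------------------------------
# Fixed-point smoother: joint (x_s, x_t) recursions
# ---------------------------------------------------------------------------

def fixedpoint_predict(fp: FixedPointBelief, model: LdsModel) -> FixedPointBelief:
    """Advance the current-time block of the joint belief by one tick.

    The fixed block (s_mean, cov_ss) is untouched because the system model
    for the frozen state is the identity; the cross block propagates as
    V_st F'.
    """
    _check_dim(fp.k, model)
    t_mean = model.apply_transition(fp.t_mean)
    cov_tt = _symmetrize(model.propagate_cov(fp.cov_tt))
    cov_st = model.apply_transition_right(fp.cov_st)
    return FixedPointBelief(
        s_mean=fp.s_mean.copy(),
        t_mean=t_mean,
        cov_ss=fp.cov_ss.copy(),
        cov_st=cov_st,
        cov_tt=cov_tt,
        fixed_tick=fp.fixed_tick,
        current_tick=fp.current_tick + 1,
    )


def fixedpoint_update(
    fp: FixedPointBelief, m: Measurement, model: LdsModel
) -> FixedPointBelief:
    """Condition the joint (x_s, x_t) belief on one scalar measurement at t.

    The current-time block receives the ordinary Kalman update; the smoother
    gain ``delta`` (cross-covariance column over innovation variance)
    propagates the same innovation back to the fixed time s.
    """
    _check_dim(fp.k, model)
    _check_pixel(m.pixel, fp.k)
    px = m.pixel
    tt_col = fp.cov_tt[:, px]
    s_var = tt_col[px] + model.meas_noise_var
    if s_var == 0.0:
        raise SingularInnovationError(
            f"innovation variance is zero at pixel {px}, tick {m.tick}"
        )
    gain = tt_col / s_var
    delta = fp.cov_st[:, px] / s_var
    innovation = m.value - fp.t_mean[px]
    s_mean = fp.s_mean + delta * innovation
    t_mean = fp.t_mean + gain * innovation
    # Rank-one block updates: H picks row/column px of the predicted blocks.
    cov_ss = _symmetrize(fp.cov_ss - np.outer(delta, fp.cov_st[:, px]))
    cov_st = fp.cov_st - np.outer(delta, fp.cov_tt[px, :])
    cov_tt = _symmetrize(fp.cov_tt - np.outer(gain, tt_col))
    return FixedPointBelief(
        s_mean=s_mean,
        t_mean=t_mean,
        cov_ss=cov_ss,
        cov_st=cov_st,
        cov_tt=cov_tt,
        fixed_tick=fp.fixed_tick,
        current_tick=fp.current_tick,
    )


# ---------------------------------------------------------------------------
# Sequential drivers
# ---------------------------------------------------------------------------

def _validated_stream(stream: Iterable[Measurement]) -> list[Measurement]:
    """Materialize and check a measurement stream: ticks consecutive from 1."""
    out: list[Measurement] = []
    expected = 1
    for rec in stream:
        m = Measurement(int(rec[0]), int(rec[1]), float(rec[2]))
        if m.tick != expected:
            if out and m.tick == out[-1].tick:
                raise ScheduleError(
                    f"duplicate tick {m.tick}: one pixel per tick by construction"
                )
            raise ScheduleError(f"expected tick {expected}, got {m.tick}")
        out.append(m)
        expected += 1
    return out


def run_filter(
    stream: Iterable[Measurement],
    model: LdsModel,
    init: GaussianBelief | None = None,
    snapshot_ticks: Iterable[int] = (),
) -> dict[int, GaussianBelief]:
    """Run the Kalman filter over a per-tick measurement stream.

    Alternates prediction and filtering for ticks 1, 2, ...; returns the
    filtered belief at each requested snapshot tick (frame-end ticks in the
    AFM protocol).

    Parameters
    ----------
    stream
        Measurements with consecutive ticks starting at 1.
    model
        The linear dynamical system.
    init
        Belief at tick 0; defaults to the diffuse prior N(0, v0 I) with
        v0 = 10.
    snapshot_ticks
        Ticks at which to record the filtered belief.
    """
    measurements = _validated_stream(stream)
    if init is None:
        init = GaussianBelief.diffuse(model.k)
    _check_dim(init.k, model)
    wanted = set(int(t) for t in snapshot_ticks)
    missing = wanted - set(range(1, len(measurements) + 1))
    if missing:
        raise ScheduleError(f"snapshot ticks {sorted(missing)} not in stream")
    snapshots: dict[int, GaussianBelief] = {}
    belief = init
    for m in measurements:
        belief = filter_update(predict(belief, model), m, model)
        if m.tick in wanted:
            snapshots[m.tick] = belief
    return snapshots


def run_fixed_point_smoother(
    stream: Iterable[Measurement],
    model: LdsModel,
    init: GaussianBelief | None = None,
    fixed_ticks: Iterable[int] = (),
    lookahead: int = 0,
) -> dict[int, np.ndarray]:
    """Fixed-point smoothed state estimates x_{s | s+lookahead}.

    For each fixed tick s the filter is run through s, then the joint
    (x_s, x_t) belief is carried through ticks s+1 ... s+lookahead and the
    marginal mean of x_s is reported.  Fixed ticks whose lookahead window
    extends past the stream are omitted (the final frame of an AFM movie
    cannot be smoothed).

    A single forward filter pass is shared across all fixed ticks, carrying
    one active cross-block per pending fixed tick; this is algebraically
    identical to an independent computation per fixed tick.
    """
    if lookahead < 0:
        raise ParameterError(f"lookahead must be >= 0, got {lookahead}")
    measurements = _validated_stream(stream)
    if init is None:
        init = GaussianBelief.diffuse(model.k)
    _check_dim(init.k, model)
    n_ticks = len(measurements)
    targets = sorted(set(int(t) for t in fixed_ticks))
    if targets and (targets[0] < 1 or targets[-1] > n_ticks):
        raise ScheduleError(f"fixed ticks must lie within the stream (1..{n_ticks})")
    # Keep only fixed ticks with a complete lookahead window.
    targets = [s for s in targets if s + lookahead <= n_ticks]
    results: dict[int, np.ndarray] = {}
    if not targets:
        return results

    belief = init
    # Active smoothing branches: fixed tick -> (s_mean, cov_ss, cov_st).
    # The t-block of every branch equals the shared filter belief, so only
    # the fixed-state blocks are carried per branch.
    active: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    pending = list(targets)
    last_needed = targets[-1] + lookahead
    for m in measurements:
        if m.tick > last_needed:
            break
        # Predict the shared t-block; propagate each branch's cross block.
        predicted = predict(belief, model)
        for s, (s_mean, cov_ss, cov_st) in active.items():
            active[s] = (s_mean, cov_ss, model.apply_transition_right(cov_st))
        # Scalar-innovation update shared by the filter and all branches.
        px = m.pixel
        _check_pixel(px, model.k)
        tt_col = predicted.cov[:, px]
        s_var = tt_col[px] + model.meas_noise_var
        if s_var == 0.0:
            raise SingularInnovationError(
                f"innovation variance is zero at pixel {px}, tick {m.tick}"
            )
        innovation = m.value - predicted.mean[px]
        for s, (s_mean, cov_ss, cov_st) in active.items():
            delta = cov_st[:, px] / s_var
            active[s] = (
                s_mean + delta * innovation,
                _symmetrize(cov_ss - np.outer(delta, cov_st[:, px])),
                cov_st - np.outer(delta, tt_col),
            )
        gain = tt_col / s_var
        belief = GaussianBelief(
            predicted.mean + gain * innovation,
            _symmetrize(predicted.cov - np.outer(gain, tt_col)),
        )
        # Open a branch at each fixed tick; close branches whose window ends.
        if pending and m.tick == pending[0]:
            s = pending.pop(0)
            if lookahead == 0:
                results[s] = belief.mean.copy()
            else:
                active[s] = (belief.mean.copy(), belief.cov.copy(), belief.cov.copy())
        for s in [s for s in active if s + lookahead == m.tick]:
            results[s] = active.pop(s)[0]
    return results
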