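"""Brute-force joint-Gaussian conditioning oracle.

Independent of the sequential recursions under test: builds the full joint
Gaussian over all states x_1..x_T implied by the linear dynamical system,
stacks the one-hot measurement rows, and conditions by Schur complement.
Only feasible for tiny problems (k*T of a few dozen), which is the point.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from afmkalman import LdsModel, Measurement


def dense_model(model: LdsModel) -> tuple[np.ndarray, np.ndarray]:
    """Densified (F, Q) with identity/zero defaults resolved."""
    if model.transition is None:
        F = np.eye(model.k)
    elif sparse.issparse(model.transition):
        F = model.transition.toarray()
    else:
        F = np.asarray(model.transition, float)
    Q = np.zeros((model.k, model.k)) if model.system_noise is None else model.system_noise
    return F, Q


def joint_state_prior(
    F: np.ndarray, Q: np.ndarray, m0: np.ndarray, V0: np.ndarray, T: int
) -> tuple[np.ndarray, np.ndarray]:
    """Prior mean and covariance of the stacked states (x_1, ..., x_T)."""
    k = m0.shape[0]
    means = np.empty((T, k))
    mu = m0
    for t in range(T):
        mu = F @ mu
        means[t] = mu
    diag = []
    prev = V0
    for _ in range(T):
        prev = F @ prev @ F.T + Q
        diag.append(prev)
    cov = np.zeros((T, k, T, k))
    for i in range(T):
        cov[i, :, i, :] = diag[i]
        acc = diag[i]
        for j in range(i + 1, T):
            acc = acc @ F.T  # cov(x_i, x_j) = cov(x_i, x_{j-1}) F'
            cov[i, :, j, :] = acc
            cov[j, :, i, :] = acc.T
    return means.reshape(T * k), cov.reshape(T * k, T * k)


def condition(
    mean: np.ndarray,
    cov: np.ndarray,
    H: np.ndarray,
    y: np.ndarray,
    noise_var: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Condition N(mean, cov) on y = H x + N(0, noise_var I)."""
    S = H @ cov @ H.T + noise_var * np.eye(H.shape[0])
    gain = cov @ H.T @ np.linalg.inv(S)
    post_mean = mean + gain @ (y - H @ mean)
    post_cov = cov - gain @ H @ cov
    return post_mean, post_cov


def posterior_state_moments(
    model: LdsModel,
    m0: np.ndarray,
    V0: np.ndarray,
    measurements: list[Measurement],
    query_ticks: list[int],
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Posterior mean and covariance of x_t for each queried tick, given all
    supplied measurements, via full joint conditioning."""
    F, Q = dense_model(model)
    k = model.k
    T = max(m.tick for m in measurements)
    mean, cov = joint_state_prior(F, Q, np.asarray(m0, float), np.asarray(V0, float), T)
    H = np.zeros((len(measurements), T * k))
    y = np.empty(len(measurements))
    for i, m in enumerate(measurements):
        H[i, (m.tick - 1) * k + m.pixel] = 1.0
        y[i] = m.value
    post_mean, post_cov = condition(mean, cov, H, y, model.meas_noise_var)
    out = {}
    for t in query_ticks:
        sl = slice((t - 1) * k, t * k)
        out[t] = (post_mean[sl], post_cov[sl, sl])
    return out
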