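# Methods

## State-space model

The image sequence is modeled as a linear dynamical system over the stacked
pixel heights `x_t` (length k = n_px · n_py, row-major with x fastest):

    x_t = F x_{t-1} + v_t,   v_t ~ N(0, Q)
    y_t = h_t' x_t + w_t,    w_t ~ N(0, r)

One scalar measurement arrives per tick; `h_t` is the one-hot vector of the
raster pixel at tick `t`. Ticks are 1-based; a frame spans k consecutive
ticks; the raster always sweeps x in the same direction and advances y by
one line per sweep.

Assumptions: the specimen's height field evolves slowly and smoothly
relative to single-pixel acquisition; measurement noise is white and
homoscedastic; dynamics are linear-Gaussian. Nonlinear or non-Gaussian
motion (e.g. discrete conformational switching) is captured only insofar as
the smooth Gaussian system noise can absorb it.

## Filter and fixed-point smoother

Prediction propagates mean and covariance through `F` and adds `Q`.
Filtering conditions on the scalar measurement: the innovation variance
`S = V[px, px] + r` is a scalar, so the Kalman gain is the covariance
column of the measured pixel divided by `S`, and the covariance update is a
rank-one subtraction. Cost is O(k²) per tick with no matrix inversion;
covariances are explicitly re-symmetrized after every update (the plain
`V − K h' V` form is used; Joseph stabilization proved unnecessary at these
problem sizes, with eigenvalues staying above −1e−8 throughout the test
suite).

The fixed-point smoother carries the joint Gaussian over `(x_s, x_t)` for a
fixed frame time `s` while `t` advances: the cross block propagates as
`V_st F'`, and each measurement updates the fixed state through the smoother
gain `Δ = V_st h / S`. The driver shares a single forward filter pass across
all requested fixed ticks, keeping one `(s_mean, V_ss, V_st)` triple per
pending frame (the `t` block is common to all of them); this is
algebraically identical to smoothing each frame independently, and a test
asserts that equality against the public single-step operations.

Frame semantics: the filter image of frame f is `x_{fk|fk}`; the smoother
image is `x_{fk|(f+1)k}` (lookahead = one full scan, configurable), so the
final frame of a movie has no smoothed image.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `q` | system-noise scale (height units per tick) | 0.1 | entry `q²` on the Q diagonal; the main knob trading responsiveness vs. smoothing |
| `Δx_Q, Δy_Q` | Q kernel length scales (pixels) | 1 | Gaussian spatial correlation of the system noise |
| `r` | measurement noise variance (height units²) | 1 | `R = r I`, one scalar measurement per tick |
| `p` | one-pixel diffusion probability per tick | 0 | `p = 0` gives `F = I`; rows of F sum to 1 (mass conserving, also at edges) |
| `v0` | initial belief variance | 10 | diffuse-but-proper prior `N(0, v0 I)`; its influence decays within the first scan |
| lookahead | smoother future window (ticks) | k | one full scan |

The Q kernel on a finite grid is symmetric positive semidefinite as-is
(verified by eigenvalue checks up to 10×10); no jitter is added by default.

## The twin experiment

The synthetic generator emulates a single rigid feature diffusing on the
stage: a linear circular cone (base radius 3 px, height 3) whose vertex
random-walks with independent per-tick Uniform(−s, s) increments per axis,
clamped to the stage `[0, n_px−1] × [0, n_py−1]` (reflection is available
as an option; the clamp is the minimal reading of "bound to inside"). The
walk starts at the stage center. Measurements sample the cone height at the
center of the raster pixel of each tick — integer coordinates are pixel
centers — plus i.i.d. N(0, 0.3²) noise. One seeded generator per
experiment, walk drawn before noise, makes every run bit-reproducible.

Default conditions: 10×10 grid, 10,000 ticks (100 frames), s = 0.1. The
ground-truth movie records the full height field at each frame-end tick.
Evaluation uses the uncentered correlation coefficient per frame, averaged
over the 99 frames all methods share; negative reconstructed heights enter
the metric unclipped (the metric is well defined for signed values), and
reports carry both the sd of the per-frame series and its standard error.

What this does and does not show: the cone is rigid, convex, and alone on
the stage, so passing these tests demonstrates the handling of
translational asynchronicity and sensor noise — not conformational change,
multiple interacting molecules, tip-shape convolution, or drift/creep of a
real instrument. Real movies enter through the generic csv-stack/tiff-stack
interfaces after external conversion.

## Numerical and design choices

- One pixel per tick is enforced: duplicate or gapped ticks raise a
  schedule error rather than being reinterpreted.
- Trailing partial scans are dropped (with a logged warning), never padded.
- A zero innovation variance (`r = 0` against an already-certain pixel)
  raises an explicit singular-innovation error; exact-measurement behavior
  is exercised in tests with `r = 0` on proper priors or `r ≈ 1e−12` in
  sequential runs.
- An all-zero image makes the correlation coefficient undefined and raises,
  rather than silently scoring 0.
- The diffusive transition keeps `1 − (existing neighbors)·p` on the
  diagonal so every row sums to 1: total height mass is conserved,
  including at the boundary, and the interior behavior reduces to the
  standard five-point diffusion stencil. It is stored sparse so the
  per-tick cost stays O(k²).
- Problem sizes in the test suite follow the default study conditions
  (10×10 grid, 10,000 ticks); exact-equivalence checks against the
  brute-force joint-Gaussian conditioning oracle run at k ≤ 6 and ≤ 10
  ticks, where the full joint covariance is tractable.

## Known limitations

- At fast diffusion (s = 1) all methods degrade; the filter retains its
  noise-reduction advantage over the raw assembly (mean c.c. ≈ 0.35 vs
  0.29), so the two are similar but not equivalent there.
- `q`, `r`, and `p` are fixed per run; likelihood-based estimation of the
  system matrices is out of scope, as are fixed-interval/fixed-lag
  smoothers, non-raster scan schedules, and tip-geometry deconvolution.
- The smoother's covariance blocks grow dense even for sparse `F`; memory
  is three k×k blocks per concurrently pending frame (at the default
  lookahead, at most two).
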