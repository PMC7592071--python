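# afmkalman

Kalman filtering and fixed-point smoothing for high-speed atomic force
microscopy (HS-AFM) height-map movies.

HS-AFM records the height of biomolecules one pixel per time tick while the
probe raster-scans the stage. A molecule keeps moving during the scan, so
each assembled frame mixes measurements taken at different times — the
frames are *asynchronous*. `afmkalman` treats the image sequence as a
linear-Gaussian state-space model and reconstructs each frame from the
per-pixel measurement stream, reducing both noise and asynchronicity. It is
aimed at HS-AFM practitioners and at anyone who needs a fixed-point
Kalman smoother with scalar (one-hot) observations.

## The model

The state `x_t` is the stacked height image (k = n_px × n_py pixels):

    x_t = F x_{t-1} + v_t,      v_t ~ N(0, Q)
    y_t = H_t x_t + w_t,        w_t ~ N(0, r)

- `H_t` is the one-hot row selecting the raster pixel of tick `t` (the probe
  sweeps x from 0 to n_px−1, then advances one line in y); each `y_t` is a
  single scalar height.
- `F = I` by default (a molecule bound to the stage); optionally a one-pixel
  diffusion operator where each pixel leaks probability `p` to its four
  neighbors.
- `Q(r, s) = q² exp(−(r_x−s_x)²/2Δx² − (r_y−s_y)²/2Δy²)` with Δx = Δy = 1
  pixel: a spatial Gaussian kernel expressing that molecular height fields
  are smooth. `q` is the main tuning knob.
- `r` is the measurement noise variance (default 1).

The **Kalman filter** estimates `x_{t|t}` from the current and past
measurements and is snapshotted at each frame-end tick. The **fixed-point
smoother** additionally propagates the next full scan of measurements back
to the frame time, producing `x_{s|s+k}`; it therefore cannot produce the
final frame. Because the innovation is scalar, every update is a rank-one
covariance operation — O(k²) per tick, no matrix inversion — which makes
60×60 or 80×80 movies practical.

Reconstructions are scored against ground truth with the uncentered
(cosine-type) correlation coefficient
`c.c. = Σ H^truth H^image / (‖H^truth‖ ‖H^image‖)`.

## Worked example

The package ships a twin experiment: a cone (base radius 3 px, height 3)
random-walks on a 10×10 stage for 10,000 ticks while the virtual probe
records one noisy pixel per tick (noise sd 0.3); the known ground truth then
scores each reconstruction.

    afmkalman twin --seed 7 --out runs/twin7

prints

    raw       mean c.c. 0.8760 (sd 0.0295, n = 99)
    filter    mean c.c. 0.9329 (sd 0.0292, n = 99)
    smoother  mean c.c. 0.9494 (sd 0.0207, n = 99)

i.e. over the 99 frames all methods share, the raw (asynchronous) movie
correlates 0.876 with the truth, the filter improves this mainly by noise
reduction, and the smoother — which also sees the following scan — resolves
the asynchronicity and reaches 0.949. Per-frame tables are written to
`runs/twin7/cc_<method>.csv`.

The same pipeline is available programmatically:

```python
from afmkalman import WalkConfig, run_twin_experiment

reports = run_twin_experiment(WalkConfig(seed=7), q=0.1)
print(reports["smoother"].mean_cc)   # 0.9494...
```

Generic movies are supported through the `simulate` / `reconstruct` /
`evaluate` subcommands and the `read_movie` / `write_movie` functions
(csv-stack or tiff-stack; one header per frame, x fastest within a row).

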