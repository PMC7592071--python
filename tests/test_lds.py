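"""Unit and property tests for the Kalman filter / fixed-point smoother core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_allclose

from afmkalman import (
    FixedPointBelief,
    GaussianBelief,
    LdsModel,
    Measurement,
    ParameterError,
    ScheduleError,
    ShapeError,
    SingularInnovationError,
    filter_update,
    fixedpoint_predict,
    fixedpoint_update,
    predict,
    run_filter,
    run_fixed_point_smoother,
)
from conftest import random_psd
from oracle import posterior_state_moments


def _static_model(k, r=1.0):
    return LdsModel(k=k, meas_noise_var=r)


# ---------------------------------------------------------------------------
# predict
# ---------------------------------------------------------------------------

class TestPredict:
    def test_identity_propagation(self, rng):
        belief = GaussianBelief(rng.normal(size=3), random_psd(rng, 3))
        out = predict(belief, _static_model(3))
        assert_allclose(out.mean, belief.mean)
        assert_allclose(out.cov, belief.cov)

    def test_identity_with_noise_adds_q(self, rng):
        q0 = random_psd(rng, 3)
        belief = GaussianBelief(rng.normal(size=3), random_psd(rng, 3))
        out = predict(belief, LdsModel(k=3, system_noise=q0))
        assert_allclose(out.mean, belief.mean)
        assert_allclose(out.cov, belief.cov + q0)

    def test_general_transition_matches_matrix_arithmetic(self):
        # shear transition, unit prior covariance: cov' = F F'
        f = np.array([[1.0, 0.5], [0.0, 1.0]])
        belief = GaussianBelief(np.array([1.0, -2.0]), np.eye(2))
        out = predict(belief, LdsModel(k=2, transition=f))
        assert_allclose(out.mean, f @ belief.mean)
        assert_allclose(out.cov, f @ f.T, atol=1e-15)

    def test_input_not_mutated(self, rng):
        belief = GaussianBelief(rng.normal(size=3), random_psd(rng, 3))
        mean0, cov0 = belief.mean.copy(), belief.cov.copy()
        out = predict(belief, LdsModel(k=3, system_noise=np.eye(3)))
        assert out is not belief
        assert_allclose(belief.mean, mean0)
        assert_allclose(belief.cov, cov0)

    def test_dimension_mismatch(self, rng):
        belief = GaussianBelief(np.zeros(3), np.eye(3))
        with pytest.raises(ShapeError):
            predict(belief, _static_model(4))


# ---------------------------------------------------------------------------
# filter_update
# ---------------------------------------------------------------------------

class TestFilterUpdate:
    @pytest.mark.parametrize("y", [-1.7, 0.0, 3.2])
    def test_scalar_closed_form(self, y):
        # prior N(0, 1), r = 1: posterior N(y/2, 1/2)
        belief = GaussianBelief(np.zeros(1), np.eye(1))
        out = filter_update(belief, Measurement(1, 0, y), _static_model(1))
        assert_allclose(out.mean, [y / 2.0])
        assert_allclose(out.cov, [[0.5]])

    def test_exact_measurement_limit(self, rng):
        # r = 0 pins the observed pixel to the measured value with zero variance
        belief = GaussianBelief(rng.normal(size=4), random_psd(rng, 4))
        out = filter_update(belief, Measurement(1, 2, 5.5), _static_model(4, r=0.0))
        assert_allclose(out.mean[2], 5.5, atol=1e-12)
        assert_allclose(out.cov[2, 2], 0.0, atol=1e-12)

    def test_matches_gaussian_conditioning(self, rng):
        # one scalar measurement == conditioning of the joint (x, y) Gaussian
        k = 4
        cov = random_psd(rng, k)
        mean = rng.normal(size=k)
        r = 0.7
        m = Measurement(1, 1, 2.3)
        out = filter_update(GaussianBelief(mean, cov), m, LdsModel(k=k, meas_noise_var=r))
        # Schur-complement conditioning oracle
        h = np.zeros((1, k))
        h[0, m.pixel] = 1.0
        s = h @ cov @ h.T + r
        gain = cov @ h.T / s
        exp_mean = mean + (gain * (m.value - mean[m.pixel])).ravel()
        exp_cov = cov - gain @ h @ cov
        assert_allclose(out.mean, exp_mean, atol=1e-10)
        assert_allclose(out.cov, exp_cov, atol=1e-10)

    def test_singular_innovation(self):
        belief = GaussianBelief(np.zeros(2), np.zeros((2, 2)))
        with pytest.raises(SingularInnovationError):
            filter_update(belief, Measurement(1, 0, 1.0), _static_model(2, r=0.0))

    def test_pixel_out_of_range(self):
        belief = GaussianBelief(np.zeros(2), np.eye(2))
        with pytest.raises(ShapeError):
            filter_update(belief, Measurement(1, 5, 1.0), _static_model(2))

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), pixel=st.integers(0, 3),
           r=st.floats(0.0, 5.0), value=st.floats(-10, 10))
    def test_never_increases_observed_variance(self, seed, pixel, r, value):
        rng = np.random.default_rng(seed)
        belief = GaussianBelief(rng.normal(size=4), random_psd(rng, 4))
        out = filter_update(belief, Measurement(1, pixel, value),
                            LdsModel(k=4, meas_noise_var=r))
        assert out.cov[pixel, pixel] <= belief.cov[pixel, pixel] + 1e-12
        out.validate()


# ---------------------------------------------------------------------------
# fixed-point smoother single steps
# ---------------------------------------------------------------------------

def _fresh_fp(rng, k, tick=1):
    belief = GaussianBelief(rng.normal(size=k), random_psd(rng, k))
    return FixedPointBelief.from_filtered(belief, tick)


class TestFixedPointSteps:
    def test_static_predict_is_identity(self, rng):
        fp = _fresh_fp(rng, 3)
        out = fixedpoint_predict(fp, _static_model(3))
        assert out.current_tick == fp.current_tick + 1
        assert_allclose(out.s_mean, fp.s_mean)
        assert_allclose(out.t_mean, fp.t_mean)
        for name in ("cov_ss", "cov_st", "cov_tt"):
            assert_allclose(getattr(out, name), getattr(fp, name))

    def test_noise_only_changes_tt_block(self, rng):
        fp = _fresh_fp(rng, 3)
        q0 = random_psd(rng, 3)
        out = fixedpoint_predict(fp, LdsModel(k=3, system_noise=q0))
        assert_allclose(out.cov_tt, fp.cov_tt + q0)
        assert_allclose(out.cov_st, fp.cov_st)
        assert_allclose(out.cov_ss, fp.cov_ss)

    def test_cross_block_propagates_by_transition(self, rng):
        f = np.array([[0.9, 0.2], [-0.1, 1.1]])
        fp = _fresh_fp(rng, 2)
        fp = fixedpoint_update(fp, Measurement(1, 0, 0.4), LdsModel(k=2))
        out = fixedpoint_predict(fp, LdsModel(k=2, transition=f))
        assert_allclose(out.cov_st, fp.cov_st @ f.T, atol=1e-12)

    def test_update_at_fixed_tick_equals_filter_update(self, rng):
        # with identical blocks the smoother gain reduces to the Kalman gain
        k, m = 3, Measurement(1, 2, 1.1)
        belief = GaussianBelief(rng.normal(size=k), random_psd(rng, k))
        fp = FixedPointBelief.from_filtered(belief, 1)
        model = _static_model(k)
        fp_out = fixedpoint_update(fp, m, model)
        filt = filter_update(belief, m, model)
        assert_allclose(fp_out.s_mean, filt.mean, atol=1e-12)
        assert_allclose(fp_out.t_mean, filt.mean, atol=1e-12)
        assert_allclose(fp_out.cov_ss, filt.cov, atol=1e-12)
        assert_allclose(fp_out.cov_tt, filt.cov, atol=1e-12)

    def test_static_state_smoother_tracks_filter(self, rng):
        # F = I, Q = 0: x_s and x_t are the same variable, so the two means agree
        k = 3
        model = _static_model(k)
        fp = _fresh_fp(rng, k)
        for tick in range(2, 8):
            fp = fixedpoint_predict(fp, model)
            fp = fixedpoint_update(
                fp, Measurement(tick, (tick * 2) % k, rng.normal()), model
            )
            assert_allclose(fp.s_mean, fp.t_mean, atol=1e-12)
        fp.validate()

    def test_matches_joint_gaussian_conditioning(self, rng):
        # smoothed x_s after two later measurements == brute-force conditioning
        k = 2
        f = np.array([[0.8, 0.3], [0.1, 0.9]])
        q = random_psd(rng, k, jitter=0.3)
        model = LdsModel(k=k, transition=f, system_noise=q, meas_noise_var=0.5)
        m0, v0 = rng.normal(size=k), random_psd(rng, k)
        measurements = [
            Measurement(1, 0, 0.7),
            Measurement(2, 1, -0.2),
            Measurement(3, 0, 1.4),
        ]
        # sequential: filter tick 1, then carry the fixed point through 2, 3
        belief = filter_update(
            predict(GaussianBelief(m0, v0), model), measurements[0], model
        )
        fp = FixedPointBelief.from_filtered(belief, 1)
        for m in measurements[1:]:
            fp = fixedpoint_update(fixedpoint_predict(fp, model), m, model)
        expected = posterior_state_moments(model, m0, v0, measurements, [1])[1]
        assert_allclose(fp.s_mean, expected[0], atol=1e-10)
        assert_allclose(fp.cov_ss, expected[1], atol=1e-10)


# ---------------------------------------------------------------------------
# sequential drivers
# ---------------------------------------------------------------------------

class TestRunFilter:
    def test_empty_snapshot_set(self, rng):
        stream = [Measurement(t, 0, 0.0) for t in range(1, 4)]
        assert run_filter(stream, _static_model(1)) == {}

    def test_conjugate_variance_closed_form(self):
        # static scalar state: posterior variance 1/(1/v0 + n/r)
        v0, r, n = 10.0, 2.0, 6
        init = GaussianBelief(np.zeros(1), v0 * np.eye(1))
        stream = [Measurement(t, 0, 1.0) for t in range(1, n + 1)]
        snaps = run_filter(stream, _static_model(1, r=r), init=init,
                           snapshot_ticks=range(1, n + 1))
        for t in range(1, n + 1):
            assert_allclose(snaps[t].cov[0, 0], 1.0 / (1.0 / v0 + t / r), atol=1e-12)

    def test_matches_batch_conditioning(self, rng):
        k = 2
        f = np.array([[1.0, 0.1], [0.0, 0.95]])
        model = LdsModel(k=k, transition=f, system_noise=random_psd(rng, k, 0.2),
                         meas_noise_var=0.8)
        m0, v0 = rng.normal(size=k), random_psd(rng, k)
        stream = [Measurement(t, t % k, rng.normal()) for t in range(1, 5)]
        snaps = run_filter(stream, model, init=GaussianBelief(m0, v0),
                           snapshot_ticks=[4])
        exp_mean, exp_cov = posterior_state_moments(model, m0, v0, stream, [4])[4]
        assert_allclose(snaps[4].mean, exp_mean, atol=1e-10)
        assert_allclose(snaps[4].cov, exp_cov, atol=1e-10)

    def test_gap_in_ticks_rejected(self):
        stream = [Measurement(1, 0, 0.0), Measurement(3, 0, 0.0)]
        with pytest.raises(ScheduleError):
            run_filter(stream, _static_model(1))

    def test_duplicate_tick_rejected(self):
        stream = [Measurement(1, 0, 0.0), Measurement(1, 0, 1.0)]
        with pytest.raises(ScheduleError):
            run_filter(stream, _static_model(1))

    def test_snapshot_outside_stream_rejected(self):
        stream = [Measurement(1, 0, 0.0)]
        with pytest.raises(ScheduleError):
            run_filter(stream, _static_model(1), snapshot_ticks=[5])


class TestRunFixedPointSmoother:
    def test_lookahead_zero_equals_filter(self, rng):
        k = 3
        model = LdsModel(k=k, system_noise=random_psd(rng, k, 0.2))
        stream = [Measurement(t, t % k, rng.normal()) for t in range(1, 7)]
        filt = run_filter(stream, model, snapshot_ticks=[3, 6])
        smoothed = run_fixed_point_smoother(stream, model, fixed_ticks=[3, 6],
                                            lookahead=0)
        for t in (3, 6):
            assert_allclose(smoothed[t], filt[t].mean, atol=1e-12)

    def test_negative_lookahead_rejected(self):
        with pytest.raises(ParameterError):
            run_fixed_point_smoother([], _static_model(1), lookahead=-1)

    def test_fixed_ticks_without_lookahead_window_omitted(self, rng):
        stream = [Measurement(t, 0, rng.normal()) for t in range(1, 7)]
        out = run_fixed_point_smoother(stream, _static_model(1),
                                       fixed_ticks=[2, 4, 6], lookahead=2)
        assert sorted(out) == [2, 4]  # tick 6 would need data through tick 8

    def test_exact_measurement_recovers_static_truth(self):
        # static 2-pixel specimen, noiseless values, r -> 0: truth recovered
        truth = np.array([1.0, 2.0])
        model = LdsModel(k=2, meas_noise_var=1e-12)
        stream = [Measurement(t, (t - 1) % 2, truth[(t - 1) % 2])
                  for t in range(1, 5)]
        out = run_fixed_point_smoother(stream, model, fixed_ticks=[2], lookahead=2)
        assert_allclose(out[2], truth, atol=1e-5)

    def test_shared_pass_equals_independent_per_fixed_point(self, rng):
        # driver optimization must be invisible: compare with a naive loop
        # over the public single-step operations, one pass per fixed tick
        k = 3
        f = np.eye(k) + 0.05 * rng.normal(size=(k, k))
        model = LdsModel(k=k, transition=f, system_noise=random_psd(rng, k, 0.2),
                         meas_noise_var=0.6)
        init = GaussianBelief(rng.normal(size=k), random_psd(rng, k))
        stream = [Measurement(t, int(rng.integers(k)), rng.normal())
                  for t in range(1, 10)]
        lookahead = 3
        fixed_ticks = [2, 3, 5, 6]
        shared = run_fixed_point_smoother(stream, model, init=init,
                                          fixed_ticks=fixed_ticks,
                                          lookahead=lookahead)
        for s in fixed_ticks:
            belief = init
            for m in stream[:s]:
                belief = filter_update(predict(belief, model), m, model)
            fp = FixedPointBelief.from_filtered(belief, s)
            for m in stream[s:s + lookahead]:
                fp = fixedpoint_update(fixedpoint_predict(fp, model), m, model)
            assert_allclose(shared[s], fp.s_mean, atol=1e-10)

    def test_oracle_equivalence_on_random_problems(self, rng):
        # the shared invariant: filter and smoother agree with full joint
        # Gaussian conditioning on any small problem
        for _ in range(10):
            k = int(rng.integers(1, 5))
            n_ticks = int(rng.integers(k, 9))
            f = np.eye(k) + 0.1 * rng.normal(size=(k, k))
            model = LdsModel(k=k, transition=f,
                             system_noise=random_psd(rng, k, 0.1),
                             meas_noise_var=float(rng.uniform(0.3, 1.5)))
            m0, v0 = rng.normal(size=k), random_psd(rng, k)
            stream = [Measurement(t, int(rng.integers(k)), float(rng.normal()))
                      for t in range(1, n_ticks + 1)]
            snaps = run_filter(stream, model, init=GaussianBelief(m0, v0),
                               snapshot_ticks=[n_ticks])
            exp = posterior_state_moments(model, m0, v0, stream, [n_ticks])
            assert_allclose(snaps[n_ticks].mean, exp[n_ticks][0], atol=1e-8)
            s = max(1, n_ticks - 2)
            sm = run_fixed_point_smoother(stream, model,
                                          init=GaussianBelief(m0, v0),
                                          fixed_ticks=[s],
                                          lookahead=n_ticks - s)
            exp_s = posterior_state_moments(model, m0, v0, stream, [s])
            assert_allclose(sm[s], exp_s[s][0], atol=1e-8)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

class TestInvariants:
    def test_covariances_stay_symmetric_psd_through_run(self, rng):
        k = 4
        model = LdsModel(k=k, system_noise=random_psd(rng, k, 0.05),
                         meas_noise_var=0.5)
        belief = GaussianBelief.diffuse(k)
        fp = None
        for tick in range(1, 15):
            m = Measurement(tick, int(rng.integers(k)), float(rng.normal()))
            belief = filter_update(predict(belief, model), m, model)
            belief.validate()
            if tick == 5:
                fp = FixedPointBelief.from_filtered(belief, tick)
            elif fp is not None:
                fp = fixedpoint_update(fixedpoint_predict(fp, model), m, model)
                fp.validate()

    def test_static_state_measurement_order_invariance(self, rng):
        # F = I, Q = 0: the state is one constant, so the posterior cannot
        # depend on the order in which the pixel measurements arrive
        k = 3
        model = _static_model(k, r=0.8)
        pairs = [(int(rng.integers(k)), float(rng.normal())) for _ in range(6)]
        means = []
        for order in (pairs, pairs[::-1]):
            stream = [Measurement(t, p, v) for t, (p, v) in enumerate(order, 1)]
            snaps = run_filter(stream, model, snapshot_ticks=[len(order)])
            means.append(snaps[len(order)].mean)
        assert_allclose(means[0], means[1], atol=1e-9)

    def test_diffuse_prior_validation(self):
        with pytest.raises(ParameterError):
            GaussianBelief.diffuse(2, variance=-1.0)
        belief = GaussianBelief.diffuse(2)
        assert_allclose(belief.cov, 10.0 * np.eye(2))

    def test_fixed_point_belief_requires_current_after_fixed(self):
        with pytest.raises(ValueError):
            FixedPointBelief(
                s_mean=np.zeros(1), t_mean=np.zeros(1),
                cov_ss=np.eye(1), cov_st=np.eye(1), cov_tt=np.eye(1),
                fixed_tick=5, current_tick=3,
            )
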