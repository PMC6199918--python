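"""Gamma kernels: SoftPlus warp, discretization, causal convolution, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gammadecoder.gamma_core import (
    GammaFilterParams,
    GammaLayerParams,
    causal_conv,
    gamma_layer_backward,
    gamma_layer_forward,
    gamma_taps,
    parameter_gradients,
    softplus_time,
)


def brute_force_conv(x, taps):
    """Direct double-loop causal convolution oracle."""
    out = np.zeros_like(x, dtype=float)
    for t in range(len(x)):
        for k in range(len(taps)):
            if t - k >= 0:
                out[t] += taps[k] * x[t - k]
    return out


def random_layer(rng, d_in, d_out, n_taps=12, dt=0.01):
    return GammaLayerParams(
        alpha=rng.standard_normal((d_in, d_out)),
        log_beta=-np.log(rng.uniform(0.01, 0.05, (d_in, d_out))),
        log_t0=np.log(rng.uniform(0.005, 0.03, (d_in, d_out))),
        n_taps=n_taps,
        dt=dt,
    )


class TestSoftplusTime:
    def test_value_at_onset(self):
        theta, beta = 10.0, 3.0
        assert softplus_time(0.25, 0.25, beta, theta) == pytest.approx(
            np.log(2) / (theta * beta)
        )

    def test_reference_point(self):
        # theta=10, beta=1, t0=0, t=1: t_f = 0.1*ln(e^10 + 1)
        assert softplus_time(1.0, 0.0, 1.0, 10.0) == pytest.approx(
            0.1 * np.log(np.exp(10.0) + 1.0), rel=1e-12
        )

    def test_far_below_onset_approaches_zero(self):
        tf = softplus_time(-8.0, 0.0, 1.0, 10.0)
        assert 0 < tf < 1e-12

    def test_far_above_onset_asymptote(self):
        # no overflow, and t_f -> t - t0 exactly in the upper tail
        tf = softplus_time(500.0, 0.1, 2.0, 10.0)
        assert np.isfinite(tf)
        assert tf == pytest.approx(500.0 - 0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        t=st.floats(-5, 10),
        log_t0=st.floats(-6, 0),
        log_beta=st.floats(-2, 1.5),
    )
    def test_strictly_positive_and_monotone(self, t, log_t0, log_beta):
        beta, t0 = np.exp(log_beta), np.exp(log_t0)
        tf = softplus_time(t, t0, beta)
        assert tf > 0
        assert softplus_time(t + 0.01, t0, beta) > tf


class TestGammaTaps:
    def test_zero_alpha_gives_zero_kernel(self):
        p = GammaFilterParams(alpha=0.0, log_beta=0.0, log_t0=np.log(0.02))
        assert np.all(gamma_taps(p) == 0)

    def test_area_equals_alpha(self):
        p = GammaFilterParams(alpha=1.5, log_beta=-np.log(0.02), log_t0=np.log(0.03))
        taps = gamma_taps(p)
        assert np.sum(taps) * p.dt == pytest.approx(1.5, rel=0.02)

    def test_peak_location_and_height(self):
        # argmax of u*exp(-beta*u) at u = 1/beta, value alpha*beta/e
        tau = 0.05
        p = GammaFilterParams(
            alpha=2.0, log_beta=-np.log(tau), log_t0=np.log(0.02), n_taps=40
        )
        taps = gamma_taps(p)
        k = int(np.argmax(taps))
        assert taps[k] == pytest.approx(2.0 * p.beta / np.e, rel=0.01)
        # peak occurs where warped time ~ 1/beta, i.e. near t0 + tau
        assert k * p.dt == pytest.approx(0.02 + tau, abs=p.dt)

    def test_sign_follows_alpha(self):
        p = GammaFilterParams(alpha=-0.8, log_beta=-np.log(0.03), log_t0=np.log(0.01))
        assert np.all(gamma_taps(p) <= 0)

    def test_area_conservation_over_random_draws(self):
        # kernel support fully inside the span (t0 + 8/beta < n_taps*dt) and
        # resolved by the grid: sampled at 2 ms so the shortest time
        # constants (5 ms) are still integrated accurately
        rng = np.random.default_rng(7)
        n_taps, dt = 300, 0.002
        worst = 0.0
        for _ in range(1000):
            t0 = rng.uniform(0.005, 0.05)
            tau = rng.uniform(0.005, min((n_taps * dt - t0) / 8.0, 0.06))
            alpha = rng.uniform(0.2, 3.0) * rng.choice([-1, 1])
            p = GammaFilterParams(
                alpha=alpha, log_beta=-np.log(tau), log_t0=np.log(t0),
                n_taps=n_taps, dt=dt,
            )
            rel = abs(np.sum(gamma_taps(p)) * dt - alpha) / abs(alpha)
            worst = max(worst, rel)
        assert worst < 0.02

    def test_sampling_rate_invariance(self):
        # halving dt and doubling n_taps leaves the area nearly unchanged
        base = dict(alpha=1.0, log_beta=-np.log(0.03), log_t0=np.log(0.02))
        coarse = GammaFilterParams(**base, n_taps=30, dt=0.01)
        fine = GammaFilterParams(**base, n_taps=60, dt=0.005)
        a1 = np.sum(gamma_taps(coarse)) * coarse.dt
        a2 = np.sum(gamma_taps(fine)) * fine.dt
        assert abs(a2 - a1) / abs(a1) < 0.01


class TestCausalConv:
    def test_impulse_reproduces_kernel(self):
        taps = np.array([1.0, 0.5, 0.25])
        x = np.zeros(10)
        x[4] = 1.0
        out = causal_conv(x, taps)
        assert np.allclose(out[4:7], taps)
        assert np.all(out[:4] == 0)

    def test_strict_causality_under_perturbation(self, rng):
        taps = rng.standard_normal(5)
        x = rng.standard_normal(30)
        base = causal_conv(x, taps)
        x2 = x.copy()
        x2[17] += 10.0
        pert = causal_conv(x2, taps)
        assert np.array_equal(base[:17], pert[:17])

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal(60)
        taps = rng.standard_normal(9)
        assert np.max(np.abs(causal_conv(x, taps) - brute_force_conv(x, taps))) < 1e-10

    def test_kernel_longer_than_trial_rejected(self):
        with pytest.raises(ValueError):
            causal_conv(np.zeros(5), np.ones(6))


class TestGammaLayerForward:
    def test_single_pair_impulse_gives_kernel(self):
        rng = np.random.default_rng(3)
        layer = random_layer(rng, 1, 1, n_taps=10)
        x = np.zeros((1, 30, 1))
        x[0, 0, 0] = 1.0
        out = gamma_layer_forward(x, layer)
        assert np.allclose(out[0, :10, 0], gamma_taps(layer.filter_at(0, 0)))

    def test_linear_in_alpha(self, rng):
        layer = random_layer(rng, 2, 3)
        x = rng.standard_normal((2, 40, 2))
        base = gamma_layer_forward(x, layer)
        layer.alpha = 2.0 * layer.alpha
        assert np.allclose(gamma_layer_forward(x, layer), 2.0 * base)

    @pytest.mark.parametrize("d_in,d_out", [(1, 1), (3, 2), (4, 4)])
    def test_matches_per_pair_brute_force(self, rng, d_in, d_out):
        layer = random_layer(rng, d_in, d_out, n_taps=8)
        x = rng.standard_normal((2, 50, d_in))
        out = gamma_layer_forward(x, layer)
        expected = np.zeros_like(out)
        for trial in range(2):
            for j in range(d_out):
                for i in range(d_in):
                    expected[trial, :, j] += brute_force_conv(
                        x[trial, :, i], gamma_taps(layer.filter_at(i, j))
                    )
        assert np.max(np.abs(out - expected)) < 1e-10

    def test_shape_mismatch_rejected(self, rng):
        layer = random_layer(rng, 3, 2)
        with pytest.raises(ValueError):
            gamma_layer_forward(rng.standard_normal((1, 20, 4)), layer)


class TestParameterGradients:
    def test_zero_alpha_zeroes_shape_gradients(self, rng):
        layer = random_layer(rng, 2, 2)
        layer.alpha = np.zeros_like(layer.alpha)
        x = rng.standard_normal((1, 30, 2))

        def loss_fn(y):
            return np.sum(y**2), 2 * y

        grads = parameter_gradients(loss_fn, layer, x)
        assert np.all(grads["log_beta"] == 0)
        assert np.all(grads["log_t0"] == 0)

    def test_matches_central_differences(self, rng):
        layer = random_layer(rng, 3, 2, n_taps=12)
        x = rng.standard_normal((2, 40, 3))
        target = rng.standard_normal((2, 40, 2))

        def loss_fn(y):
            return np.sum((y - target) ** 2), 2 * (y - target)

        grads = parameter_gradients(loss_fn, layer, x)
        h = 1e-5
        for name in ("alpha", "log_beta", "log_t0"):
            arr = getattr(layer, name)
            for i in range(arr.shape[0]):
                for j in range(arr.shape[1]):
                    orig = arr[i, j]
                    arr[i, j] = orig + h
                    lp, _ = loss_fn(gamma_layer_forward(x, layer))
                    arr[i, j] = orig - h
                    lm, _ = loss_fn(gamma_layer_forward(x, layer))
                    arr[i, j] = orig
                    num = (lp - lm) / (2 * h)
                    rel = abs(grads[name][i, j] - num) / max(abs(num), 1e-8)
                    assert rel < 1e-4, f"{name}[{i},{j}]"

    def test_area_insensitive_to_log_beta(self):
        # area conservation: d(sum taps * dt)/d log_beta ~ 0 for contained kernels
        layer = GammaLayerParams(
            alpha=np.array([[1.0]]),
            log_beta=np.array([[-np.log(0.02)]]),
            log_t0=np.array([[np.log(0.02)]]),
            n_taps=200,
            dt=0.002,
        )
        x = np.zeros((1, 210, 1))
        x[0, 0, 0] = 1.0  # impulse: output integral = kernel area

        def loss_fn(y):
            return np.sum(y) * layer.dt, np.full_like(y, layer.dt)

        grads = parameter_gradients(loss_fn, layer, x)
        assert abs(grads["log_beta"][0, 0]) < 1e-3

    def test_backward_input_gradient_matches_fd(self, rng):
        layer = random_layer(rng, 2, 1, n_taps=6)
        x = rng.standard_normal((1, 20, 2))
        y = gamma_layer_forward(x, layer)
        gx, _ = gamma_layer_backward(x, layer, 2 * y)
        h = 1e-6
        for (t, b, c) in [(0, 3, 0), (0, 10, 1), (0, 19, 0)]:
            xp = x.copy()
            xp[t, b, c] += h
            lp = np.sum(gamma_layer_forward(xp, layer) ** 2)
            xp[t, b, c] -= 2 * h
            lm = np.sum(gamma_layer_forward(xp, layer) ** 2)
            num = (lp - lm) / (2 * h)
            assert gx[t, b, c] == pytest.approx(num, rel=1e-4, abs=1e-8)


def test_kernel_length_defaults():
    p = GammaFilterParams(alpha=1.0, log_beta=0.0, log_t0=np.log(0.01))
    assert p.n_taps == 30 and p.dt == 0.01  # 300 ms at 10 ms bins
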