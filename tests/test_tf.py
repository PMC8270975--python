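"""Unit tests for gamma-variate transfer functions: evaluation, prediction,
fitting, and state comparison."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from nvckit.synthdata import GroundTruth, make_calcium_trace, make_vascular_trace
from nvckit.tf import (
    DEFAULT_INIT,
    FitConfig,
    TransferFunction,
    TransferFunctionModel,
    compare_states,
    cross_predict,
    eval_tf,
    predict,
)

SMALL = FitConfig.small()


def noiseless_pair(truth=None, rate=10.0, duration=30.0):
    truth = truth or GroundTruth(noise_sd=0.0, vasomotion_amplitude=0.0)
    ca = make_calcium_trace(10.0, 5.0, rate, truth, duration=duration)
    va = make_vascular_trace(ca, truth)
    return truth, (ca.time, ca.value), (va.time, va.value)


class TestEval:
    def test_zero_before_onset(self):
        tf = TransferFunction(1.3, 0.5, 0.27, 0.19)
        t = np.array([0.0, 0.1, 0.27])
        assert np.all(eval_tf(tf, t) == 0.0)

    def test_nonnegative(self):
        tf = TransferFunction(2.0, 1.0, 0.3, 8.0)
        assert np.all(eval_tf(tf, np.linspace(0, 30, 3001)) >= 0.0)

    def test_analytic_mode(self):
        tf = TransferFunction(2.5, 1.5, 0.4, 3.0)
        t = np.arange(0, 20, 1e-4)
        assert t[np.argmax(eval_tf(tf, t))] == pytest.approx(tf.mode, abs=1e-4)

    def test_invalid_params_rejected(self):
        for bad in [(0.0, 1, 0, 1), (1, -1, 0, 1), (2, 1, -0.1, 1), (2, 1, 0, 0)]:
            with pytest.raises(ValueError):
                TransferFunction(*bad)

    def test_mass_is_gain(self):
        tf = TransferFunction(3.0, 0.7, 1.2, 5.5)
        val, _ = quad(lambda t: float(eval_tf(tf, np.array([t]))[0]),
                      tf.p3, tf.p3 + 80.0 * tf.p1 / tf.p2, limit=200)
        assert val == pytest.approx(tf.p4, rel=1e-6)

    def test_paper_initial_values_integral(self):
        tf = TransferFunction(*DEFAULT_INIT)
        t = np.arange(0.0, 120.0 + 5e-4, 1e-3)
        integral = np.trapezoid(eval_tf(tf, t), t)
        assert integral == pytest.approx(0.19, abs=1e-3)


class TestPredict:
    def test_impulse_response(self):
        tf = TransferFunction(2.0, 1.0, 0.3, 8.0)
        dt = 0.1
        t = np.arange(0, 20, dt)
        ca = np.zeros_like(t)
        ca[0] = 1.0
        out = predict(tf, (t, ca))
        k = tf.kernel(dt)
        n = min(k.size, out.size)
        assert np.allclose(out[:n], k[:n] * dt)
        assert np.allclose(out[k.size:], 0.0)

    def test_linearity(self):
        truth, ca, va = noiseless_pair()
        t, v = ca
        rng = np.random.default_rng(3)
        other = rng.normal(0, 1, size=v.size)
        tf = truth.tf
        both = predict(tf, (t, v + other))
        assert np.allclose(both, predict(tf, (t, v)) + predict(tf, (t, other)))

    def test_nonuniform_rejected(self):
        tf = TransferFunction(2.0, 1.0)
        with pytest.raises(ValueError, match="uniform"):
            predict(tf, (np.array([0.0, 0.1, 0.3]), np.zeros(3)))

    def test_quadrature_oracle(self):
        # discrete prediction at 100 Hz vs dense 1 kHz convolution
        truth = GroundTruth(noise_sd=0.0, vasomotion_amplitude=0.0)
        ca100 = make_calcium_trace(10.0, 5.0, 100.0, truth, duration=30.0)
        ca1k = make_calcium_trace(10.0, 5.0, 1000.0, truth, duration=30.0)
        pred = predict(truth.tf, ca100)
        dense = np.convolve(ca1k.value, truth.tf.kernel(1e-3))[: ca1k.value.size] * 1e-3
        oracle = dense[::10][: pred.size]
        assert np.max(np.abs(pred - oracle)) / np.max(np.abs(oracle)) < 0.01


class TestCrossPredict:
    def test_self_prediction(self):
        truth, ca, va = noiseless_pair()
        obs = predict(truth.tf, ca)
        res = cross_predict(truth.tf, ca, (ca[0], obs))
        assert res.scale == pytest.approx(1.0, rel=1e-12)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_scale(self):
        truth, ca, va = noiseless_pair()
        obs = 3.0 * predict(truth.tf, ca)
        res = cross_predict(truth.tf, ca, (ca[0], obs))
        assert res.scale == pytest.approx(3.0, rel=1e-12)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_brute_force_scale_oracle(self, rng):
        truth, ca, va = noiseless_pair()
        pred = predict(truth.tf, ca)
        obs = 2.2 * pred + rng.normal(0, 0.5, size=pred.size)
        res = cross_predict(truth.tf, ca, (ca[0], obs))

        def cost(a):
            return float(np.sum((obs - a * pred) ** 2))

        grid = np.linspace(0.0, 5.0, 2001)
        a0 = grid[np.argmin([cost(a) for a in grid])]
        ref = minimize_scalar(cost, bounds=(a0 - 0.01, a0 + 0.01), method="bounded",
                              options={"xatol": 1e-10})
        assert res.scale == pytest.approx(ref.x, abs=1e-6)

    def test_r_invariant_to_scale_and_offset(self, rng):
        truth, ca, va = noiseless_pair()
        obs = predict(truth.tf, ca) + rng.normal(0, 0.3, size=ca[0].size)
        r0 = cross_predict(truth.tf, ca, (ca[0], obs)).pearson_r
        r1 = cross_predict(truth.tf, ca, (ca[0], 4.0 * obs + 7.0)).pearson_r
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_prediction_rejected(self):
        tf = TransferFunction(2.0, 1.0, 0.3, 8.0)
        t = np.arange(0, 10, 0.1)
        with pytest.raises(ValueError, match="variance"):
            cross_predict(tf, (t, np.zeros_like(t)), (t, np.ones_like(t)))


class TestFit:
    def test_noiseless_recovery(self):
        truth, ca, va = noiseless_pair()
        fit = TransferFunctionModel(ca, va, config=SMALL).fit(seed=0)
        kt = truth.tf.kernel(0.01)
        kf = fit.tf.kernel(0.01)
        n = max(kt.size, kf.size)
        kt = np.pad(kt, (0, n - kt.size))
        kf = np.pad(kf, (0, n - kf.size))
        assert np.max(np.abs(kt - kf)) < 0.02 * kt.max()

    def test_determinism(self):
        truth, ca, va = noiseless_pair()
        f1 = TransferFunctionModel(ca, va, config=SMALL).fit(seed=7)
        f2 = TransferFunctionModel(ca, va, config=SMALL).fit(seed=7)
        assert np.array_equal(f1.params, f2.params)

    def test_gain_linearity(self):
        truth, ca, va = noiseless_pair()
        f1 = TransferFunctionModel(ca, va, config=SMALL).fit(seed=0)
        f2 = TransferFunctionModel(ca, (va[0], 2.0 * va[1]), config=SMALL).fit(seed=0)
        assert f2.tf.p4 == pytest.approx(2.0 * f1.tf.p4, rel=1e-3)
        for a, b in [(f2.tf.p1, f1.tf.p1), (f2.tf.p2, f1.tf.p2), (f2.tf.p3, f1.tf.p3)]:
            assert a == pytest.approx(b, rel=1e-3, abs=1e-3)

    def test_zero_variance_rejected(self):
        t = np.arange(0, 10, 0.1)
        with pytest.raises(ValueError, match="variance"):
            TransferFunctionModel((t, np.sin(t)), (t, np.ones_like(t)))

    def test_mismatched_base_rejected(self):
        t = np.arange(0, 10, 0.1)
        t2 = np.arange(0, 5, 0.05)
        with pytest.raises(ValueError, match="time base"):
            TransferFunctionModel((t, np.sin(t)), (t2, np.sin(t2)))

    def test_fitted_params_within_bounds(self):
        truth, ca, va = noiseless_pair()
        fit = TransferFunctionModel(ca, va, config=SMALL).fit(seed=0)
        for p, (lo, hi) in zip(fit.params, SMALL.bounds):
            assert lo <= p <= hi

    def test_summary_and_json(self, tmp_path):
        truth, ca, va = noiseless_pair()
        fit = TransferFunctionModel(ca, va, config=SMALL).fit(seed=0)
        assert "kernel mode" in fit.summary()
        path = tmp_path / "tf.json"
        fit.to_json(path)
        loaded = TransferFunction.from_dict(
            __import__("json").load(open(path))
        )
        assert loaded.p1 == pytest.approx(fit.tf.p1)


class TestCompareStates:
    def test_identical_tfs_identical_r(self):
        truth, ca, va = noiseless_pair()
        tf = truth.tf
        df = compare_states(tf, tf, [ca], [va])
        assert df.loc[0, "r_a"] == df.loc[0, "r_b"]
        assert df.loc[0, "slope_a"] == df.loc[0, "slope_b"]

    def test_swapping_tfs_swaps_columns(self):
        fast = GroundTruth(tf_params=(1.6, 2.5, 0.15, 6.0), noise_sd=0.0,
                           vasomotion_amplitude=0.0)
        slow = GroundTruth(tf_params=(2.0, 0.8, 0.6, 8.0), noise_sd=0.0,
                           vasomotion_amplitude=0.0)
        _, ca, va = noiseless_pair(fast)
        d1 = compare_states(fast.tf, slow.tf, [ca], [va])
        d2 = compare_states(slow.tf, fast.tf, [ca], [va])
        assert d1.loc[0, "r_a"] == d2.loc[0, "r_b"]
        assert d1.loc[0, "slope_b"] == d2.loc[0, "slope_a"]

    def test_self_prediction_ceiling(self):
        # TF fitted on its own pair predicts it at least as well as a TF
        # fitted on a different-state pair (Fig. 4e vs 4g pattern).
        fast = GroundTruth(tf_params=(1.6, 2.5, 0.15, 6.0), noise_sd=0.0,
                           vasomotion_amplitude=0.0)
        slow = GroundTruth(tf_params=(2.0, 0.8, 0.6, 8.0), noise_sd=0.0,
                           vasomotion_amplitude=0.0)
        _, ca_f, va_f = noiseless_pair(fast)
        _, ca_s, va_s = noiseless_pair(slow)
        tf_fast = TransferFunctionModel(ca_f, va_f, config=SMALL).fit(seed=1).tf
        tf_slow = TransferFunctionModel(ca_s, va_s, config=SMALL).fit(seed=2).tf
        r_self = cross_predict(tf_fast, ca_f, va_f).pearson_r
        r_cross = cross_predict(tf_slow, ca_f, va_f).pearson_r
        assert r_self >= r_cross
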