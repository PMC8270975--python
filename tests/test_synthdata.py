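"""Unit tests for the synthetic-data generator."""

import numpy as np
import pytest
from dataclasses import replace

from nvckit.kymo import extract_diameter
from nvckit.synthdata import (
    GroundTruth,
    make_calcium_trace,
    make_trial_set,
    make_vascular_trace,
    read_trial_set,
    render_kymograph,
    write_trial_set,
)
from nvckit.trials import TrialTrace


class TestGroundTruth:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GroundTruth(tf_params=(0.9, 1.0, 0.3, 1.0))  # p1 <= 1
        with pytest.raises(ValueError):
            GroundTruth(tf_params=(2.0, -1.0, 0.3, 1.0))
        with pytest.raises(ValueError):
            GroundTruth(vasomotion_freq=1.5)
        with pytest.raises(ValueError):
            GroundTruth(noise_sd=-0.1)
        with pytest.raises(ValueError):
            GroundTruth(tau_rise=0.0)

    def test_round_trips_dict(self):
        gt = GroundTruth(seed=9)
        d = gt.to_dict()
        d["tf_params"] = tuple(d["tf_params"])
        assert GroundTruth(**d) == gt


class TestCalciumTrace:
    def test_null_response(self):
        truth = GroundTruth(ca_peak_amplitude=0.0, noise_sd=0.0)
        tr = make_calcium_trace(10.0, 5.0, 10.0, truth)
        assert np.allclose(tr.value, 0.0)

    def test_peak_equals_amplitude(self):
        truth = GroundTruth(ca_peak_amplitude=2.5, noise_sd=0.0)
        tr = make_calcium_trace(10.0, 5.0, 10.0, truth)
        assert tr.value.max() == pytest.approx(2.5, abs=1e-9)

    def test_baseline_zero(self):
        truth = GroundTruth(noise_sd=0.0)
        tr = make_calcium_trace(10.0, 5.0, 10.0, truth)
        assert np.allclose(tr.value[tr.time < 10.0 + truth.ca_onset], 0.0)

    def test_seed_determinism(self):
        truth = GroundTruth(seed=42)
        a = make_calcium_trace(10.0, 5.0, 10.0, truth)
        b = make_calcium_trace(10.0, 5.0, 10.0, truth)
        assert np.array_equal(a.value, b.value)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            make_calcium_trace(10.0, 5.0, -1.0, GroundTruth())
        with pytest.raises(ValueError):
            make_calcium_trace(10.0, -5.0, 10.0, GroundTruth())


class TestVascularTrace:
    def test_impulse_response(self):
        truth = GroundTruth(noise_sd=0.0, vasomotion_amplitude=0.0)
        dt = 0.1
        t = np.arange(0.0, 30.0, dt)
        v = np.zeros_like(t)
        v[50] = 1.0  # impulse at t0 = 5 s
        ca = TrialTrace(time=t, value=v, stim_onset=5.0, stim_duration=1.0,
                        baseline_window=(0.0, 5.0), modality="calcium")
        out = make_vascular_trace(ca, truth)
        k = truth.tf.kernel(dt)
        n = min(k.size, t.size - 50)
        assert np.allclose(out.value[50:50 + n], k[:n] * dt)
        assert np.allclose(out.value[:50], 0.0)

    def test_constant_steady_state(self):
        truth = GroundTruth(noise_sd=0.0, vasomotion_amplitude=0.0)
        t = np.arange(0.0, 60.0, 0.1)
        ca = TrialTrace(time=t, value=np.full_like(t, 2.0), stim_onset=50.0,
                        stim_duration=1.0, baseline_window=(0.0, 50.0),
                        modality="calcium")
        out = make_vascular_trace(ca, truth)
        # kernel integrates to p4 -> steady state c * p4
        assert out.value[-1] == pytest.approx(2.0 * truth.tf.p4, rel=1e-2)

    def test_linearity(self):
        truth = GroundTruth(noise_sd=0.0, vasomotion_amplitude=0.0)
        ca = make_calcium_trace(10.0, 5.0, 10.0, truth, duration=30.0)
        out1 = make_vascular_trace(ca, truth).value
        ca3 = TrialTrace(time=ca.time, value=3.0 * ca.value, stim_onset=10.0,
                         stim_duration=5.0, baseline_window=ca.baseline_window,
                         modality="calcium")
        out3 = make_vascular_trace(ca3, truth).value
        assert np.allclose(out3, 3.0 * out1)

    def test_nonnegative_for_nonnegative_ca(self):
        truth = GroundTruth(noise_sd=0.0, vasomotion_amplitude=0.0)
        ca = make_calcium_trace(10.0, 5.0, 10.0, truth, duration=30.0)
        assert np.all(make_vascular_trace(ca, truth).value >= 0.0)


class TestTrialSet:
    def test_shared_timing_and_count(self):
        ts = make_trial_set(5, "diameter", GroundTruth(seed=1))
        assert len(ts.trials) == 5
        for tr in ts.trials:
            assert tr.stim_onset == ts.trials[0].stim_onset
            assert tr.dt == ts.trials[0].dt

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            make_trial_set(0, "diameter", GroundTruth())

    def test_seed_determinism(self):
        a = make_trial_set(3, "diameter", GroundTruth(seed=7))
        b = make_trial_set(3, "diameter", GroundTruth(seed=7))
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.value, tb.value)

    def test_baseline_offset(self):
        ts = make_trial_set(2, "diameter", GroundTruth(noise_sd=0.0, seed=1),
                            baseline_offset=10.0)
        for tr in ts.trials:
            assert tr.baseline_mean() == pytest.approx(10.0, abs=1.0)

    def test_csv_round_trip(self, tmp_path):
        ts = make_trial_set(3, "calcium", GroundTruth(seed=2))
        path = tmp_path / "trials.csv"
        write_trial_set(ts, path)
        back = read_trial_set(path)
        assert back.modality == "calcium"
        assert back.truth == ts.truth
        assert len(back.trials) == 3
        for ta, tb in zip(ts.trials, back.trials):
            assert np.allclose(ta.value, tb.value)
            assert ta.stim_onset == tb.stim_onset


class TestRenderKymograph:
    def test_diameter_plateau_fwhm(self):
        # constant 4 um vessel at dx = 0.2 -> FWHM 20 px (within blur)
        t = np.arange(0.0, 0.6, 0.1)
        tr = TrialTrace(time=t, value=np.full_like(t, 4.0), stim_onset=0.4,
                        stim_duration=0.1, baseline_window=(0.0, 0.4))
        truth = GroundTruth(noise_sd=0.0, vasomotion_amplitude=0.0)
        k = render_kymograph(tr, None, dx=0.2, dt_line=0.001, truth=truth,
                             mode="diameter", duration=0.2)
        m = extract_diameter(k)
        assert np.nanmedian(m.value) / 0.2 == pytest.approx(20.0, abs=1.0)

    def test_intensity_range(self):
        t = np.arange(0.0, 0.6, 0.1)
        tr = TrialTrace(time=t, value=np.full_like(t, 4.0), stim_onset=0.4,
                        stim_duration=0.1, baseline_window=(0.0, 0.4))
        truth = GroundTruth(noise_sd=0.0, vasomotion_amplitude=0.0)
        k = render_kymograph(tr, None, dx=0.2, dt_line=0.001, truth=truth,
                             mode="diameter", duration=0.2)
        assert k.image.min() >= 0.0 and k.image.max() <= 1.0

    def test_shadow_advance_per_line(self):
        # constant velocity v: line j+1 equals line j shifted by v * dt_line
        v = 2.0  # mm/s -> 2 um per 1 ms line
        t = np.arange(0.0, 0.6, 0.1)
        tr = TrialTrace(time=t, value=np.full_like(t, v), stim_onset=0.4,
                        stim_duration=0.1, baseline_window=(0.0, 0.4),
                        modality="velocity")
        truth = GroundTruth(noise_sd=0.0, vasomotion_amplitude=0.0)
        k = render_kymograph(None, tr, dx=0.2, dt_line=0.001, truth=truth,
                             mode="velocity", duration=0.1)
        x = (np.arange(k.image.shape[1]) + 0.5) * k.dx
        shift = v * k.dt_line * 1000.0  # um per line
        for j in (10, 40, 70):
            expected = np.interp(x - shift, x, k.image[j])
            interior = slice(20, -20)
            assert np.max(np.abs(k.image[j + 1][interior] - expected[interior])) < 0.02

    def test_diameter_exceeding_scan_rejected(self):
        t = np.arange(0.0, 0.6, 0.1)
        tr = TrialTrace(time=t, value=np.full_like(t, 50.0), stim_onset=0.4,
                        stim_duration=0.1, baseline_window=(0.0, 0.4))
        with pytest.raises(ValueError, match="scan"):
            render_kymograph(tr, None, dx=0.2, dt_line=0.001,
                             truth=GroundTruth(), mode="diameter",
                             scan_length_um=20.0)

    def test_missing_trace_rejected(self):
        with pytest.raises(ValueError, match="requires"):
            render_kymograph(None, None, dx=0.2, dt_line=0.001,
                             truth=GroundTruth(), mode="diameter")
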