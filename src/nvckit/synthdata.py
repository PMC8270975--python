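"""Synthetic neurovascular data with known ground truth.

Every downstream stage of the analysis (kymograph extraction, z-scoring,
sigmoid onsets, transfer-function fitting, vasomotion) is validated by
recovery against data generated here:

* stimulus-locked neuronal Ca2+ transients (double-exponential kinetics,
  boxcar-driven for the stimulus duration, GCaMP6-like);
* vascular responses as the causal convolution of the Ca2+ trace with a
  known gamma-variate transfer function, plus a low-frequency (~0.1 Hz)
  vasomotion sinusoid of controlled amplitude/phase and additive Gaussian
  noise;
* line-scan kymographs containing a vessel of pulsating width (diameter
  mode) or moving RBC shadow streaks of prescribed slope (velocity mode).

Identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .kymo import Kymograph
from .tf import TransferFunction
from .trials import TrialTrace

__all__ = [
    "GroundTruth",
    "SyntheticTrialSet",
    "make_calcium_trace",
    "make_vascular_trace",
    "make_trial_set",
    "render_kymograph",
    "write_trial_set",
    "read_trial_set",
]


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters shared by all synthetic outputs.

    tf_params : (p1, p2, p3, p4)
        Gamma-variate transfer function: shape (>1), rate (1/s),
        delay (s, >=0), gain (>0).
    ca_onset : s
        Delay from stimulus onset to the Ca2+ rise.
    ca_peak_amplitude : dimensionless
        Peak of the noiseless Ca2+ transient.
    vasomotion_amplitude : percent of baseline
        Amplitude of the vasomotion sinusoid added to vascular traces.
    vasomotion_freq : Hz, within (0.02, 1)
    vasomotion_phase : radians
    noise_sd : signal units
        SD of the additive i.i.d. Gaussian noise.
    tau_rise, tau_decay : s
        Double-exponential Ca2+ kinetics (GCaMP6-like defaults).
    """

    tf_params: tuple[float, float, float, float] = (2.0, 1.0, 0.3, 8.0)
    ca_onset: float = 0.1
    ca_peak_amplitude: float = 1.0
    vasomotion_amplitude: float = 2.0
    vasomotion_freq: float = 0.1
    vasomotion_phase: float = 0.0
    noise_sd: float = 0.3
    seed: int = 0
    tau_rise: float = 0.2
    tau_decay: float = 1.0

    def __post_init__(self) -> None:
        p1, p2, p3, p4 = self.tf_params
        if not (p1 > 1 and p2 > 0 and p3 >= 0 and p4 > 0):
            raise ValueError("tf_params must satisfy p1>1, p2>0, p3>=0, p4>0")
        if not (0.02 < self.vasomotion_freq < 1.0):
            raise ValueError("vasomotion_freq must lie within (0.02, 1) Hz")
        if self.noise_sd < 0 or self.vasomotion_amplitude < 0:
            raise ValueError("noise_sd and vasomotion_amplitude must be >= 0")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")

    @property
    def tf(self) -> TransferFunction:
        return TransferFunction(*self.tf_params)

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTrialSet:
    """A set of trials generated from one ground truth."""

    trials: list[TrialTrace]
    truth: GroundTruth
    modality: str

    def __post_init__(self) -> None:
        if len(self.trials) < 1:
            raise ValueError("a trial set needs at least one trial")
        t0 = self.trials[0]
        for t in self.trials[1:]:
            if not (
                np.isclose(t.dt, t0.dt)
                and np.isclose(t.stim_onset, t0.stim_onset)
                and np.isclose(t.stim_duration, t0.stim_duration)
            ):
                raise ValueError("trials must share sampling rate and stimulus timing")


def _ca_waveform(
    time: np.ndarray,
    stim_onset: float,
    stim_duration: float,
    truth: GroundTruth,
) -> np.ndarray:
    """Noiseless Ca2+ transient: boxcar drive convolved with a
    double-exponential kernel, peak-normalized to ca_peak_amplitude."""
    dt = time[1] - time[0]
    t0 = stim_onset + truth.ca_onset
    tau = np.arange(0.0, stim_duration + 8.0 * truth.tau_decay, dt)
    kern = np.exp(-tau / truth.tau_decay) - np.exp(-tau / truth.tau_rise)
    drive = ((time >= t0) & (time < t0 + stim_duration)).astype(float)
    resp = np.convolve(drive, kern)[: time.size] * dt
    peak = resp.max()
    if peak > 0 and truth.ca_peak_amplitude != 0:
        resp = resp * (truth.ca_peak_amplitude / peak)
    else:
        resp = np.zeros_like(resp)
    return resp


def make_calcium_trace(
    stim_onset: float,
    stim_duration: float,
    rate: float,
    truth: GroundTruth,
    duration: float | None = None,
    baseline_window: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> TrialTrace:
    """Stimulus-locked GCaMP6-like trial trace.

    Baseline-zero-mean apart from noise; rises after ``stim_onset`` (plus the
    ground truth's Ca2+ onset delay) with double-exponential kinetics scaled
    to ``truth.ca_peak_amplitude``.
    """
    if rate <= 0 or stim_duration <= 0:
        raise ValueError("rate and stim_duration must be positive")
    if duration is None:
        duration = stim_onset + stim_duration + 15.0
    dt = 1.0 / rate
    time = np.arange(0.0, duration, dt)
    if baseline_window is None:
        baseline_window = (0.0, stim_onset)
    if stim_onset < baseline_window[1] - 1e-12 or stim_onset <= 0:
        raise ValueError("stim_onset must come after the baseline window")
    value = _ca_waveform(time, stim_onset, stim_duration, truth)
    if truth.noise_sd > 0:
        rng = rng or truth.rng(stream=1)
        value = value + rng.normal(0.0, truth.noise_sd, size=time.size)
    return TrialTrace(
        time=time,
        value=value,
        stim_onset=stim_onset,
        stim_duration=stim_duration,
        baseline_window=baseline_window,
        modality="calcium",
    )


def make_vascular_trace(
    ca: TrialTrace,
    truth: GroundTruth,
    modality: str = "diameter",
    rng: np.random.Generator | None = None,
    vasomotion_phase: float | None = None,
) -> TrialTrace:
    """Vascular trace = conv(Ca2+, TF) + vasomotion sinusoid + noise.

    The convolution is causal and scaled by the sample interval, so a unit
    impulse in ``ca`` returns the kernel samples times dt and the steady-state
    response to a constant c is c * p4 (the kernel integrates to its gain).
    """
    kernel = truth.tf.kernel(ca.dt)
    evoked = np.convolve(ca.value, kernel)[: ca.time.size] * ca.dt
    phase = truth.vasomotion_phase if vasomotion_phase is None else vasomotion_phase
    vaso = truth.vasomotion_amplitude * np.sin(
        2.0 * np.pi * truth.vasomotion_freq * ca.time + phase
    )
    value = evoked + vaso
    if truth.noise_sd > 0:
        rng = rng or truth.rng(stream=2)
        value = value + rng.normal(0.0, truth.noise_sd, size=value.size)
    return TrialTrace(
        time=ca.time,
        value=value,
        stim_onset=ca.stim_onset,
        stim_duration=ca.stim_duration,
        baseline_window=ca.baseline_window,
        modality=modality,
    )


def make_trial_set(
    n_trials: int,
    modality: str,
    truth: GroundTruth,
    stim_onset: float = 10.0,
    stim_duration: float = 5.0,
    rate: float = 10.0,
    duration: float | None = None,
    baseline_offset: float = 0.0,
    amplitude_jitter_sd: float = 0.0,
    adaptation_decay: float = 0.0,
    randomize_phase: bool = True,
) -> SyntheticTrialSet:
    """Generate ``n_trials`` trials of one modality from shared ground truth.

    ``baseline_offset`` adds a constant resting level (e.g. a resting
    diameter in um) so percent-change normalization is meaningful;
    ``amplitude_jitter_sd`` draws a per-trial multiplicative response
    amplitude jitter ~ N(1, sd); ``adaptation_decay`` shrinks the evoked
    amplitude by that fraction on each successive trial.  The vasomotion
    phase is drawn uniformly per trial unless ``randomize_phase`` is False.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = np.random.SeedSequence((truth.seed, 1000))
    children = ss.spawn(n_trials)
    trials: list[TrialTrace] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        gain = 1.0
        if amplitude_jitter_sd > 0:
            gain *= max(rng.normal(1.0, amplitude_jitter_sd), 0.0)
        if adaptation_decay > 0:
            gain *= (1.0 - adaptation_decay) ** i
        trial_truth = replace(
            truth, ca_peak_amplitude=truth.ca_peak_amplitude * gain
        )
        ca = make_calcium_trace(
            stim_onset, stim_duration, rate, trial_truth, duration=duration, rng=rng
        )
        if modality == "calcium":
            trace = ca
        else:
            ca_clean = make_calcium_trace(
                stim_onset, stim_duration, rate,
                replace(trial_truth, noise_sd=0.0), duration=duration,
            )
            phase = rng.uniform(0, 2 * np.pi) if randomize_phase else None
            trace = make_vascular_trace(
                ca_clean, trial_truth, modality=modality, rng=rng,
                vasomotion_phase=phase,
            )
        if baseline_offset:
            trace = TrialTrace(
                time=trace.time,
                value=trace.value + baseline_offset,
                stim_onset=trace.stim_onset,
                stim_duration=trace.stim_duration,
                baseline_window=trace.baseline_window,
                modality=trace.modality,
            )
        trials.append(trace)
    return SyntheticTrialSet(trials=trials, truth=truth, modality=modality)


# ---------------------------------------------------------------------------
# kymograph rendering

def render_kymograph(
    diameter_t: TrialTrace | None,
    velocity_t: TrialTrace | None,
    dx: float,
    dt_line: float,
    truth: GroundTruth,
    mode: str = "diameter",
    scan_length_um: float | None = None,
    duration: float | None = None,
    edge_blur_um: float = 0.3,
    shadow_spacing_um: float = 8.0,
    shadow_width_um: float = 1.5,
) -> Kymograph:
    """Render a synthetic line-scan kymograph.

    Diameter mode: each scan line (perpendicular to the vessel) is a bright
    plateau of the instantaneous width with Gaussian-blurred edges on a dark
    background.  Velocity mode: the line runs along the vessel; the bright
    plasma carries dark RBC shadow streaks whose slope equals the
    instantaneous velocity (distance per line time).  Intensities lie in
    [0, 1] before noise.
    """
    if dx <= 0 or dt_line <= 0:
        raise ValueError("dx and dt_line must be positive")
    src = diameter_t if mode == "diameter" else velocity_t
    if src is None:
        raise ValueError(f"{mode} mode requires the corresponding trace")
    if duration is None:
        duration = float(src.time[-1])
    n_lines = int(round(duration / dt_line))
    t_lines = np.arange(n_lines) * dt_line
    rng = truth.rng(stream=3)

    if mode == "diameter":
        d = np.interp(t_lines, src.time, src.value)
        if scan_length_um is None:
            scan_length_um = 2.5 * float(np.nanmax(d))
        if np.nanmax(d) >= scan_length_um:
            raise ValueError("diameter exceeds the scan length")
        n_px = int(round(scan_length_um / dx))
        x = (np.arange(n_px) + 0.5) * dx
        center = scan_length_um / 2.0
        s2 = edge_blur_um * np.sqrt(2.0)
        left = (center - d / 2.0)[:, None]
        right = (center + d / 2.0)[:, None]
        img = 0.45 * (erf((x[None, :] - left) / s2) - erf((x[None, :] - right) / s2))
        img = np.clip(img + 0.05, 0.0, 1.0)
    else:
        v = np.interp(t_lines, src.time, src.value)  # mm/s
        if scan_length_um is None:
            scan_length_um = 100.0
        n_px = int(round(scan_length_um / dx))
        x = (np.arange(n_px) + 0.5) * dx
        # cumulative displacement in um (mm/s * s * 1000)
        disp = np.concatenate([[0.0], np.cumsum(v[:-1] * dt_line)]) * 1000.0
        # Shadows ride a fixed random dip pattern that slides by disp(t):
        # line j at position x samples the pattern at u = x - disp_j, so a
        # shadow at x on line i reappears at x + v*dt_line on line i+1.  New
        # cells enter the scan from the pattern's tails (no wrap-around).
        u_lo = -disp.max() - 3 * shadow_width_um
        u_hi = scan_length_um - disp.min() + 3 * shadow_width_um
        n_shadows = max(2, int(round((u_hi - u_lo) / shadow_spacing_um)))
        centers = rng.uniform(u_lo, u_hi, size=n_shadows)
        u_grid = np.arange(u_lo, u_hi + dx, dx)
        pattern = np.zeros_like(u_grid)
        sw2 = 2.0 * shadow_width_um**2
        for c in centers:
            lo = np.searchsorted(u_grid, c - 5 * shadow_width_um)
            hi = np.searchsorted(u_grid, c + 5 * shadow_width_um)
            pattern[lo:hi] += np.exp(-((u_grid[lo:hi] - c) ** 2) / sw2)
        pattern = np.minimum(pattern, 1.0)
        img = np.empty((n_lines, n_px))
        for j in range(n_lines):
            img[j] = 0.85 - 0.7 * np.interp(x - disp[j], u_grid, pattern)
        img = np.clip(img, 0.0, 1.0)

    if truth.noise_sd > 0:
        img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)
    return Kymograph(image=img, dt_line=dt_line, dx=dx, mode=mode)


# ---------------------------------------------------------------------------
# I/O

def write_trial_set(ts: SyntheticTrialSet, csv_path, sidecar_path=None) -> None:
    """Long-format CSV (trial_id, time_s, value) + JSON sidecar with the
    ground truth and stimulus metadata."""
    frames = [
        pd.DataFrame({"trial_id": i, "time_s": t.time, "value": t.value})
        for i, t in enumerate(ts.trials)
    ]
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    sidecar_path = sidecar_path or str(csv_path) + ".json"
    t0 = ts.trials[0]
    meta = {
        "truth": ts.truth.to_dict(),
        "modality": ts.modality,
        "stim_onset": t0.stim_onset,
        "stim_duration": t0.stim_duration,
        "baseline_window": list(t0.baseline_window),
        "rate_hz": t0.rate,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def read_trial_set(csv_path, sidecar_path=None) -> SyntheticTrialSet:
    sidecar_path = sidecar_path or str(csv_path) + ".json"
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    df = pd.read_csv(csv_path)
    truth_d = dict(meta["truth"])
    truth_d["tf_params"] = tuple(truth_d["tf_params"])
    truth = GroundTruth(**truth_d)
    trials = []
    for _, grp in df.groupby("trial_id", sort=True):
        trials.append(
            TrialTrace(
                time=grp["time_s"].to_numpy(),
                value=grp["value"].to_numpy(),
                stim_onset=meta["stim_onset"],
                stim_duration=meta["stim_duration"],
                baseline_window=tuple(meta["baseline_window"]),
                modality=meta["modality"],
            )
        )
    return SyntheticTrialSet(trials=trials, truth=truth, modality=meta["modality"])
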