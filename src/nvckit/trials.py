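"""Trial traces and their normalizations.

A :class:`TrialTrace` is one trial of a uniformly sampled signal (neuronal
Ca2+ fluorescence, vessel diameter, or RBC velocity) together with its
stimulus timing and baseline window.  The functions in this module implement
the per-trial representations used throughout the analysis:

* ``delta_f``       -- baseline-subtracted fluorescence, dF = F - F0
* ``percent_change``-- 100 * (value - baseline mean) / baseline mean
* ``zscore_trial``  -- (value - baseline mean) / baseline sample SD
* ``average_trials``-- pointwise mean with SEM across z-scored trials
* ``intertrial_variability`` / ``adaptation_check`` -- response-amplitude
  statistics across repeated stimulus presentations

All windows are half-open ``[start, end)`` in seconds from trial start.
Missing samples (NaN, e.g. quality-0 kymograph lines) are excluded from
baseline statistics and linearly interpolated for trace arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TrialTrace",
    "ZScoredTrial",
    "MeanTrace",
    "delta_f",
    "percent_change",
    "zscore_trial",
    "average_trials",
    "response_amplitude",
    "intertrial_variability",
    "adaptation_check",
]

_UNIFORMITY_RTOL = 1e-6

MODALITIES = ("calcium", "diameter", "velocity")
COMPARTMENTS = (
    "pial",
    "penetrating",
    "first_order",
    "second_order",
    "third_order",
    "capillary_ge4",
)


def _check_uniform(time: np.ndarray) -> float:
    if time.size < 2:
        raise ValueError("trace needs at least 2 samples")
    dt = np.diff(time)
    dt0 = float(dt[0])
    if dt0 <= 0 or not np.allclose(dt, dt0, rtol=_UNIFORMITY_RTOL, atol=0):
        raise ValueError("time base must be uniform and increasing")
    return dt0


@dataclass
class TrialTrace:
    """One trial's uniformly sampled signal with stimulus metadata.

    Parameters
    ----------
    time : array of float
        Sample times in seconds from trial start, uniformly spaced.
    value : array of float
        Signal samples.  NaN marks missing samples.
    stim_onset, stim_duration : float
        Stimulus timing in seconds.
    baseline_window : (float, float)
        Half-open window ``[start, end)`` used for baseline statistics;
        must end at or before ``stim_onset``.
    modality : str
        One of ``calcium``, ``diameter``, ``velocity``.
    """

    time: np.ndarray
    value: np.ndarray
    stim_onset: float
    stim_duration: float
    baseline_window: tuple[float, float]
    modality: str = "diameter"
    compartment: str | None = None
    arbor_id: str | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value must have equal length")
        self._dt = _check_uniform(self.time)
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be positive")
        b0, b1 = self.baseline_window
        if not b0 < b1:
            raise ValueError("baseline_window must be a nonempty interval")
        if b1 > self.stim_onset + 1e-12:
            raise ValueError("baseline_window must end at or before stim_onset")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def dt(self) -> float:
        return self._dt

    @property
    def rate(self) -> float:
        return 1.0 / self._dt

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        start, end = window
        return (self.time >= start - 1e-12) & (self.time < end - 1e-12)

    def baseline_values(self) -> np.ndarray:
        vals = self.value[self.window_mask(self.baseline_window)]
        if vals.size == 0:
            raise ValueError("baseline window contains no samples")
        return vals

    def baseline_mean(self) -> float:
        vals = self.baseline_values()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("baseline window contains no finite samples")
        return float(np.mean(vals))

    def baseline_sd(self) -> float:
        """Sample SD (n-1 denominator) of finite baseline samples."""
        vals = self.baseline_values()
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise ValueError("baseline needs >= 2 finite samples")
        return float(np.std(vals, ddof=1))

    def filled(self) -> "TrialTrace":
        """Copy with missing samples linearly interpolated."""
        v = self.value
        bad = ~np.isfinite(v)
        if not bad.any():
            return self
        if bad.all():
            raise ValueError("trace has no finite samples")
        v = v.copy()
        good = ~bad
        v[bad] = np.interp(self.time[bad], self.time[good], v[good])
        return replace(self, value=v)

    def response_window(self, pad_s: float = 2.0) -> tuple[float, float]:
        """Default window for response amplitudes: stimulus onset to
        stimulus offset plus ``pad_s`` seconds."""
        return (self.stim_onset, self.stim_onset + self.stim_duration + pad_s)


@dataclass
class ZScoredTrial:
    """A trial normalized by its baseline mean and sample SD."""

    time: np.ndarray
    z: np.ndarray
    baseline_mean: float
    baseline_sd: float
    stim_onset: float
    stim_duration: float
    baseline_window: tuple[float, float]
    modality: str = "diameter"
    compartment: str | None = None
    arbor_id: str | None = None

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        start, end = window
        return (self.time >= start - 1e-12) & (self.time < end - 1e-12)

    def response_window(self, pad_s: float = 2.0) -> tuple[float, float]:
        return (self.stim_onset, self.stim_onset + self.stim_duration + pad_s)


@dataclass
class MeanTrace:
    """Pointwise mean across z-scored trials with per-sample SEM."""

    time: np.ndarray
    z: np.ndarray
    sem: np.ndarray
    n: int
    stim_onset: float
    stim_duration: float
    baseline_window: tuple[float, float]
    modality: str = "diameter"
    compartment: str | None = None
    arbor_id: str | None = None


def delta_f(trace: TrialTrace) -> TrialTrace:
    """Baseline subtraction, dF = F - F0 with F0 the baseline mean."""
    f0 = trace.baseline_mean()
    return replace(trace, value=trace.value - f0)


def percent_change(trace: TrialTrace) -> TrialTrace:
    """Percent change from the baseline mean.

    Raises ``ValueError`` when the baseline mean is zero (the trace carries
    no usable baseline level to normalize by).
    """
    f0 = trace.baseline_mean()
    if f0 == 0.0:
        raise ValueError("baseline mean is zero; percent change undefined")
    return replace(trace, value=100.0 * (trace.value - f0) / f0)


def zscore_trial(trace: TrialTrace) -> ZScoredTrial:
    """z-score a single trial against its baseline window.

    z(t) = (value(t) - baseline mean) / baseline sample SD, where the SD
    uses the n-1 denominator.  A flat baseline (SD = 0) is an error.
    """
    mu = trace.baseline_mean()
    sd = trace.baseline_sd()
    if sd == 0.0:
        raise ValueError("baseline SD is zero; trace cannot be z-scored")
    return ZScoredTrial(
        time=trace.time,
        z=(trace.value - mu) / sd,
        baseline_mean=mu,
        baseline_sd=sd,
        stim_onset=trace.stim_onset,
        stim_duration=trace.stim_duration,
        baseline_window=trace.baseline_window,
        modality=trace.modality,
        compartment=trace.compartment,
        arbor_id=trace.arbor_id,
    )


def _check_common_base(trials: Sequence[ZScoredTrial]) -> None:
    t0 = trials[0]
    for t in trials[1:]:
        if t.time.shape != t0.time.shape or not np.allclose(
            t.time, t0.time, rtol=_UNIFORMITY_RTOL, atol=1e-9
        ):
            raise ValueError("trials do not share a common time base")
        if not (
            np.isclose(t.stim_onset, t0.stim_onset)
            and np.isclose(t.stim_duration, t0.stim_duration)
        ):
            raise ValueError("trials do not share stimulus timing")


def average_trials(trials: Sequence[ZScoredTrial]) -> MeanTrace:
    """Pointwise mean and SEM (SD/sqrt(n)) across z-scored trials."""
    if len(trials) == 0:
        raise ValueError("no trials to average")
    _check_common_base(trials)
    zs = np.vstack([t.z for t in trials])
    n = len(trials)
    mean = np.nanmean(zs, axis=0)
    if n > 1:
        sem = np.nanstd(zs, axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    t0 = trials[0]
    return MeanTrace(
        time=t0.time,
        z=mean,
        sem=sem,
        n=n,
        stim_onset=t0.stim_onset,
        stim_duration=t0.stim_duration,
        baseline_window=t0.baseline_window,
        modality=t0.modality,
        compartment=t0.compartment,
        arbor_id=t0.arbor_id,
    )


def response_amplitude(
    trial: ZScoredTrial, response_window: tuple[float, float] | None = None
) -> float:
    """Response amplitude: maximum of z within the response window."""
    window = response_window or trial.response_window()
    vals = trial.z[trial.window_mask(window)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("response window contains no finite samples")
    return float(np.max(vals))


def intertrial_variability(
    trials: Sequence[ZScoredTrial],
    response_window: tuple[float, float] | None = None,
) -> float:
    """Sample SD of per-trial response amplitudes across trials."""
    if len(trials) < 2:
        raise ValueError("need >= 2 trials for inter-trial variability")
    amps = [response_amplitude(t, response_window) for t in trials]
    return float(np.std(amps, ddof=1))


def adaptation_check(
    trials: Sequence[ZScoredTrial],
    k: int = 3,
    response_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Response amplitudes of the first ``k`` trials, in presentation order.

    Used to assess trial-to-trial adaptation by comparing the amplitudes of
    the first stimulus presentations.
    """
    if len(trials) < k:
        raise ValueError(f"need >= {k} trials, got {len(trials)}")
    return np.array(
        [response_amplitude(t, response_window) for t in trials[:k]], dtype=float
    )
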