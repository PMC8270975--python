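"""Baseline vasomotion: bandpower and phase at stimulus onset.

Vasomotion is the spontaneous low-frequency (~0.1 Hz) oscillation of vessel
diameter.  Its strength is quantified as the average bandpower of the
percent-change baseline in the 0.02-1 Hz band (mean-removed rectangular
periodogram, ordinates summed over the band).  Its phase at stimulus onset
is classified from the 0.2 Hz-lowpassed baseline in a 2.5 s pre-stimulus
window (a quarter cycle at 0.1 Hz):

    phase 1: above baseline average and ascending
    phase 2: above baseline average and descending
    phase 3: below baseline average and descending
    phase 4: below baseline average and ascending
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.stats import pearsonr

from .trials import TrialTrace

__all__ = [
    "VasomotionProfile",
    "bandpower",
    "lowpass",
    "classify_phase",
    "vasomotion_profile",
    "power_response_correlation",
]

DEFAULT_BAND = (0.02, 1.0)
DEFAULT_CUTOFF = 0.2
PHASE_WINDOW_S = 2.5


def bandpower(
    values: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Average power of ``values`` within ``band`` (Hz).

    Mean-removed rectangular-window periodogram; band power is the sum of
    one-sided density ordinates within [band[0], band[1]] times the bin
    width, so a pure in-band sinusoid of amplitude A yields ~A^2/2.
    """
    lo, hi = band
    if fs <= 2 * hi:
        raise ValueError(f"sampling rate {fs} Hz cannot resolve a {hi} Hz band edge")
    values = np.asarray(values, dtype=float)
    f, pxx = signal.periodogram(values, fs=fs, window="boxcar", detrend="constant")
    df = f[1] - f[0]
    sel = (f >= lo) & (f <= hi)
    return float(np.sum(pxx[sel]) * df)


def lowpass(values: np.ndarray, fs: float, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Zero-phase lowpass (4th-order Butterworth, forward-backward).

    Unit DC gain; attenuation at twice the cutoff well beyond 20 dB.
    """
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    values = np.asarray(values, dtype=float)
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    padlen = min(values.size - 1, 3 * (2 * 4 + 1))
    return signal.sosfiltfilt(sos, values, padlen=padlen)


@dataclass
class VasomotionProfile:
    """Baseline vasomotion summary for one trial."""

    bandpower_02_1: float
    phase: int
    filtered_baseline: np.ndarray
    flags: tuple[str, ...] = ()


def classify_phase(
    trace: TrialTrace,
    stim_onset: float | None = None,
    window_s: float = PHASE_WINDOW_S,
    cutoff: float = DEFAULT_CUTOFF,
    trend: str = "endpoint",
) -> tuple[int, tuple[str, ...]]:
    """Classify the vasomotion phase in the pre-stimulus window.

    The percent-change trace is lowpassed at ``cutoff``; *above/below* is the
    sign of the window mean relative to the whole filtered-baseline mean, and
    *ascending/descending* the sign of the filtered end-minus-start
    difference over the window (``trend='regression'`` uses a least-squares
    slope instead).  Ties classify as the lower phase number and are flagged.
    """
    onset = trace.stim_onset if stim_onset is None else stim_onset
    trace = trace.filled()
    pre = trace.time < onset - 1e-12
    t_pre, v_pre = trace.time[pre], trace.value[pre]
    if t_pre.size == 0 or onset - t_pre[0] < window_s - 1e-9:
        raise ValueError(f"need >= {window_s} s of baseline before stimulus onset")
    filt = lowpass(v_pre, trace.rate, cutoff)
    ref = float(np.mean(filt))
    win = t_pre >= onset - window_s - 1e-12
    fw = filt[win]
    if fw.size < 2:
        raise ValueError("phase window contains fewer than 2 samples")
    flags: list[str] = []
    above = float(np.mean(fw)) - ref
    if trend == "regression":
        tw = t_pre[win]
        slope = float(np.polyfit(tw - tw[0], fw, 1)[0])
    else:
        slope = float(fw[-1] - fw[0])
    if above == 0.0:
        flags.append("tie_level")
    if slope == 0.0:
        flags.append("tie_trend")
    if above > 0:
        phase = 1 if slope > 0 else 2
    elif above < 0:
        phase = 4 if slope > 0 else 3
    else:  # exact tie on level: lower phase number given the trend
        phase = 1 if slope > 0 else 2
    if flags and "tie_trend" in flags:
        # zero trend: lower phase number within the level class
        phase = 1 if above >= 0 else 3
    return phase, tuple(flags)


def vasomotion_profile(
    trace: TrialTrace,
    band: tuple[float, float] = DEFAULT_BAND,
    cutoff: float = DEFAULT_CUTOFF,
    window_s: float = PHASE_WINDOW_S,
) -> VasomotionProfile:
    """Bandpower + phase of one percent-change trial baseline."""
    trace_f = trace.filled()
    base = trace_f.value[trace_f.window_mask(trace_f.baseline_window)]
    bp = bandpower(base, trace_f.rate, band)
    phase, flags = classify_phase(trace_f, window_s=window_s, cutoff=cutoff)
    pre = trace_f.time < trace_f.stim_onset - 1e-12
    return VasomotionProfile(
        bandpower_02_1=bp,
        phase=phase,
        filtered_baseline=lowpass(trace_f.value[pre], trace_f.rate, cutoff),
        flags=flags,
    )


def power_response_correlation(
    bandpowers: Sequence[float], responses: Sequence[float]
) -> tuple[float, int]:
    """Pearson correlation between baseline bandpower and a response metric.

    Returns ``(r, n)``.  Raises on unpaired input, n < 3, or zero variance.
    """
    bp = np.asarray(bandpowers, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if bp.shape != resp.shape:
        raise ValueError("bandpowers and responses must be paired")
    if bp.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(bp) == 0 or np.std(resp) == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(pearsonr(bp, resp).statistic)
    return r, int(bp.size)
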